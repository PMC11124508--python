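"""Structure and trajectory I/O, bond graphs, and the HintTable format.

PDB structures are read through biotite (altloc resolved to highest
occupancy, waters stripped by default); trajectories (XTC, DCD,
multi-model PDB) through MDAnalysis.  Covalent bonds come from residue
templates (the Chemical Component Dictionary bundled with biotite),
including the peptide C-N link between consecutive residues, with a
covalent-radius distance rule as fallback for non-template atoms.  From
the bond graph the 1-2 (bonded) and 1-3 (angle) exclusion sets are
derived; those pairs never enter the score sum.

Periodic-box images are NOT unwrapped: supply whole-molecule
trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .params import (
    HydropathicAtom,
    ParameterDictionary,
    apply_hydrogen_policy,
    default_dictionary,
    element_fallback_entry,
)

__all__ = [
    "MolecularSystem",
    "Frame",
    "Trajectory",
    "HintTableRecord",
    "StructureError",
    "EmptySelectionError",
    "TopologyMismatchError",
    "read_structure",
    "read_trajectory",
    "infer_bonds",
    "build_exclusions",
    "write_hint_table",
    "read_hint_table",
    "system_from_arrays",
    "write_pdb",
]

WATER_NAMES = frozenset({"HOH", "WAT", "SOL", "TIP3", "TIP4", "SPC", "DOD"})
ION_NAMES = frozenset({"NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "BR", "IOD"})

#: single-bond covalent radii (Å) for the distance-rule fallback
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39,
}
#: two atoms closer than this multiple of the sum of their covalent
#: radii are considered bonded (catches S-S at 2.05 Å, rejects 1-3 pairs)
BOND_TOLERANCE = 1.25


class StructureError(ValueError):
    """Malformed structural input."""


class EmptySelectionError(StructureError):
    """A filter left no atoms."""


class TopologyMismatchError(StructureError):
    """Trajectory atom count does not match the topology."""


@dataclass
class Frame:
    """Coordinates of one trajectory frame, in Å."""

    coordinates: np.ndarray
    frame_index: int = 0
    time: float = 0.0  # ps

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructureError("frame coordinates must be an (N, 3) array")


@dataclass
class MolecularSystem:
    """Atoms plus covalent bond graph and derived exclusion sets.

    Atom indices are 0-based and contiguous; user-facing output uses the
    source file's residue numbering.
    """

    atoms: list[HydropathicAtom]
    bonds: frozenset[tuple[int, int]] = frozenset()
    exclusions_12: frozenset[tuple[int, int]] = frozenset()
    exclusions_13: frozenset[tuple[int, int]] = frozenset()
    source: str = ""
    #: indices of these atoms in the source file (before filtering)
    source_indices: np.ndarray | None = None
    _parent_heavy: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def retained_mask(self) -> np.ndarray:
        return np.array([a.retained for a in self.atoms], dtype=bool)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=np.float64)

    @property
    def parent_heavy(self) -> np.ndarray:
        """For each atom, the index of its bonded heavy atom (itself if heavy).

        Used by the hydrogen-bond distance rule, which always measures
        heavy-atom/heavy-atom distances.
        """
        if self._parent_heavy is None:
            parent = np.arange(self.n_atoms)
            adjacency: dict[int, list[int]] = {}
            for i, j in self.bonds:
                adjacency.setdefault(i, []).append(j)
                adjacency.setdefault(j, []).append(i)
            for a in self.atoms:
                if a.is_hydrogen:
                    heavies = [
                        k for k in adjacency.get(a.atom_id, [])
                        if not self.atoms[k].is_hydrogen
                    ]
                    if heavies:
                        parent[a.atom_id] = heavies[0]
            self._parent_heavy = parent
        return self._parent_heavy

    def is_excluded(self, i: int, j: int) -> bool:
        pair = (i, j) if i < j else (j, i)
        return pair in self.exclusions_12 or pair in self.exclusions_13

    def residue_key(self, atom_index: int) -> tuple[str, int, str]:
        a = self.atoms[atom_index]
        return (a.chain_id, a.residue_number, a.residue_name)


@dataclass
class Trajectory:
    system: MolecularSystem
    frames: list[Frame]
    time_step: float = 0.0  # ps between stored frames

    def __post_init__(self) -> None:
        n = self.system.n_atoms
        for f in self.frames:
            if f.coordinates.shape[0] != n:
                raise TopologyMismatchError(
                    f"frame {f.frame_index} has {f.coordinates.shape[0]} atoms, "
                    f"system has {n}"
                )
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise StructureError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class HintTableRecord:
    """One scored atom pair, as written to the tabular output."""

    name_i: str
    residue_i: str
    number_i: int
    chain_i: str
    name_j: str
    residue_j: str
    number_j: int
    chain_j: str
    a_i: float
    s_i: float
    a_j: float
    s_j: float
    distance: float
    b_ij: float
    interaction_class: str


HINT_TABLE_COLUMNS = [
    "atom_i", "residue_i", "resnum_i", "chain_i",
    "atom_j", "residue_j", "resnum_j", "chain_j",
    "a_i", "S_i", "a_j", "S_j", "distance", "b_ij", "interaction_class",
]


# ---------------------------------------------------------------------------
# construction


def system_from_arrays(
    atom_names: Sequence[str],
    elements: Sequence[str],
    residue_names: Sequence[str],
    residue_numbers: Sequence[int],
    chain_ids: Sequence[str],
    coordinates: np.ndarray,
    dictionary: ParameterDictionary | None = None,
    hydrogen_policy: str = "semi_essential",
    source: str = "arrays",
    source_indices: np.ndarray | None = None,
) -> tuple[MolecularSystem, Frame]:
    """Build a fully parameterized system from parallel annotation arrays."""
    if dictionary is None:
        dictionary = default_dictionary()
    atoms = []
    for i, (name, elem, res, num, chain) in enumerate(
        zip(atom_names, elements, residue_names, residue_numbers, chain_ids)
    ):
        elem = (elem or _guess_element(name)).upper()
        entry = dictionary.lookup(res, name)
        if entry is None:
            entry = element_fallback_entry(elem)
            if res.upper() not in WATER_NAMES:
                warnings.warn(
                    f"no dictionary entry for {res} {name}; using element "
                    f"fallback for {elem}",
                    stacklevel=2,
                )
        atoms.append(
            HydropathicAtom(
                atom_id=i,
                atom_name=name,
                element=elem,
                residue_name=res,
                residue_number=int(num),
                chain_id=str(chain),
                hydrophobic_constant=entry.hydrophobic_constant,
                polarity_class=entry.polarity_class,
                radius=entry.radius,
                is_hydrogen=(elem == "H"),
            )
        )
    frame = Frame(coordinates=np.asarray(coordinates, dtype=np.float64))
    system = MolecularSystem(atoms=atoms, source=source, source_indices=source_indices)
    system.bonds = infer_bonds(system, frame)
    system.exclusions_12, system.exclusions_13 = build_exclusions(system.bonds)
    system.atoms = apply_hydrogen_policy(system.atoms, system.bonds, hydrogen_policy)
    for k, a in enumerate(system.atoms):
        a.atom_id = k
        a.validate()
    return system, frame


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise StructureError(f"cannot infer element from atom name {atom_name!r}")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE"):
        return stripped[:2].upper()
    return stripped[0].upper()


# ---------------------------------------------------------------------------
# reading


def read_structure(
    path: str | Path,
    chain_filter: str | None = None,
    keep_waters: bool = False,
    include_ligand: bool = True,
    dictionary: ParameterDictionary | None = None,
    hydrogen_policy: str = "semi_essential",
) -> tuple[MolecularSystem, Frame]:
    """Read a PDB file into a parameterized system plus coordinates.

    Atoms keep file order and verbatim residue numbering; altlocs are
    resolved to the highest-occupancy variant (ties favour altloc 'A');
    waters are stripped unless ``keep_waters``.
    """
    import biotite.structure.io.pdb as pdbio

    path = Path(path)
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        array = pdb_file.get_structure(model=1, altloc="occupancy")
    except Exception as exc:
        raise StructureError(f"cannot parse {path.name}: {exc}") from exc

    mask = np.ones(array.array_length(), dtype=bool)
    if chain_filter is not None:
        mask &= array.chain_id == chain_filter
    if not keep_waters:
        mask &= ~np.isin(array.res_name, list(WATER_NAMES))
        mask &= ~np.isin(array.res_name, list(ION_NAMES))
    if not include_ligand:
        mask &= ~array.hetero
    if not mask.any():
        raise EmptySelectionError(
            f"{path.name}: no atoms left after filtering "
            f"(chain={chain_filter!r}, keep_waters={keep_waters})"
        )
    source_indices = np.flatnonzero(mask)
    array = array[mask]
    return system_from_arrays(
        atom_names=list(array.atom_name),
        elements=list(array.element),
        residue_names=list(array.res_name),
        residue_numbers=list(array.res_id),
        chain_ids=list(array.chain_id),
        coordinates=array.coord,
        dictionary=dictionary,
        hydrogen_policy=hydrogen_policy,
        source=str(path),
        source_indices=source_indices,
    )


def read_trajectory(
    topology: str | Path,
    traj: str | Path,
    stride: int = 1,
    chain_filter: str | None = None,
    keep_waters: bool = False,
    dictionary: ParameterDictionary | None = None,
    hydrogen_policy: str = "semi_essential",
) -> Trajectory:
    """Read a trajectory (XTC, DCD, or multi-model PDB) against a PDB topology.

    The topology defines atom identity and parameterization; frames are
    subset to the topology's post-filter atom selection and strided.
    """
    import MDAnalysis as mda

    if stride < 1:
        raise StructureError("stride must be >= 1")
    system, _ = read_structure(
        topology, chain_filter=chain_filter, keep_waters=keep_waters,
        dictionary=dictionary, hydrogen_policy=hydrogen_policy,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            universe = mda.Universe(str(topology), str(traj))
        except Exception as exc:
            raise StructureError(f"cannot read trajectory {traj}: {exc}") from exc
        n_file_atoms = int(np.max(system.source_indices)) + 1
        if universe.atoms.n_atoms < n_file_atoms:
            raise TopologyMismatchError(
                f"trajectory has {universe.atoms.n_atoms} atoms but topology "
                f"selection references atom index {n_file_atoms - 1}"
            )
        frames = []
        for k, ts in enumerate(universe.trajectory[::stride]):
            coords = np.asarray(ts.positions, dtype=np.float64)[system.source_indices]
            frames.append(Frame(coordinates=coords, frame_index=k, time=float(ts.time)))
    if not frames:
        raise StructureError(f"trajectory {traj} contains no frames")
    dt = frames[1].time - frames[0].time if len(frames) > 1 else 0.0
    return Trajectory(system=system, frames=frames, time_step=dt)


# ---------------------------------------------------------------------------
# bonds and exclusions


def infer_bonds(system: MolecularSystem, frame: Frame) -> frozenset[tuple[int, int]]:
    """Covalent bonds from residue templates plus a distance fallback.

    Standard residues (and anything else in the component dictionary)
    are connected by atom name, including inter-residue peptide links;
    atoms left unbonded are connected to any neighbour closer than
    ``BOND_TOLERANCE`` times the sum of their covalent radii.
    """
    import biotite.structure as struc

    n = system.n_atoms
    array = struc.AtomArray(n)
    array.coord = frame.coordinates.astype(np.float32)
    array.atom_name = np.array([a.atom_name for a in system.atoms])
    array.element = np.array([a.element for a in system.atoms])
    array.res_name = np.array([a.residue_name for a in system.atoms])
    array.res_id = np.array([a.residue_number for a in system.atoms])
    array.chain_id = np.array([a.chain_id for a in system.atoms])
    bond_list = struc.connect_via_residue_names(array, inter_residue=True)
    bonds = {
        (int(i), int(j)) if i < j else (int(j), int(i))
        for i, j, _ in bond_list.as_array()
    }

    rcov = np.array(
        [COVALENT_RADII.get(a.element.upper(), 0.77) for a in system.atoms]
    )
    bonded = set()
    for i, j in bonds:
        bonded.add(i)
        bonded.add(j)
    orphans = [k for k in range(n) if k not in bonded]
    if orphans and n > 1:
        from scipy.spatial import cKDTree

        tree = cKDTree(frame.coordinates)
        max_cut = BOND_TOLERANCE * 2 * rcov.max()
        for k in orphans:
            for m in tree.query_ball_point(frame.coordinates[k], max_cut):
                if m == k:
                    continue
                d = float(np.linalg.norm(frame.coordinates[k] - frame.coordinates[m]))
                if d < BOND_TOLERANCE * (rcov[k] + rcov[m]):
                    bonds.add((k, m) if k < m else (m, k))

    # disulfide bridges: templates cannot know about them, so any two
    # sulfurs within the covalent distance rule are linked
    sulfurs = [k for k in range(n) if system.atoms[k].element.upper() == "S"]
    for a_pos in range(len(sulfurs)):
        for b_pos in range(a_pos + 1, len(sulfurs)):
            k, m = sulfurs[a_pos], sulfurs[b_pos]
            d = float(np.linalg.norm(frame.coordinates[k] - frame.coordinates[m]))
            if d < BOND_TOLERANCE * (rcov[k] + rcov[m]):
                bonds.add((k, m) if k < m else (m, k))
    still_orphan = [
        k for k in range(n)
        if not any(k in pair for pair in bonds)
    ]
    if still_orphan and n > 1:
        names = ", ".join(
            f"{system.atoms[k].residue_name}{system.atoms[k].residue_number}/"
            f"{system.atoms[k].atom_name}"
            for k in still_orphan[:5]
        )
        warnings.warn(f"{len(still_orphan)} atom(s) with no bonds (e.g. {names})",
                      stacklevel=2)
    return frozenset(bonds)


def build_exclusions(
    bonds: Iterable[tuple[int, int]],
) -> tuple[frozenset[tuple[int, int]], frozenset[tuple[int, int]]]:
    """1-2 and 1-3 exclusion sets from the bond graph.

    1-2 pairs are the bonds themselves; 1-3 pairs are at graph distance
    exactly two (i.e. share a bonded neighbour but are not bonded).
    """
    bonds12 = frozenset(
        (i, j) if i < j else (j, i) for i, j in bonds
    )
    adjacency: dict[int, set[int]] = {}
    for i, j in bonds12:
        adjacency.setdefault(i, set()).add(j)
        adjacency.setdefault(j, set()).add(i)
    excl13 = set()
    for center, neighbors in adjacency.items():
        nb = sorted(neighbors)
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                pair = (nb[a], nb[b])
                if pair not in bonds12:
                    excl13.add(pair)
    return bonds12, frozenset(excl13)


# ---------------------------------------------------------------------------
# HintTable output


def write_hint_table(records: Sequence[HintTableRecord], path: str | Path) -> None:
    """Write scored pairs as TSV, one row per pair, interaction class last.

    Rows are emitted in canonical order (atom_i index, then atom_j); the
    formatting is fixed so identical runs produce byte-identical files.
    """
    path = Path(path)
    lines = ["\t".join(HINT_TABLE_COLUMNS)]
    for r in records:
        lines.append(
            f"{r.name_i}\t{r.residue_i}\t{r.number_i}\t{r.chain_i}\t"
            f"{r.name_j}\t{r.residue_j}\t{r.number_j}\t{r.chain_j}\t"
            f"{r.a_i:.6g}\t{r.s_i:.6g}\t{r.a_j:.6g}\t{r.s_j:.6g}\t"
            f"{r.distance:.6g}\t{r.b_ij:.6g}\t{r.interaction_class}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_hint_table(path: str | Path):
    """Read a HintTable TSV back as a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(path, sep="\t")


def write_pdb(system: MolecularSystem, frames: Frame | Sequence[Frame],
              path: str | Path) -> None:
    """Write the system as a (multi-model) PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    if isinstance(frames, Frame):
        frames = [frames]
    n = system.n_atoms
    array = struc.AtomArray(n)
    array.atom_name = np.array([a.atom_name for a in system.atoms])
    array.element = np.array([a.element for a in system.atoms])
    array.res_name = np.array([a.residue_name for a in system.atoms])
    array.res_id = np.array([a.residue_number for a in system.atoms])
    array.chain_id = np.array([a.chain_id for a in system.atoms])
    if len(frames) == 1:
        array.coord = frames[0].coordinates.astype(np.float32)
        target = array
    else:
        stack = struc.stack([array] * len(frames))
        stack.coord = np.stack(
            [f.coordinates.astype(np.float32) for f in frames]
        )
        target = stack
    out = pdbio.PDBFile()
    out.set_structure(target)
    out.write(str(path))
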