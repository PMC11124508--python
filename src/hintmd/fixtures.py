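"""Deterministic synthetic structures and trajectories with known truth.

Small peptide systems are assembled from idealized residue geometries
(the Chemical Component Dictionary templates bundled with biotite) so
that every part of the pipeline — parameterization, bond inference,
SASA, scoring, trajectory analysis — can be exercised without fetching
any structure.  Residues are spaced generously along the chain axis;
the covalent graph is correct (template-based), the backbone geometry
intentionally is not, which is irrelevant for the quantities the
fixtures pin down (contact distances, exclusion sets, fluctuation
amplitudes).

Acidic protons (Asp HD2, Glu HE2) and free-molecule termini (OXT, HXT,
H2) are removed, matching the neutral-pH protonation the parameter
table assumes.

`brute_force_frame` is an independent reference scorer (plain double
loop, breadth-first-search exclusions via networkx) used as the oracle
against the engine's pruned implementation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .params import ParameterDictionary
from .sasa import AtomSASA
from .scoring import ScoreConfig
from .structure import (
    COVALENT_RADII,
    Frame,
    HintTableRecord,
    MolecularSystem,
    StructureError,
    Trajectory,
    system_from_arrays,
    write_hint_table,
    write_pdb,
)

__all__ = [
    "FixtureSpec",
    "DEFAULT_CONTACT_ATOMS",
    "make_peptide",
    "make_contact_pair",
    "make_hinge_trajectory",
    "make_translated_trajectory",
    "make_golden_hint_table",
    "brute_force_frame",
]

#: template atoms dropped from every fixture residue
_DROP_ATOMS = frozenset({"OXT", "HXT", "H2"})
#: acidic protons absent at neutral pH
_DROP_PER_RESIDUE = {"ASP": frozenset({"HD2"}), "GLU": frozenset({"HE2"})}

#: representative side-chain contact atom per residue for contact pairs
DEFAULT_CONTACT_ATOMS = {
    "ASP": "OD1", "GLU": "OE1", "LYS": "NZ", "ARG": "NH1", "SER": "OG",
    "THR": "OG1", "TYR": "OH", "ASN": "OD1", "GLN": "OE1", "HIS": "NE2",
    "LEU": "CD1", "ILE": "CD1", "VAL": "CG1", "ALA": "CB", "PHE": "CZ",
    "MET": "SD", "CYS": "SG", "TRP": "NE1", "GLY": "CA", "PRO": "CG",
}


@dataclass
class FixtureSpec:
    """Parameters of a synthetic trajectory fixture.

    The seed fully determines the output; regenerating with the same
    spec yields byte-identical files.
    """

    name: str = "hinge"
    n_residues: int = 6
    sequence: tuple[str, ...] | None = None  # defaults to poly-ALA
    geometry_mode: str = "hinge"  # extended | contact_pair | hinge
    displacement_amplitude: float = 3.0  # Å RMS displacement of the mobile half
    jitter_sigma: float = 0.0  # Å per-coordinate Gaussian jitter
    n_frames: int = 10
    seed: int = 0
    time_step: float = 20.0  # ps between stored frames

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise StructureError("n_frames must be >= 1")
        if self.sequence is None:
            self.sequence = tuple(["ALA"] * self.n_residues)
        self.n_residues = len(self.sequence)


def _template(res_name: str) -> tuple[list[str], list[str], np.ndarray]:
    """Atom names, elements, centered coordinates of one residue template."""
    import biotite.structure.info as info

    res = info.residue(res_name)
    drop = _DROP_ATOMS | _DROP_PER_RESIDUE.get(res_name, frozenset())
    mask = ~np.isin(res.atom_name, list(drop))
    res = res[mask]
    coords = res.coord.astype(np.float64)
    coords = coords - coords.mean(axis=0)
    return list(res.atom_name), list(res.element), coords


def _assemble(
    residues: list[tuple[str, np.ndarray]],
    chain_id: str = "A",
    dictionary: ParameterDictionary | None = None,
    hydrogen_policy: str = "semi_essential",
    source: str = "fixture",
) -> tuple[MolecularSystem, Frame]:
    names: list[str] = []
    elements: list[str] = []
    res_names: list[str] = []
    res_numbers: list[int] = []
    chains: list[str] = []
    coords: list[np.ndarray] = []
    for number, (res_name, offset_coords) in enumerate(residues, start=1):
        t_names, t_elements, _ = _template(res_name)
        names.extend(t_names)
        elements.extend(t_elements)
        res_names.extend([res_name] * len(t_names))
        res_numbers.extend([number] * len(t_names))
        chains.extend([chain_id] * len(t_names))
        coords.append(offset_coords)
    return system_from_arrays(
        atom_names=names,
        elements=elements,
        residue_names=res_names,
        residue_numbers=res_numbers,
        chain_ids=chains,
        coordinates=np.vstack(coords),
        dictionary=dictionary,
        hydrogen_policy=hydrogen_policy,
        source=source,
    )


def make_peptide(
    sequence: tuple[str, ...] | list[str],
    spacing: float = 8.0,
    dictionary: ParameterDictionary | None = None,
    hydrogen_policy: str = "semi_essential",
) -> tuple[MolecularSystem, Frame]:
    """A chain of template residues spaced ``spacing`` Å apart along x."""
    residues = []
    for k, res_name in enumerate(sequence):
        _, _, coords = _template(res_name)
        residues.append((res_name, coords + np.array([k * spacing, 0.0, 0.0])))
    return _assemble(residues, source=f"peptide:{'-'.join(sequence)}")


def _orient(coords: np.ndarray, contact_index: int, direction: np.ndarray) -> np.ndarray:
    """Rotate so the centroid lies along ``direction`` from the contact
    atom, then put the contact atom at the origin."""
    shifted = coords - coords[contact_index]
    centroid = shifted.mean(axis=0)
    norm = np.linalg.norm(centroid)
    if norm < 1e-9:
        return shifted
    v = centroid / norm
    d = direction / np.linalg.norm(direction)
    axis = np.cross(v, d)
    s = np.linalg.norm(axis)
    c = float(np.dot(v, d))
    if s < 1e-12:
        if c > 0:
            return shifted
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(v[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(v, perp)
        axis /= np.linalg.norm(axis)
        s, c = 0.0, -1.0
        k = np.array([
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ])
        rot = np.eye(3) + 2.0 * (k @ k)
        return shifted @ rot.T
    axis = axis / s
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    rot = np.eye(3) + s * k + (1 - c) * (k @ k)
    return shifted @ rot.T


def make_contact_pair(
    donor_residue: str,
    acceptor_residue: str,
    heavy_atom_distance: float,
    contact_atoms: tuple[str, str] | None = None,
    dictionary: ParameterDictionary | None = None,
    hydrogen_policy: str = "semi_essential",
) -> tuple[MolecularSystem, Frame]:
    """Two residues posed so their contact atoms sit at an exact distance.

    Each residue is oriented with its body pointing away from the
    contact, so the designated heavy atoms are the closest approach.
    The built distance is exact to well below 1e-3 Å.
    """
    if contact_atoms is None:
        contact_atoms = (
            DEFAULT_CONTACT_ATOMS[donor_residue],
            DEFAULT_CONTACT_ATOMS[acceptor_residue],
        )
    name_a, name_b = contact_atoms
    names_a, elements_a, coords_a = _template(donor_residue)
    names_b, elements_b, coords_b = _template(acceptor_residue)
    try:
        ia = names_a.index(name_a)
        ib = names_b.index(name_b)
    except ValueError as exc:
        raise StructureError(f"contact atom not in residue template: {exc}") from exc
    ra = COVALENT_RADII.get(elements_a[ia].upper(), 0.77)
    rb = COVALENT_RADII.get(elements_b[ib].upper(), 0.77)
    # anything shorter than 90% of the covalent-radii sum is a clash even
    # for a covalently bonded pair (e.g. a 2.05 Å disulfide is fine)
    if heavy_atom_distance < 0.9 * (ra + rb):
        raise StructureError(
            f"requested contact distance {heavy_atom_distance} Å overlaps the "
            f"contact atoms (covalent radii sum {ra + rb:.2f} Å)"
        )
    coords_a = _orient(coords_a, ia, np.array([-1.0, 0.0, 0.0]))
    coords_b = _orient(coords_b, ib, np.array([+1.0, 0.0, 0.0]))
    coords_b = coords_b + np.array([heavy_atom_distance, 0.0, 0.0])
    names = names_a + names_b
    elements = elements_a + elements_b
    res_names = [donor_residue] * len(names_a) + [acceptor_residue] * len(names_b)
    res_numbers = [1] * len(names_a) + [2] * len(names_b)
    chains = ["A"] * len(names)
    system, frame = system_from_arrays(
        atom_names=names,
        elements=elements,
        residue_names=res_names,
        residue_numbers=res_numbers,
        chain_ids=chains,
        coordinates=np.vstack([coords_a, coords_b]),
        dictionary=dictionary,
        hydrogen_policy=hydrogen_policy,
        source=f"contact:{donor_residue}-{acceptor_residue}@{heavy_atom_distance}",
    )
    # the residues are deliberately disconnected: drop the spurious
    # peptide C-N link the template connector adds between consecutive
    # residue numbers (real contacts, e.g. disulfides, are kept)
    n_a = len(names_a)
    bonds = frozenset(
        (i, j) for i, j in system.bonds
        if (i < n_a) == (j < n_a)
        or {system.atoms[i].atom_name, system.atoms[j].atom_name} != {"C", "N"}
    )
    if bonds != system.bonds:
        from .structure import build_exclusions

        system.bonds = bonds
        system.exclusions_12, system.exclusions_13 = build_exclusions(bonds)
        system._parent_heavy = None
    achieved = float(np.linalg.norm(frame.coordinates[ia] - frame.coordinates[n_a + ib]))
    assert abs(achieved - heavy_atom_distance) < 1e-6
    return system, frame


def make_hinge_trajectory(
    spec: FixtureSpec,
    dictionary: ParameterDictionary | None = None,
) -> tuple[Trajectory, dict]:
    """A trajectory whose second half oscillates about its mean.

    Mobile residues alternate between +A and -A along z (so each mobile
    atom's RMS displacement about its mean is exactly the amplitude A),
    optionally with per-coordinate Gaussian jitter of width
    ``jitter_sigma`` applied to every atom.  ``n_frames`` must be even
    so the alternation averages to zero.  Returns the trajectory and a
    manifest with the ground-truth per-residue RMSF.
    """
    if spec.geometry_mode != "hinge":
        raise StructureError("make_hinge_trajectory needs geometry_mode='hinge'")
    if spec.n_frames % 2 != 0:
        raise StructureError("hinge fixture needs an even n_frames")
    system, base = make_peptide(spec.sequence, dictionary=dictionary)
    n_mobile_res = spec.n_residues // 2
    mobile_first_res = spec.n_residues - n_mobile_res + 1
    mobile_mask = np.array(
        [a.residue_number >= mobile_first_res for a in system.atoms]
    )
    rng = np.random.default_rng(spec.seed)
    amplitude = spec.displacement_amplitude
    frames = []
    for t in range(spec.n_frames):
        sign = 1.0 if t % 2 == 0 else -1.0
        coords = base.coordinates.copy()
        coords[mobile_mask, 2] += sign * amplitude
        if spec.jitter_sigma > 0:
            coords += rng.normal(0.0, spec.jitter_sigma, size=coords.shape)
        frames.append(
            Frame(coordinates=coords, frame_index=t, time=t * spec.time_step)
        )
    truth_rmsf = {}
    expected = math.sqrt(amplitude ** 2 + 3 * spec.jitter_sigma ** 2)
    expected_rigid = math.sqrt(3) * spec.jitter_sigma
    for a in system.atoms:
        key = (a.chain_id, a.residue_number)
        truth_rmsf[key] = (
            expected if a.residue_number >= mobile_first_res else expected_rigid
        )
    manifest = {
        "name": spec.name,
        "sequence": list(spec.sequence),
        "n_frames": spec.n_frames,
        "seed": spec.seed,
        "rng": "numpy.default_rng(PCG64)",
        "displacement_amplitude": amplitude,
        "jitter_sigma": spec.jitter_sigma,
        "mobile_residues": list(range(mobile_first_res, spec.n_residues + 1)),
        "rigid_residues": list(range(1, mobile_first_res)),
        "expected_mobile_rmsf": expected,
        "expected_rigid_rmsf": expected_rigid,
        "rmsf_per_residue": {
            f"{c}:{n}": v for (c, n), v in sorted(truth_rmsf.items())
        },
    }
    return Trajectory(system=system, frames=frames, time_step=spec.time_step), manifest


def make_translated_trajectory(
    system: MolecularSystem,
    frame: Frame,
    n_frames: int,
    step: tuple[float, float, float] = (5.0, 0.0, 0.0),
    time_step: float = 20.0,
) -> Trajectory:
    """Rigid translation of the same conformation, one step per frame.

    After superposition every frame is identical: RMSD and RMSF are
    exactly zero, and every internal score is unchanged frame to frame.
    """
    step_v = np.asarray(step, dtype=np.float64)
    frames = [
        Frame(coordinates=frame.coordinates + t * step_v, frame_index=t,
              time=t * time_step)
        for t in range(n_frames)
    ]
    return Trajectory(system=system, frames=frames, time_step=time_step)


# ---------------------------------------------------------------------------
# independent reference scorer


def _bfs_excluded(bonds: frozenset[tuple[int, int]], n_atoms: int):
    """Pairs at graph distance 1 or 2, via networkx shortest paths."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n_atoms))
    g.add_edges_from(bonds)
    excluded = set()
    for i in range(n_atoms):
        lengths = nx.single_source_shortest_path_length(g, i, cutoff=2)
        for j, dist in lengths.items():
            if j > i and dist in (1, 2):
                excluded.add((i, j))
    return excluded


def brute_force_frame(
    system: MolecularSystem,
    frame: Frame,
    sasa: AtomSASA,
    config: ScoreConfig | None = None,
) -> tuple[float, list[tuple[int, int, float, str]]]:
    """Plain O(N^2) reference scorer, independent of the engine.

    Enumerates all retained atom pairs (no spatial pruning beyond the
    configured cutoff), removes pairs at bond-graph distance <= 2 found
    by breadth-first search, and evaluates the score term directly.
    Returns the total and the scored (i, j, b_ij, class) list in
    canonical order.
    """
    if config is None:
        config = ScoreConfig()
    excluded = _bfs_excluded(system.bonds, system.n_atoms)
    coords = frame.coordinates
    atoms = system.atoms
    parent = system.parent_heavy
    total = 0.0
    rows = []
    for i in range(system.n_atoms):
        if not atoms[i].retained:
            continue
        for j in range(i + 1, system.n_atoms):
            if not atoms[j].retained:
                continue
            if (i, j) in excluded:
                continue
            d = math.dist(coords[i], coords[j])
            if config.cutoff is not None and d > config.cutoff:
                continue
            ci = atoms[i].polarity_class
            cj = atoms[j].polarity_class
            if ci == "hydrophobic" and cj == "hydrophobic":
                cls = "hydrophobic"
                sign = +1
            elif "hydrophobic" in (ci, cj):
                cls = "hydrophobic_polar"
                sign = -1
            elif ci == cj == "acid":
                cls = "acid_acid"
                sign = -1
            elif ci == cj == "base":
                cls = "base_base"
                sign = -1
            else:
                hd = math.dist(coords[parent[i]], coords[parent[j]])
                cls = "hydrogen_bond" if hd <= config.hbond_threshold else "acid_base"
                sign = +1
            if config.distance_function == "exponential":
                r = math.exp(-d)
            elif config.distance_function == "linear":
                r = max(0.0, 1.0 - d / 10.0)
            else:
                r = 1.0 / (d * d)
            b = sign * abs(
                sasa.values[i] * atoms[i].hydrophobic_constant
                * sasa.values[j] * atoms[j].hydrophobic_constant
            ) * r
            total += b
            rows.append((i, j, b, cls))
    return total, rows


def make_golden_hint_table(
    system: MolecularSystem,
    frame: Frame,
    sasa: AtomSASA,
    table_path: str | Path,
    manifest_path: str | Path | None = None,
    config: ScoreConfig | None = None,
) -> dict:
    """Brute-force-scored golden HintTable plus a settings manifest."""
    if config is None:
        config = ScoreConfig()
    if system.n_atoms > 50:
        raise StructureError("golden tables are for small systems (<= 50 atoms)")
    total, rows = brute_force_frame(system, frame, sasa, config)
    records = []
    for i, j, b, cls in rows:
        ai = system.atoms[i]
        aj = system.atoms[j]
        records.append(
            HintTableRecord(
                name_i=ai.atom_name, residue_i=ai.residue_name,
                number_i=ai.residue_number, chain_i=ai.chain_id,
                name_j=aj.atom_name, residue_j=aj.residue_name,
                number_j=aj.residue_number, chain_j=aj.chain_id,
                a_i=ai.hydrophobic_constant, s_i=float(sasa.values[i]),
                a_j=aj.hydrophobic_constant, s_j=float(sasa.values[j]),
                distance=math.dist(frame.coordinates[i], frame.coordinates[j]),
                b_ij=b, interaction_class=cls,
            )
        )
    write_hint_table(records, table_path)
    manifest = {
        "source": system.source,
        "n_atoms": system.n_atoms,
        "n_scored_pairs": len(rows),
        "total": total,
        "config": {
            "distance_function": config.distance_function,
            "cutoff": config.cutoff,
            "hbond_threshold": config.hbond_threshold,
            "sasa_probe_radius": sasa.probe_radius,
            "sasa_n_points": sasa.n_sphere_points,
        },
    }
    if manifest_path is not None:
        Path(manifest_path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
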