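"""Hydropathic atom parameterization.

Every atom entering the scoring function carries three parameters: a
hydrophobic atom constant ``a_i`` (dimensionless, derived from fragment
LogP_o/w contributions; positive for apolar atoms, negative for polar
ones), a polarity class used for interaction typing, and a van der Waals
radius used for surface-area computation.

Parameters are looked up in a :class:`ParameterDictionary` keyed by
``(residue_name, atom_name)``.  The bundled default table covers the 20
standard amino acids (including hydrogens and common terminal variants)
and was generated from simple atomic-contribution rules in the spirit of
Ghose-Crippen atomic LogP schemes; it is fully user-replaceable via the
TSV interface.  Protonation states follow neutral pH: Asp/Glu
carboxylates deprotonated (acid class), Lys/Arg protonated (base class),
His neutral by default (switchable), Ser/Thr/Tyr/Cys hydroxyl/thiol
polar-neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

__all__ = [
    "POLARITY_CLASSES",
    "HydropathicAtom",
    "ParameterEntry",
    "ParameterDictionary",
    "ParameterError",
    "TopologyError",
    "load_parameter_dictionary",
    "write_parameter_dictionary",
    "default_dictionary",
    "classify_polarity",
    "apply_hydrogen_policy",
    "element_fallback_entry",
]

POLARITY_CLASSES = frozenset({"hydrophobic", "acid", "base", "polar_neutral"})

#: classes whose atoms can accept a hydrogen bond
ACCEPTOR_CLASSES = frozenset({"acid", "polar_neutral"})
#: classes whose atoms can donate a hydrogen bond
DONOR_CLASSES = frozenset({"base", "polar_neutral"})

VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}


class ParameterError(ValueError):
    """Raised on malformed or inconsistent parameter input."""


class TopologyError(ValueError):
    """Raised when bonding context required for an operation is missing."""


class ParameterEntry(NamedTuple):
    hydrophobic_constant: float
    polarity_class: str
    radius: float


@dataclass
class HydropathicAtom:
    """One atom with hydropathic parameters attached.

    ``retained`` records the outcome of the hydrogen policy: non-hydrogen
    atoms are always retained; hydrogens only if the policy keeps them.
    Non-retained atoms are excluded from SASA and scoring but keep their
    index so that trajectory coordinates stay aligned.
    """

    atom_id: int
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    hydrophobic_constant: float = 0.0
    polarity_class: str = "hydrophobic"
    radius: float = 1.70
    is_hydrogen: bool = False
    retained: bool = True

    def validate(self) -> None:
        if self.polarity_class not in POLARITY_CLASSES:
            raise ParameterError(
                f"unknown polarity class {self.polarity_class!r} on atom "
                f"{self.residue_name} {self.atom_name}"
            )
        _check_sign_consistency(
            self.hydrophobic_constant, self.polarity_class,
            f"{self.residue_name} {self.atom_name}",
        )
        if self.radius <= 0:
            raise ParameterError(
                f"non-positive radius on atom {self.residue_name} {self.atom_name}"
            )
        if not self.is_hydrogen and not self.retained:
            raise ParameterError("non-hydrogen atoms must be retained")


def _check_sign_consistency(constant: float, polarity_class: str, where: str) -> None:
    if polarity_class == "hydrophobic" and constant <= 0:
        raise ParameterError(
            f"{where}: hydrophobic class requires a positive constant, got {constant}"
        )
    if polarity_class in ("acid", "base", "polar_neutral") and constant >= 0:
        raise ParameterError(
            f"{where}: polar class {polarity_class} requires a negative "
            f"constant, got {constant}"
        )


@dataclass
class ParameterDictionary:
    """Mapping ``(residue_name, atom_name) -> ParameterEntry``."""

    entries: dict[tuple[str, str], ParameterEntry] = field(default_factory=dict)
    provenance: str = ""
    version: str = ""

    def lookup(self, residue_name: str, atom_name: str) -> ParameterEntry | None:
        return self.entries.get((residue_name.upper(), atom_name.upper()))

    def residues_covered(self) -> set[str]:
        return {res for res, _ in self.entries}

    def validate(self) -> None:
        for (res, atom), entry in self.entries.items():
            if entry.polarity_class not in POLARITY_CLASSES:
                raise ParameterError(
                    f"row {res} {atom}: unknown class {entry.polarity_class!r}"
                )
            _check_sign_consistency(
                entry.hydrophobic_constant, entry.polarity_class, f"row {res} {atom}"
            )
            if entry.radius <= 0:
                raise ParameterError(f"row {res} {atom}: non-positive radius")


_TSV_COLUMNS = ("residue", "atom", "constant", "class", "radius")


def load_parameter_dictionary(path: str | Path) -> ParameterDictionary:
    """Load and validate a TSV parameter dictionary.

    Format: tab-separated columns ``residue atom constant class radius``
    with a header row; ``#``-prefixed lines before the header may carry
    ``# provenance: ...`` and ``# version: ...`` metadata.
    """
    path = Path(path)
    provenance = ""
    version = ""
    header: list[str] | None = None
    entries: dict[tuple[str, str], ParameterEntry] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("provenance:"):
                    provenance = body.split(":", 1)[1].strip()
                elif body.lower().startswith("version:"):
                    version = body.split(":", 1)[1].strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                missing = [c for c in _TSV_COLUMNS if c not in header]
                if missing:
                    raise ParameterError(
                        f"{path.name}: missing column(s) {missing} in header"
                    )
                continue
            row = dict(zip(header, fields))
            key = (row["residue"].strip().upper(), row["atom"].strip().upper())
            if key in entries:
                raise ParameterError(
                    f"{path.name}:{lineno}: duplicate key {key[0]} {key[1]}"
                )
            try:
                entry = ParameterEntry(
                    float(row["constant"]), row["class"].strip(), float(row["radius"])
                )
            except ValueError as exc:
                raise ParameterError(f"{path.name}:{lineno}: {exc}") from exc
            if entry.polarity_class not in POLARITY_CLASSES:
                raise ParameterError(
                    f"{path.name}:{lineno}: unknown class {entry.polarity_class!r}"
                )
            try:
                _check_sign_consistency(
                    entry.hydrophobic_constant, entry.polarity_class,
                    f"{path.name}:{lineno} ({key[0]} {key[1]})",
                )
            except ParameterError:
                raise
            if entry.radius <= 0:
                raise ParameterError(
                    f"{path.name}:{lineno}: non-positive radius for {key[0]} {key[1]}"
                )
            entries[key] = entry
    if header is None:
        raise ParameterError(f"{path.name}: no header row found")
    return ParameterDictionary(entries=entries, provenance=provenance, version=version)


def write_parameter_dictionary(dictionary: ParameterDictionary, path: str | Path) -> None:
    """Write a dictionary as TSV (sorted rows; round-trips exactly)."""
    path = Path(path)
    lines = []
    if dictionary.provenance:
        lines.append(f"# provenance: {dictionary.provenance}")
    if dictionary.version:
        lines.append(f"# version: {dictionary.version}")
    lines.append("\t".join(_TSV_COLUMNS))
    for (res, atom) in sorted(dictionary.entries):
        entry = dictionary.entries[(res, atom)]
        lines.append(
            f"{res}\t{atom}\t{entry.hydrophobic_constant:+.2f}\t"
            f"{entry.polarity_class}\t{entry.radius:.2f}"
        )
    path.write_text("\n".join(lines) + "\n")


_DEFAULT_CACHE: dict[bool, ParameterDictionary] = {}


def default_dictionary(his_protonated: bool = False) -> ParameterDictionary:
    """The bundled default parameter table (neutral pH).

    ``his_protonated=True`` switches histidine imidazole nitrogens from
    polar-neutral to base (doubly protonated side chain).
    """
    if his_protonated not in _DEFAULT_CACHE:
        with resources.as_file(
            resources.files("hintmd").joinpath("data/default_dictionary.tsv")
        ) as p:
            d = load_parameter_dictionary(p)
        if his_protonated:
            for atom in ("ND1", "NE2"):
                old = d.entries[("HIS", atom)]
                d.entries[("HIS", atom)] = ParameterEntry(-1.00, "base", old.radius)
        _DEFAULT_CACHE[his_protonated] = d
    return _DEFAULT_CACHE[his_protonated]


_ELEMENT_FALLBACK = {
    "C": ParameterEntry(+0.30, "hydrophobic", 1.70),
    "N": ParameterEntry(-0.60, "base", 1.55),
    "O": ParameterEntry(-0.75, "acid", 1.52),
    "S": ParameterEntry(-0.30, "polar_neutral", 1.80),
    "P": ParameterEntry(-0.40, "polar_neutral", 1.80),
    "H": ParameterEntry(+0.10, "hydrophobic", 1.20),
}


def element_fallback_entry(element: str) -> ParameterEntry:
    """Generic per-element parameters for atoms absent from the dictionary."""
    try:
        return _ELEMENT_FALLBACK[element.upper()]
    except KeyError:
        raise ParameterError(f"no parameters for element {element!r}") from None


def classify_polarity(
    residue_name: str,
    atom_name: str,
    ph_mode: str = "neutral",
    dictionary: ParameterDictionary | None = None,
    element: str | None = None,
) -> str:
    """Polarity class of one atom under the neutral-pH partitioning.

    Falls back to a per-element assignment when the (residue, atom) pair
    is not in the dictionary and ``element`` is given.
    """
    if ph_mode != "neutral":
        raise ParameterError(f"unsupported pH mode {ph_mode!r}")
    d = dictionary if dictionary is not None else default_dictionary()
    entry = d.lookup(residue_name, atom_name)
    if entry is not None:
        return entry.polarity_class
    if element is not None:
        return element_fallback_entry(element).polarity_class
    raise ParameterError(
        f"unknown atom {residue_name} {atom_name} and no element fallback given"
    )


# sp2 carbons of the standard residues, by PDB v3 atom name; the backbone
# carbonyl carbon "C" is sp2 in every residue.
_SP2_CARBONS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"CG"}),
    "GLU": frozenset({"CD"}),
    "ASN": frozenset({"CG"}),
    "GLN": frozenset({"CD"}),
    "ARG": frozenset({"CZ"}),
    "HIS": frozenset({"CG", "CD2", "CE1"}),
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
}

_HETERO_ELEMENTS = frozenset({"N", "O", "S"})

HYDROGEN_POLICIES = ("semi_essential", "all", "none")


def _is_sp2_carbon(atom: HydropathicAtom, n_neighbors: int) -> bool:
    if atom.atom_name == "C":
        return True
    if atom.atom_name in _SP2_CARBONS.get(atom.residue_name, frozenset()):
        return True
    # fallback for non-template residues: a carbon with three bonded
    # partners (counting hydrogens) is planar
    return n_neighbors == 3


def apply_hydrogen_policy(
    atoms: list[HydropathicAtom],
    bonds: Iterable[tuple[int, int]],
    policy: str = "semi_essential",
) -> list[HydropathicAtom]:
    """Mark which hydrogens take part in scoring.

    ``semi_essential`` keeps the hydrogens that carry hydropathic
    information: those bonded to N/O/S (polar), those on sp2 carbons
    (unsaturated), and those on carbons directly bonded to a N/O/S
    heteroatom (alpha to heteroatom).  Apolar sp3 hydrogens are dropped.
    ``all`` keeps every hydrogen, ``none`` keeps only heavy atoms.
    Returns a new list; heavy atoms are never modified.
    """
    if policy not in HYDROGEN_POLICIES:
        raise ParameterError(f"unknown hydrogen policy {policy!r}")
    adjacency: dict[int, list[int]] = {}
    for i, j in bonds:
        adjacency.setdefault(i, []).append(j)
        adjacency.setdefault(j, []).append(i)

    out: list[HydropathicAtom] = []
    for atom in atoms:
        if not atom.is_hydrogen:
            out.append(replace(atom, retained=True))
            continue
        if policy == "all":
            out.append(replace(atom, retained=True))
            continue
        if policy == "none":
            out.append(replace(atom, retained=False))
            continue
        partners = [atoms[j] for j in adjacency.get(atom.atom_id, []) if not atoms[j].is_hydrogen]
        if not partners:
            raise TopologyError(
                f"hydrogen {atom.atom_name} of {atom.residue_name} "
                f"{atom.residue_number} has no bonded heavy atom"
            )
        heavy = partners[0]
        keep = False
        if heavy.element.upper() in _HETERO_ELEMENTS:
            keep = True
        elif heavy.element.upper() == "C":
            n_nb = len(adjacency.get(heavy.atom_id, []))
            if _is_sp2_carbon(heavy, n_nb):
                keep = True
            else:
                for k in adjacency.get(heavy.atom_id, []):
                    if atoms[k].element.upper() in _HETERO_ELEMENTS:
                        keep = True
                        break
        out.append(replace(atom, retained=keep))
    return out
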