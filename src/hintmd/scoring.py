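"""The intramolecular hydropathic interaction score.

The total score of a conformation is a sum over unique non-excluded
atom pairs

    B = Σ_i Σ_{j>i} b_ij,      b_ij = S_i a_i S_j a_j T_ij R(d_ij)

where ``a`` is the hydrophobic atom constant, ``S`` the atom's
solvent-accessible surface area (Å²), ``R`` a monotonically decreasing
distance function (default ``exp(-d)`` with d in Å), and ``T_ij`` a
sign term enforcing the interaction semantics: hydrogen bonds,
acid-base attractions and hydrophobic contacts are favorable
(positive), while acid-acid, base-base and hydrophobic-polar
(desolvation) contacts are unfavorable (negative).  The sign cannot be
carried by the constants alone — two polar atoms both have negative
``a``, so their bare product is positive regardless of whether the pair
attracts or repels — hence ``T_ij`` is applied to the magnitude
``|S_i a_i S_j a_j|``.

Pairs in the 1-2 (bonded) and 1-3 (angle) sets are excluded.  A polar
pair with complementary donor/acceptor roles is a hydrogen bond when
the heavy-atom/heavy-atom distance is at or below 3.65 Å and an
acid-base (electrostatic) interaction above it; hydrogens retained by
the semi-essential policy score as separate atoms, but the
hydrogen-bond distance rule always measures between their parent heavy
atoms.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .params import ACCEPTOR_CLASSES, DONOR_CLASSES
from .sasa import AtomSASA
from .structure import Frame, HintTableRecord, MolecularSystem

__all__ = [
    "ScoreConfig",
    "PairInteraction",
    "FrameScore",
    "INTERACTION_CLASSES",
    "FAVORABLE_CLASSES",
    "get_distance_function",
    "distance_function",
    "sign_logic",
    "hbond_capable",
    "classify_interaction",
    "pair_score",
    "score_frame",
    "to_hint_records",
]

INTERACTION_CLASSES = (
    "hydrophobic",
    "acid_base",
    "acid_acid",
    "base_base",
    "hydrophobic_polar",
    "hydrogen_bond",
)
FAVORABLE_CLASSES = frozenset({"hydrophobic", "acid_base", "hydrogen_bond"})

#: default heavy-atom distance separating hydrogen bonds from plain
#: acid/base interactions, Å
HBOND_THRESHOLD = 3.65


class ScoringError(ValueError):
    pass


def _r_exponential(r: float) -> float:
    return math.exp(-r)


def _r_linear(r: float, r_max: float = 10.0) -> float:
    return max(0.0, 1.0 - r / r_max)


def _r_inverse_square(r: float) -> float:
    return 1.0 / (r * r)


_DISTANCE_FUNCTIONS = {
    "exponential": _r_exponential,
    "linear": _r_linear,
    "inverse_square": _r_inverse_square,
}


def get_distance_function(name: str):
    try:
        return _DISTANCE_FUNCTIONS[name]
    except KeyError:
        raise ScoringError(
            f"unknown distance function {name!r}; "
            f"choose from {sorted(_DISTANCE_FUNCTIONS)}"
        ) from None


def distance_function(r: float, name: str = "exponential") -> float:
    """R(r): positive, strictly decreasing weight of a pair at distance r Å."""
    if r <= 0:
        raise ScoringError(f"distance must be positive, got {r}")
    return get_distance_function(name)(r)


@dataclass
class ScoreConfig:
    """Knobs of the scoring engine (defaults are the recommended settings)."""

    distance_function: str = "exponential"
    cutoff: float | None = 9.0  # Å; None disables spatial truncation
    hbond_threshold: float = HBOND_THRESHOLD  # Å, heavy-atom distance
    include_ligand: bool = True
    sasa_mode: str = "per_frame"  # or "static"
    sasa_probe_radius: float = 1.4
    sasa_n_points: int = 960

    def __post_init__(self) -> None:
        if self.hbond_threshold <= 0:
            raise ScoringError("hbond_threshold must be positive")
        if self.cutoff is not None and self.cutoff <= 0:
            raise ScoringError("cutoff must be positive or None")
        get_distance_function(self.distance_function)


@dataclass
class PairInteraction:
    """One scored atom pair; ``favorable`` mirrors the sign of ``score``."""

    atom_i: int
    atom_j: int
    distance: float
    score: float
    interaction_class: str
    favorable: bool


@dataclass
class FrameScore:
    """Per-frame totals, decomposed by interaction type.

    ``total`` always equals ``hbond_sum + electrostatic_sum +
    hydrophobic_sum + unfavorable_sum``.  ``hbond_salt_bridge_sum`` is
    the portion of ``hbond_sum`` between formally charged (acid/base)
    partners, reported separately so electrostatics may alternatively be
    read as ``electrostatic_sum + hbond_salt_bridge_sum``; it is not an
    extra term of the closure.
    """

    total: float = 0.0
    hbond_sum: float = 0.0
    electrostatic_sum: float = 0.0
    hydrophobic_sum: float = 0.0
    unfavorable_sum: float = 0.0
    hbond_salt_bridge_sum: float = 0.0
    n_pairs_scored: int = 0
    frame_index: int = 0
    time: float = 0.0

    CONTRIBUTIONS = ("hbond", "electrostatic", "hydrophobic", "unfavorable")

    def contribution(self, name: str) -> float:
        return {
            "total": self.total,
            "hbond": self.hbond_sum,
            "electrostatic": self.electrostatic_sum,
            "hydrophobic": self.hydrophobic_sum,
            "unfavorable": self.unfavorable_sum,
        }[name]


def hbond_capable(class_i: str, class_j: str) -> bool:
    """Whether two polarity classes form a donor/acceptor-complementary pair.

    Acids accept, bases donate, polar-neutral atoms (hydroxyls, neutral
    imidazole) do both.
    """
    return (class_i in DONOR_CLASSES and class_j in ACCEPTOR_CLASSES) or (
        class_j in DONOR_CLASSES and class_i in ACCEPTOR_CLASSES
    )


def classify_interaction(
    class_i: str,
    class_j: str,
    heavy_atom_distance: float,
    hbond_threshold: float = HBOND_THRESHOLD,
) -> str:
    """Interaction type of a pair given polarity classes and geometry.

    Donor/acceptor-compatible polar pairs are hydrogen bonds at
    heavy-atom distance <= threshold and acid-base above it; like-charge
    polar pairs are acid-acid or base-base; mixed hydrophobic/polar
    pairs are desolvation contacts.
    """
    i_phobic = class_i == "hydrophobic"
    j_phobic = class_j == "hydrophobic"
    if i_phobic and j_phobic:
        return "hydrophobic"
    if i_phobic or j_phobic:
        return "hydrophobic_polar"
    if hbond_capable(class_i, class_j):
        if heavy_atom_distance <= hbond_threshold:
            return "hydrogen_bond"
        return "acid_base"
    if class_i == "acid" and class_j == "acid":
        return "acid_acid"
    return "base_base"


def sign_logic(class_i: str, class_j: str, is_hbond: bool) -> int:
    """T_ij: +1 for favorable pair types, -1 for unfavorable ones."""
    if is_hbond:
        return +1
    cls = classify_interaction(class_i, class_j, heavy_atom_distance=math.inf)
    return +1 if cls in FAVORABLE_CLASSES else -1


def pair_score(
    i: int,
    j: int,
    frame: Frame,
    sasa: AtomSASA,
    system: MolecularSystem,
    config: ScoreConfig | None = None,
) -> PairInteraction:
    """Score one atom pair: b_ij = T_ij |S_i a_i S_j a_j| R(d_ij)."""
    if config is None:
        config = ScoreConfig()
    if i == j:
        raise ScoringError("cannot score an atom against itself")
    if i > j:
        i, j = j, i
    if system.is_excluded(i, j):
        raise ScoringError(f"pair ({i}, {j}) is in the 1-2/1-3 exclusion sets")
    ai = system.atoms[i]
    aj = system.atoms[j]
    if not (ai.retained and aj.retained):
        raise ScoringError(f"pair ({i}, {j}) involves a non-retained atom")
    rfun = get_distance_function(config.distance_function)
    d = float(np.linalg.norm(frame.coordinates[i] - frame.coordinates[j]))
    parent = system.parent_heavy
    hi, hj = parent[i], parent[j]
    heavy_d = (
        d if (hi == i and hj == j)
        else float(np.linalg.norm(frame.coordinates[hi] - frame.coordinates[hj]))
    )
    cls = classify_interaction(
        ai.polarity_class, aj.polarity_class, heavy_d, config.hbond_threshold
    )
    sign = +1 if cls in FAVORABLE_CLASSES else -1
    magnitude = abs(
        sasa.values[i] * ai.hydrophobic_constant
        * sasa.values[j] * aj.hydrophobic_constant
    ) * rfun(d)
    return PairInteraction(
        atom_i=i,
        atom_j=j,
        distance=d,
        score=sign * magnitude,
        interaction_class=cls,
        favorable=sign > 0,
    )


_BUCKET = {
    "hydrogen_bond": "hbond_sum",
    "acid_base": "electrostatic_sum",
    "hydrophobic": "hydrophobic_sum",
    "acid_acid": "unfavorable_sum",
    "base_base": "unfavorable_sum",
    "hydrophobic_polar": "unfavorable_sum",
}


def score_frame(
    system: MolecularSystem,
    frame: Frame,
    sasa: AtomSASA,
    config: ScoreConfig | None = None,
) -> tuple[FrameScore, list[PairInteraction]]:
    """Score every unique non-excluded retained atom pair of a frame.

    Pairs are enumerated within ``config.cutoff`` (a k-d tree prunes the
    search; ``cutoff=None`` scores all pairs) and accumulated in
    canonical (i, j) order so the floating-point sum is reproducible.
    """
    if config is None:
        config = ScoreConfig()
    if sasa.values.shape[0] != system.n_atoms:
        raise ScoringError(
            f"SASA has {sasa.values.shape[0]} entries for {system.n_atoms} atoms"
        )
    if frame.coordinates.shape[0] != system.n_atoms:
        raise ScoringError("frame/system atom count mismatch")

    retained = np.flatnonzero(system.retained_mask)
    coords = frame.coordinates
    if config.cutoff is None or not np.isfinite(config.cutoff):
        candidate_pairs = itertools.combinations(retained.tolist(), 2)
    else:
        from scipy.spatial import cKDTree

        tree = cKDTree(coords[retained])
        local = tree.query_pairs(config.cutoff, output_type="ndarray")
        mapped = retained[local]
        mapped.sort(axis=1)
        order = np.lexsort((mapped[:, 1], mapped[:, 0]))
        candidate_pairs = (tuple(p) for p in mapped[order])

    rfun = get_distance_function(config.distance_function)
    parent = system.parent_heavy
    atoms = system.atoms
    sv = sasa.values
    score = FrameScore(frame_index=frame.frame_index, time=frame.time)
    pairs: list[PairInteraction] = []
    for i, j in candidate_pairs:
        if system.is_excluded(i, j):
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d == 0.0:
            raise ScoringError(f"atoms {i} and {j} are coincident")
        ai, aj = atoms[i], atoms[j]
        hi, hj = parent[i], parent[j]
        heavy_d = (
            d if (hi == i and hj == j)
            else float(np.linalg.norm(coords[hi] - coords[hj]))
        )
        cls = classify_interaction(
            ai.polarity_class, aj.polarity_class, heavy_d, config.hbond_threshold
        )
        sign = +1 if cls in FAVORABLE_CLASSES else -1
        b = sign * abs(
            sv[i] * ai.hydrophobic_constant * sv[j] * aj.hydrophobic_constant
        ) * rfun(d)
        pairs.append(
            PairInteraction(
                atom_i=int(i), atom_j=int(j), distance=d, score=b,
                interaction_class=cls, favorable=sign > 0,
            )
        )
        bucket = _BUCKET[cls]
        setattr(score, bucket, getattr(score, bucket) + b)
        if cls == "hydrogen_bond" and {ai.polarity_class, aj.polarity_class} <= {"acid", "base"}:
            score.hbond_salt_bridge_sum += b
        score.n_pairs_scored += 1
    score.total = (
        score.hbond_sum + score.electrostatic_sum
        + score.hydrophobic_sum + score.unfavorable_sum
    )
    return score, pairs


def to_hint_records(
    system: MolecularSystem,
    sasa: AtomSASA,
    pairs: list[PairInteraction],
) -> list[HintTableRecord]:
    """Expand scored pairs into HintTable rows."""
    records = []
    for p in pairs:
        ai = system.atoms[p.atom_i]
        aj = system.atoms[p.atom_j]
        records.append(
            HintTableRecord(
                name_i=ai.atom_name, residue_i=ai.residue_name,
                number_i=ai.residue_number, chain_i=ai.chain_id,
                name_j=aj.atom_name, residue_j=aj.residue_name,
                number_j=aj.residue_number, chain_j=aj.chain_id,
                a_i=ai.hydrophobic_constant, s_i=float(sasa.values[p.atom_i]),
                a_j=aj.hydrophobic_constant, s_j=float(sasa.values[p.atom_j]),
                distance=p.distance, b_ij=p.score,
                interaction_class=p.interaction_class,
            )
        )
    return records
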