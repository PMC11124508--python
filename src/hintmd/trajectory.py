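"""Trajectory-level analysis: score time series, RMSD/RMSF, extreme
frames, and residue-pair interaction maps.

The scoring engine is applied frame by frame to give a time series of
totals and per-type contributions, summarized as mean +/- sample
standard deviation per run.  Flexibility is profiled with standard
least-squares (Kabsch) superposition: RMSD against a reference frame
and per-residue RMSF about the iterated mean structure.  Atom-pair
scores aggregate to residue-pair interaction maps whose difference
between two ensembles localizes where the interaction networks of two
conformational states diverge.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sasa import AtomSASA, compute_sasa
from .scoring import FrameScore, ScoreConfig, score_frame
from .structure import Frame, MolecularSystem, Trajectory

__all__ = [
    "EnsembleSeries",
    "RMSFProfile",
    "ResiduePairMap",
    "AnalysisError",
    "score_trajectory",
    "superpose",
    "compute_rmsd",
    "compute_rmsf",
    "extract_extreme_frames",
    "residue_pair_map",
    "ensemble_difference",
    "resolve_selection",
]

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

_SERIES_COLUMNS = ["frame", "time", "total", "hbond", "electrostatic",
                   "hydrophobic", "unfavorable", "n_pairs"]


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# score series


@dataclass
class EnsembleSeries:
    """Ordered per-frame scores of one trajectory plus summary statistics."""

    frame_scores: list[FrameScore]
    run_label: str = ""

    def __post_init__(self) -> None:
        if not self.frame_scores:
            raise AnalysisError("an ensemble needs at least one frame score")

    def values(self, contribution: str = "total") -> np.ndarray:
        return np.array(
            [fs.contribution(contribution) for fs in self.frame_scores]
        )

    def mean(self, contribution: str = "total") -> float:
        return float(self.values(contribution).mean())

    def std(self, contribution: str = "total") -> float:
        v = self.values(contribution)
        return float(v.std(ddof=1)) if v.size > 1 else 0.0

    def summary(self) -> pd.DataFrame:
        rows = [
            {"contribution": c, "mean": self.mean(c), "std": self.std(c)}
            for c in ("total", "hbond", "electrostatic", "hydrophobic", "unfavorable")
        ]
        return pd.DataFrame(rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "frame": fs.frame_index,
                    "time": fs.time,
                    "total": fs.total,
                    "hbond": fs.hbond_sum,
                    "electrostatic": fs.electrostatic_sum,
                    "hydrophobic": fs.hydrophobic_sum,
                    "unfavorable": fs.unfavorable_sum,
                    "n_pairs": fs.n_pairs_scored,
                }
                for fs in self.frame_scores
            ],
            columns=_SERIES_COLUMNS,
        )

    def write(self, path: str | Path) -> None:
        """Per-frame TSV with fixed formatting (byte-stable across runs)."""
        lines = ["\t".join(_SERIES_COLUMNS)]
        for fs in self.frame_scores:
            lines.append(
                f"{fs.frame_index}\t{fs.time:.6g}\t{fs.total:.10g}\t"
                f"{fs.hbond_sum:.10g}\t{fs.electrostatic_sum:.10g}\t"
                f"{fs.hydrophobic_sum:.10g}\t{fs.unfavorable_sum:.10g}\t"
                f"{fs.n_pairs_scored}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def score_trajectory(
    trajectory: Trajectory,
    config: ScoreConfig | None = None,
    run_label: str = "",
) -> EnsembleSeries:
    """Apply the scoring engine to every frame of a trajectory.

    With ``config.sasa_mode == "static"`` the first frame's SASA is
    reused for all frames (an approximation that ignores burial changes
    along the trajectory); the default recomputes SASA per frame.
    """
    if config is None:
        config = ScoreConfig()
    if trajectory.n_frames == 0:
        raise AnalysisError("empty trajectory")
    system = trajectory.system
    static_sasa: AtomSASA | None = None
    if config.sasa_mode == "static":
        static_sasa = compute_sasa(
            system, trajectory.frames[0],
            probe_radius=config.sasa_probe_radius, n_points=config.sasa_n_points,
        )
    scores = []
    for frame in trajectory.frames:
        sasa = static_sasa if static_sasa is not None else compute_sasa(
            system, frame,
            probe_radius=config.sasa_probe_radius, n_points=config.sasa_n_points,
        )
        fs, _ = score_frame(system, frame, sasa, config)
        scores.append(fs)
    return EnsembleSeries(frame_scores=scores, run_label=run_label)


def extract_extreme_frames(series: EnsembleSeries, k: int = 1) -> list[int]:
    """Indices of the k frames with the highest total score, descending.

    The highest-score frames are the lowest-energy conformations; ties
    are broken toward the earlier frame.
    """
    n = len(series.frame_scores)
    if not 1 <= k <= n:
        raise AnalysisError(f"k must be in [1, {n}], got {k}")
    totals = series.values("total")
    order = sorted(range(n), key=lambda i: (-totals[i], i))
    return [series.frame_scores[i].frame_index for i in order[:k]]


# ---------------------------------------------------------------------------
# superposition, RMSD, RMSF


def resolve_selection(system: MolecularSystem, selection) -> np.ndarray:
    """Turn a selection spec into sorted atom indices.

    Accepts ``"all"``, ``"backbone"`` (N/CA/C/O), ``"CA"``, ``"heavy"``,
    a boolean mask, or an index array.
    """
    if isinstance(selection, str):
        if selection == "all":
            idx = np.arange(system.n_atoms)
        elif selection == "backbone":
            idx = np.array(
                [a.atom_id for a in system.atoms if a.atom_name in BACKBONE_NAMES]
            )
        elif selection == "CA":
            idx = np.array([a.atom_id for a in system.atoms if a.atom_name == "CA"])
        elif selection == "heavy":
            idx = np.array([a.atom_id for a in system.atoms if not a.is_hydrogen])
        else:
            raise AnalysisError(f"unknown selection {selection!r}")
    else:
        arr = np.asarray(selection)
        idx = np.flatnonzero(arr) if arr.dtype == bool else arr.astype(int)
    if idx.size == 0:
        raise AnalysisError("empty atom selection")
    return np.sort(idx)


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation/translation of ``mobile`` onto ``reference``.

    Returns (rotation matrix, mobile centroid, reference centroid);
    proper rotation enforced via the determinant sign correction.
    """
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return rot, cm, cr


def superpose(
    coords: np.ndarray, reference: np.ndarray, fit_indices: np.ndarray
) -> np.ndarray:
    """Least-squares superpose full coordinates onto a reference using
    the fit atoms; returns transformed copies of all atoms."""
    rot, cm, cr = _kabsch(coords[fit_indices], reference[fit_indices])
    return (coords - cm) @ rot.T + cr


def compute_rmsd(
    trajectory: Trajectory,
    reference: Frame,
    selection="backbone",
) -> np.ndarray:
    """Per-frame RMSD (Å) over the selection after optimal superposition."""
    idx = resolve_selection(trajectory.system, selection)
    ref = reference.coordinates
    out = np.empty(trajectory.n_frames)
    for k, frame in enumerate(trajectory.frames):
        moved = superpose(frame.coordinates, ref, idx)
        delta = moved[idx] - ref[idx]
        out[k] = np.sqrt((delta ** 2).sum(axis=1).mean())
    return out


@dataclass
class RMSFProfile:
    """Per-residue RMSF (Å) keyed by (chain, residue number)."""

    values: dict[tuple[str, int], float]
    superposition_selection: str = "backbone"
    averaging: str = "backbone"

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"chain": c, "resnum": n, "rmsf": v}
            for (c, n), v in sorted(self.values.items())
        ]
        return pd.DataFrame(rows, columns=["chain", "resnum", "rmsf"])

    def write(self, path: str | Path) -> None:
        lines = ["chain\tresnum\trmsf"]
        for (c, n), v in sorted(self.values.items()):
            lines.append(f"{c}\t{n}\t{v:.6g}")
        Path(path).write_text("\n".join(lines) + "\n")

    def region(self, start: int, stop: int, chain: str | None = None) -> dict:
        """min/max/mean RMSF over residues start..stop (inclusive)."""
        vals = [
            v for (c, n), v in self.values.items()
            if start <= n <= stop and (chain is None or c == chain)
        ]
        if not vals:
            raise AnalysisError(f"no residues in region {start}-{stop}")
        return {"min": min(vals), "max": max(vals), "mean": float(np.mean(vals))}


_AVERAGING_SELECTIONS = {"backbone": "backbone", "CA": "CA", "heavy": "heavy"}


def compute_rmsf(
    trajectory: Trajectory,
    averaging: str = "backbone",
    superpose_selection="backbone",
    n_mean_passes: int = 2,
) -> RMSFProfile:
    """Per-residue RMSF about the iterated mean structure.

    Frames are superposed onto the running mean structure over
    ``superpose_selection`` (``None`` skips superposition entirely, for
    pre-aligned trajectories); the mean is re-estimated ``n_mean_passes``
    times.  Atomic fluctuations sqrt(<|x - <x>|^2>) are then averaged
    within each residue over the ``averaging`` atom set.
    """
    if trajectory.n_frames < 2:
        raise AnalysisError("RMSF needs at least two frames")
    if averaging not in _AVERAGING_SELECTIONS:
        raise AnalysisError(f"unknown averaging mode {averaging!r}")
    system = trajectory.system
    stack = np.stack([f.coordinates for f in trajectory.frames])

    if superpose_selection is not None:
        fit_idx = resolve_selection(system, superpose_selection)
        reference = stack[0]
        for _ in range(n_mean_passes):
            aligned = np.stack(
                [superpose(c, reference, fit_idx) for c in stack]
            )
            reference = aligned.mean(axis=0)
        stack = aligned

    mean_coords = stack.mean(axis=0)
    per_atom = np.sqrt(((stack - mean_coords) ** 2).sum(axis=2).mean(axis=0))

    avg_idx = resolve_selection(system, _AVERAGING_SELECTIONS[averaging])
    per_residue: dict[tuple[str, int], list[float]] = {}
    for i in avg_idx:
        a = system.atoms[int(i)]
        per_residue.setdefault((a.chain_id, a.residue_number), []).append(
            float(per_atom[i])
        )
    values = {key: float(np.mean(v)) for key, v in per_residue.items()}
    sel_name = superpose_selection if isinstance(superpose_selection, str) else (
        "none" if superpose_selection is None else "custom"
    )
    return RMSFProfile(values=values, superposition_selection=sel_name,
                       averaging=averaging)


# ---------------------------------------------------------------------------
# residue-pair interaction maps


@dataclass
class ResiduePairMap:
    """Residue-pair interaction scores averaged over a set of frames.

    ``cells`` maps (residue_key_i, residue_key_j, interaction_class) to
    the frame-averaged summed pair score, with residue keys
    ``(chain, residue number)`` and key_i < key_j canonical.  Pairs of
    atoms within one residue are not mapped (the matrix describes
    inter-residue structure) but their mean total is kept in
    ``intra_residue_total`` so the map still accounts for the full frame
    score.
    """

    cells: dict[tuple[tuple[str, int], tuple[str, int], str], float]
    n_frames: int
    intra_residue_total: float = 0.0
    run_label: str = ""

    def get(self, res_a, res_b, interaction_class: str) -> float:
        if res_a == res_b:
            raise AnalysisError("residue self-pairs are not mapped")
        key = (min(res_a, res_b), max(res_a, res_b), interaction_class)
        return self.cells.get(key, 0.0)

    def total(self) -> float:
        """Sum of every cell plus the intra-residue remainder."""
        return float(sum(self.cells.values())) + self.intra_residue_total

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "chain_i": ka[0], "res_i": ka[1],
                "chain_j": kb[0], "res_j": kb[1],
                "interaction_class": cls, "mean_score": v,
            }
            for (ka, kb, cls), v in sorted(self.cells.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["chain_i", "res_i", "chain_j", "res_j",
                     "interaction_class", "mean_score"],
        )

    def write(self, path: str | Path) -> None:
        lines = ["chain_i\tres_i\tchain_j\tres_j\tinteraction_class\tmean_score"]
        for (ka, kb, cls), v in sorted(self.cells.items()):
            lines.append(f"{ka[0]}\t{ka[1]}\t{kb[0]}\t{kb[1]}\t{cls}\t{v:.10g}")
        Path(path).write_text("\n".join(lines) + "\n")

    def top_pairs(self, k: int = 10) -> list[tuple]:
        """Residue pairs ranked by summed |score| over all classes."""
        by_pair: dict[tuple, float] = {}
        signed: dict[tuple, float] = {}
        for (ka, kb, _cls), v in self.cells.items():
            by_pair[(ka, kb)] = by_pair.get((ka, kb), 0.0) + abs(v)
            signed[(ka, kb)] = signed.get((ka, kb), 0.0) + v
        ranked = sorted(by_pair, key=lambda p: (-by_pair[p], p))
        return [(ka, kb, signed[(ka, kb)]) for ka, kb in ranked[:k]]


def residue_pair_map(
    trajectory: Trajectory,
    config: ScoreConfig | None = None,
    frame_subset: Sequence[int] | None = None,
    run_label: str = "",
) -> ResiduePairMap:
    """Aggregate atom-pair scores to residue pairs, per interaction class,
    averaged over the chosen frames (all frames by default)."""
    if config is None:
        config = ScoreConfig()
    if frame_subset is None:
        frame_subset = range(trajectory.n_frames)
    frame_subset = list(frame_subset)
    if not frame_subset:
        raise AnalysisError("empty frame subset")
    system = trajectory.system
    acc: dict[tuple, float] = {}
    intra = 0.0
    for fi in frame_subset:
        frame = trajectory.frames[fi]
        sasa = compute_sasa(
            system, frame,
            probe_radius=config.sasa_probe_radius, n_points=config.sasa_n_points,
        )
        _, pairs = score_frame(system, frame, sasa, config)
        for p in pairs:
            ai = system.atoms[p.atom_i]
            aj = system.atoms[p.atom_j]
            ka = (ai.chain_id, ai.residue_number)
            kb = (aj.chain_id, aj.residue_number)
            if ka == kb:
                intra += p.score
                continue
            key = (min(ka, kb), max(ka, kb), p.interaction_class)
            acc[key] = acc.get(key, 0.0) + p.score
    n = len(frame_subset)
    return ResiduePairMap(
        cells={k: v / n for k, v in acc.items()},
        n_frames=n,
        intra_residue_total=intra / n,
        run_label=run_label,
    )


def ensemble_difference(map_a: ResiduePairMap, map_b: ResiduePairMap) -> ResiduePairMap:
    """Cellwise map_a - map_b (outer join, missing cells treated as zero)."""
    keys = set(map_a.cells) | set(map_b.cells)
    delta = {
        k: map_a.cells.get(k, 0.0) - map_b.cells.get(k, 0.0) for k in keys
    }
    return ResiduePairMap(
        cells=delta,
        n_frames=max(map_a.n_frames, map_b.n_frames),
        intra_residue_total=map_a.intra_residue_total - map_b.intra_residue_total,
        run_label=f"{map_a.run_label or 'A'} - {map_b.run_label or 'B'}",
    )
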