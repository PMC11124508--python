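"""Trajectory analytics: score series, RMSD/RMSF, extremes, residue maps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hintmd.fixtures import (
    FixtureSpec,
    make_contact_pair,
    make_hinge_trajectory,
    make_peptide,
    make_translated_trajectory,
)
from hintmd.sasa import compute_sasa
from hintmd.scoring import FrameScore, ScoreConfig, score_frame
from hintmd.structure import Frame, Trajectory
from hintmd.trajectory import (
    AnalysisError,
    EnsembleSeries,
    compute_rmsd,
    compute_rmsf,
    ensemble_difference,
    extract_extreme_frames,
    residue_pair_map,
    score_trajectory,
)

from conftest import build_toy_system


def identical_frame_trajectory(n_frames=3):
    system, frame = make_contact_pair("ASP", "LYS", 2.9)
    frames = [
        Frame(coordinates=frame.coordinates.copy(), frame_index=t, time=float(t))
        for t in range(n_frames)
    ]
    return Trajectory(system=system, frames=frames, time_step=1.0)


class TestScoreTrajectory:
    def test_constant_series_has_zero_sd(self):
        traj = identical_frame_trajectory(3)
        series = score_trajectory(traj)
        totals = series.values("total")
        assert np.all(totals == totals[0])
        assert series.std("total") == 0.0

    def test_mean_is_mean_of_frame_totals(self):
        traj, _ = make_hinge_trajectory(
            FixtureSpec(n_frames=4, jitter_sigma=0.2, seed=11)
        )
        series = score_trajectory(traj)
        assert series.mean("total") == pytest.approx(
            float(np.mean([fs.total for fs in series.frame_scores]))
        )

    def test_frames_match_single_frame_scoring(self):
        traj, _ = make_hinge_trajectory(
            FixtureSpec(n_frames=4, jitter_sigma=0.1, seed=3)
        )
        config = ScoreConfig()
        series = score_trajectory(traj, config)
        for fs, frame in zip(series.frame_scores, traj.frames):
            sasa = compute_sasa(traj.system, frame)
            single, _ = score_frame(traj.system, frame, sasa, config)
            assert fs.total == single.total
            assert fs.hbond_sum == single.hbond_sum

    def test_contribution_closure_propagates_to_means(self):
        traj, _ = make_hinge_trajectory(
            FixtureSpec(n_frames=6, jitter_sigma=0.15, seed=9)
        )
        series = score_trajectory(traj)
        assert series.mean("total") == pytest.approx(
            series.mean("hbond") + series.mean("electrostatic")
            + series.mean("hydrophobic") + series.mean("unfavorable"),
            rel=1e-9,
        )

    def test_static_sasa_mode_runs(self):
        traj = identical_frame_trajectory(2)
        series = score_trajectory(traj, ScoreConfig(sasa_mode="static"))
        assert len(series.frame_scores) == 2

    def test_empty_series_rejected(self):
        with pytest.raises(AnalysisError):
            EnsembleSeries(frame_scores=[])


class TestRMSD:
    def test_identical_frame_is_zero(self):
        traj = identical_frame_trajectory(2)
        rmsd = compute_rmsd(traj, traj.frames[0], selection="heavy")
        np.testing.assert_allclose(rmsd, 0.0, atol=1e-9)

    def test_translation_removed_by_superposition(self):
        system, frame = make_peptide(("ALA", "SER"))
        traj = make_translated_trajectory(system, frame, 4, step=(5.0, 0.0, 0.0))
        rmsd = compute_rmsd(traj, traj.frames[0], selection="heavy")
        np.testing.assert_allclose(rmsd, 0.0, atol=1e-9)

    def test_matches_independent_kabsch_oracle(self):
        import MDAnalysis.analysis.rms as mda_rms

        rng = np.random.default_rng(42)
        system, frame = make_peptide(("ALA", "LEU", "SER"))
        distorted = Frame(
            coordinates=frame.coordinates + rng.normal(0, 0.8, frame.coordinates.shape),
            frame_index=1, time=1.0,
        )
        traj = Trajectory(system=system, frames=[frame, distorted], time_step=1.0)
        ours = compute_rmsd(traj, frame, selection="all")
        oracle = mda_rms.rmsd(
            distorted.coordinates, frame.coordinates,
            center=True, superposition=True,
        )
        assert ours[1] == pytest.approx(oracle, abs=1e-6)

    def test_empty_selection_rejected(self):
        traj = identical_frame_trajectory(2)
        with pytest.raises(AnalysisError):
            compute_rmsd(traj, traj.frames[0], selection=np.array([], dtype=int))


class TestRMSF:
    def test_static_trajectory_all_zero(self):
        traj = identical_frame_trajectory(3)
        profile = compute_rmsf(traj)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in profile.values.values())

    def test_single_frame_rejected(self):
        traj = identical_frame_trajectory(1)
        with pytest.raises(AnalysisError):
            compute_rmsf(traj)

    def test_single_atom_alternation_closed_form(self):
        # one CA alternates +/- d along z about the mean: its residue's
        # CA-averaged RMSF is exactly d
        system, base = make_peptide(("ALA", "GLY"))
        d = 1.7
        ca = next(a.atom_id for a in system.atoms
                  if a.atom_name == "CA" and a.residue_number == 2)
        frames = []
        for t in range(6):
            coords = base.coordinates.copy()
            coords[ca, 2] += d if t % 2 == 0 else -d
            frames.append(Frame(coordinates=coords, frame_index=t, time=float(t)))
        traj = Trajectory(system=system, frames=frames, time_step=1.0)
        profile = compute_rmsf(traj, averaging="CA", superpose_selection=None)
        assert profile.values[("A", 2)] == pytest.approx(d, abs=1e-12)
        assert profile.values[("A", 1)] == pytest.approx(0.0, abs=1e-12)

    def test_hinge_mobile_exceeds_rigid(self):
        for seed in (0, 1, 2):
            traj, manifest = make_hinge_trajectory(
                FixtureSpec(n_frames=10, jitter_sigma=0.3, seed=seed)
            )
            rigid_atoms = np.array(
                [a.atom_id for a in traj.system.atoms
                 if a.residue_number in manifest["rigid_residues"]]
            )
            profile = compute_rmsf(traj, superpose_selection=rigid_atoms)
            mobile = [profile.values[("A", r)] for r in manifest["mobile_residues"]]
            rigid = [profile.values[("A", r)] for r in manifest["rigid_residues"]]
            assert min(mobile) > max(rigid)

    def test_rigid_motion_invariance(self):
        traj, manifest = make_hinge_trajectory(
            FixtureSpec(n_frames=6, jitter_sigma=0.2, seed=5)
        )
        profile = compute_rmsf(traj)
        theta = 0.6
        rot = np.array(
            [
                [1, 0, 0],
                [0, math.cos(theta), -math.sin(theta)],
                [0, math.sin(theta), math.cos(theta)],
            ]
        )
        moved = Trajectory(
            system=traj.system,
            frames=[
                Frame(coordinates=f.coordinates @ rot.T + np.array([3.0, -8.0, 1.0]),
                      frame_index=f.frame_index, time=f.time)
                for f in traj.frames
            ],
            time_step=traj.time_step,
        )
        profile2 = compute_rmsf(moved)
        for key in profile.values:
            assert profile2.values[key] == pytest.approx(
                profile.values[key], abs=1e-9
            )

    def test_region_report(self):
        traj, manifest = make_hinge_trajectory(FixtureSpec(n_frames=4, seed=1))
        rigid_atoms = np.array(
            [a.atom_id for a in traj.system.atoms
             if a.residue_number in manifest["rigid_residues"]]
        )
        profile = compute_rmsf(traj, superpose_selection=rigid_atoms)
        lo, hi = manifest["mobile_residues"][0], manifest["mobile_residues"][-1]
        stats = profile.region(lo, hi)
        assert stats["mean"] == pytest.approx(3.0, abs=1e-9)
        with pytest.raises(AnalysisError):
            profile.region(900, 999)


class TestExtractExtremeFrames:
    def series_from_totals(self, totals):
        return EnsembleSeries(
            frame_scores=[
                FrameScore(total=t, frame_index=i, time=float(i))
                for i, t in enumerate(totals)
            ]
        )

    def test_strictly_increasing_k1_is_last(self):
        series = self.series_from_totals([1.0, 2.0, 3.0, 4.0])
        assert extract_extreme_frames(series, 1) == [3]

    def test_ties_prefer_earlier_frames(self):
        series = self.series_from_totals([5.0, 5.0, 5.0])
        assert extract_extreme_frames(series, 2) == [0, 1]

    def test_k_out_of_range_rejected(self):
        series = self.series_from_totals([1.0, 2.0])
        with pytest.raises(AnalysisError):
            extract_extreme_frames(series, 3)
        with pytest.raises(AnalysisError):
            extract_extreme_frames(series, 0)

    @settings(max_examples=50, deadline=None)
    @given(
        totals=st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=30
        ),
        data=st.data(),
    )
    def test_matches_full_sort_oracle(self, totals, data):
        k = data.draw(st.integers(1, len(totals)))
        series = self.series_from_totals(totals)
        got = extract_extreme_frames(series, k)
        oracle = [
            i for _, i in sorted(
                ((-t, i) for i, t in enumerate(totals))
            )
        ][:k]
        assert got == oracle


class TestResiduePairMap:
    def test_single_frame_conservation(self):
        traj = identical_frame_trajectory(1)
        config = ScoreConfig()
        rpm = residue_pair_map(traj, config)
        sasa = compute_sasa(traj.system, traj.frames[0])
        fs, _ = score_frame(traj.system, traj.frames[0], sasa, config)
        assert rpm.total() == pytest.approx(fs.total, rel=1e-9)

    def test_symmetric_lookup(self):
        traj = identical_frame_trajectory(1)
        rpm = residue_pair_map(traj)
        r1, r2 = ("A", 1), ("A", 2)
        for cls in ("hydrogen_bond", "hydrophobic_polar"):
            assert rpm.get(r1, r2, cls) == rpm.get(r2, r1, cls)

    def test_self_pairs_not_mapped(self):
        traj = identical_frame_trajectory(1)
        rpm = residue_pair_map(traj)
        assert all(ka != kb for ka, kb, _ in rpm.cells)
        with pytest.raises(AnalysisError):
            rpm.get(("A", 1), ("A", 1), "hydrophobic")

    def test_empty_frame_subset_rejected(self):
        traj = identical_frame_trajectory(2)
        with pytest.raises(AnalysisError):
            residue_pair_map(traj, frame_subset=[])

    def test_average_over_frames(self):
        traj = identical_frame_trajectory(3)
        one = residue_pair_map(traj, frame_subset=[0])
        all_frames = residue_pair_map(traj)
        for key, value in one.cells.items():
            assert all_frames.cells[key] == pytest.approx(value, rel=1e-12)


class TestEnsembleDifference:
    def test_map_minus_itself_is_zero(self):
        traj = identical_frame_trajectory(2)
        rpm = residue_pair_map(traj)
        delta = ensemble_difference(rpm, rpm)
        assert all(v == 0.0 for v in delta.cells.values())

    def test_antisymmetric_under_swap(self):
        traj_a = identical_frame_trajectory(1)
        system_b, frame_b = make_contact_pair("ASP", "LYS", 4.5)
        traj_b = Trajectory(system=system_b, frames=[frame_b], time_step=1.0)
        a = residue_pair_map(traj_a)
        b = residue_pair_map(traj_b)
        d1 = ensemble_difference(a, b)
        d2 = ensemble_difference(b, a)
        for key, value in d1.cells.items():
            assert d2.cells[key] == pytest.approx(-value, rel=1e-12)

    def test_engineered_contact_is_top_delta(self):
        # ensembles share a 3-residue universe; in A, residue 3 is pulled
        # next to residue 1, creating the only differing contact
        system, frame = make_peptide(("ALA", "ALA", "ALA"), spacing=8.0)
        res3 = np.array([a.residue_number == 3 for a in system.atoms])
        coords_a = frame.coordinates.copy()
        coords_a[res3] += np.array([-16.0, 6.0, 0.0])  # res3 now ~6 Å from res1
        frame_a = Frame(coordinates=coords_a)
        traj_a = Trajectory(system=system, frames=[frame_a], time_step=1.0)
        traj_b = Trajectory(system=system, frames=[frame], time_step=1.0)
        delta = ensemble_difference(
            residue_pair_map(traj_a), residue_pair_map(traj_b)
        )
        top = delta.top_pairs(1)[0]
        assert {top[0], top[1]} == {("A", 1), ("A", 3)}
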