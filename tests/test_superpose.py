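"""Kabsch fitting and the RMSD/RMSF metric family."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from trajcomm.io import FrameSeries, Selection, select
from trajcomm.superpose import (
    FitError,
    WindowError,
    kabsch_fit,
    rmsd_series,
    rmsf_profile,
    subrange_rmsd,
    superpose_series,
)
from trajcomm.synth import EnsembleSpec, TwoStateSpec, sample_correlated_ensemble, sample_two_state


class TestKabschFit:
    def test_identical_sets_give_zero(self, rng):
        pts = rng.normal(size=(10, 3))
        res = kabsch_fit(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-8)

    def test_rigid_transform_recovered(self, rng):
        pts = rng.normal(size=(12, 3))
        rot = Rotation.random(random_state=rng).as_matrix()
        moved = pts @ rot.T + np.array([5.0, -3.0, 2.0])
        res = kabsch_fit(moved, pts)
        assert res.rmsd <= 1e-8
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_single_displaced_point_matches_independent_fit(self, rng):
        """One point displaced by d: rmsd ≤ d/√N and equals an independent
        least-squares superposition (scipy align_vectors as oracle)."""
        pts = rng.normal(size=(8, 3))
        moved = pts.copy()
        d = 2.0
        moved[3] += [0, 0, d]
        res = kabsch_fit(moved, pts)
        assert res.rmsd <= d / np.sqrt(8) + 1e-9
        _, oracle_rssd = Rotation.align_vectors(
            pts - pts.mean(0), moved - moved.mean(0)
        )
        assert res.rmsd == pytest.approx(oracle_rssd / np.sqrt(8), abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_geometry_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(FitError):
            kabsch_fit(line, line)

    def test_rotation_is_proper(self, rng):
        # mirror-image target must still produce det +1
        pts = rng.normal(size=(6, 3))
        mirrored = pts * np.array([1, 1, -1])
        res = kabsch_fit(pts, mirrored)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)


class TestRmsdSeries:
    def _static(self, rng, n_frames=5, n_atoms=9):
        coords = np.repeat(rng.normal(size=(1, n_atoms, 3)), n_frames, axis=0)
        return FrameSeries(coords)

    def test_static_trajectory_is_zero(self, rng):
        series = self._static(rng)
        sel = Selection(tuple(range(series.n_atoms)))
        vals = rmsd_series(series, series.coords[0], sel)
        np.testing.assert_allclose(vals, 0.0, atol=1e-10)

    def test_rigidly_rotated_frames_are_zero_after_fit(self, rng):
        base = rng.normal(size=(10, 3))
        frames = []
        for _ in range(6):
            rot = Rotation.random(random_state=rng).as_matrix()
            frames.append(base @ rot.T + rng.uniform(-5, 5, 3))
        series = FrameSeries(np.array(frames))
        sel = Selection(tuple(range(10)))
        vals = rmsd_series(series, base, sel)
        np.testing.assert_allclose(vals, 0.0, atol=1e-8)

    def test_two_state_closed_form(self, rng):
        """Half the measured atoms displaced 3 Å on alternating frames:
        RMSD alternates 0 and 3·√(½)."""
        base = rng.normal(size=(20, 3)) * 10
        displaced = base.copy()
        displaced[12:16] += [0, 0, 3.0]  # 4 of 8 measured atoms
        coords = np.array([base, displaced] * 3)
        series = FrameSeries(coords)
        fit_sel = Selection(tuple(range(8)))  # static anchor
        meas_sel = Selection(tuple(range(8, 16)))
        vals = rmsd_series(series, base, fit_sel, meas_sel)
        expected = np.array([0.0, 3.0 * np.sqrt(0.5)] * 3)
        np.testing.assert_allclose(vals, expected, atol=1e-6)

    def test_rmsd_invariant_to_rigid_transform_of_frame(self, rng):
        base = rng.normal(size=(3, 12, 3))
        series = FrameSeries(base)
        sel = Selection(tuple(range(12)))
        ref = rng.normal(size=(12, 3))
        vals = rmsd_series(series, ref, sel)
        rot = Rotation.random(random_state=rng).as_matrix()
        moved = FrameSeries(base @ rot.T + np.array([1.0, 2.0, 3.0]))
        vals2 = rmsd_series(moved, ref, sel)
        np.testing.assert_allclose(vals, vals2, atol=1e-8)

    def test_frame_msd_identity(self, rng):
        """Mean per-atom squared deviation equals the squared series value."""
        series = FrameSeries(rng.normal(size=(2, 10, 3)))
        sel = Selection(tuple(range(10)))
        ref = rng.normal(size=(10, 3))
        vals = rmsd_series(series, ref, sel)
        fit = kabsch_fit(series.coords[1], ref)
        msd = np.mean(np.sum((fit.apply(series.coords[1]) - ref) ** 2, axis=1))
        assert vals[1] ** 2 == pytest.approx(msd, rel=1e-10)


class TestRmsfProfile:
    def test_static_trajectory_all_zero(self, rng):
        from trajcomm.synth import make_reference

        topology, ref = make_reference(8)
        series = FrameSeries(np.repeat(ref.coords, 6, axis=0))
        sel = select(topology, "name CA")
        prof = rmsf_profile(series, topology, sel, equilibration_cut=0.0)
        assert all(v == pytest.approx(0.0, abs=1e-10) for v in prof.values())

    def test_isotropic_gaussian_matches_sigma_sqrt3(self):
        """Per-coordinate σ = 0.5 Å ⇒ RMSF = σ√3 = 0.866 Å (3-D Gaussian moment)."""
        topology, series = sample_correlated_ensemble(
            EnsembleSpec(n_residues=100, sigma=0.5, n_frames=4000, seed=11)
        )
        sel = select(topology, "name CA")
        prof = rmsf_profile(series, topology, sel, equilibration_cut=0.0)
        mean_rmsf = np.mean(list(prof.values()))
        assert mean_rmsf == pytest.approx(0.5 * np.sqrt(3), rel=0.03)

    def test_planted_hot_residue_is_argmax(self):
        sigma = np.full(30, 0.4)
        sigma[17] = 0.8
        topology, series = sample_correlated_ensemble(
            EnsembleSpec(n_residues=30, sigma=sigma, n_frames=2000, seed=12)
        )
        sel = select(topology, "name CA")
        prof = rmsf_profile(series, topology, sel, equilibration_cut=0.0)
        vals = list(prof.values())
        assert int(np.argmax(vals)) == 17

    def test_self_concatenation_preserves_rmsf(self, rng):
        from trajcomm.synth import make_reference

        topology, ref = make_reference(10)
        coords = ref.coords + rng.normal(scale=0.3, size=(50, topology.n_atoms, 3))
        once = FrameSeries(coords)
        twice = FrameSeries(np.concatenate([coords, coords]))
        sel = select(topology, "name CA")
        p1 = rmsf_profile(once, topology, sel, equilibration_cut=0.0)
        p2 = rmsf_profile(twice, topology, sel, equilibration_cut=0.0)
        np.testing.assert_allclose(list(p1.values()), list(p2.values()), atol=1e-8)

    def test_cut_removing_everything_raises(self, rng):
        from trajcomm.synth import make_reference

        topology, ref = make_reference(5)
        series = FrameSeries(np.repeat(ref.coords, 4, axis=0))
        sel = select(topology, "name CA")
        with pytest.raises(WindowError):
            rmsf_profile(series, topology, sel, equilibration_cut=100.0)

    def test_default_cut_discards_first_half(self, rng):
        from trajcomm.synth import make_reference

        topology, ref = make_reference(6)
        # first half wildly displaced; default cut should ignore it
        quiet = np.repeat(ref.coords, 10, axis=0)
        noisy = quiet + 50.0
        series = FrameSeries(np.concatenate([noisy, quiet]))
        sel = select(topology, "name CA")
        prof = rmsf_profile(series, topology, sel)
        assert all(v == pytest.approx(0.0, abs=1e-8) for v in prof.values())


class TestSubrangeRmsd:
    def test_reference_trajectory_gives_zero(self):
        from trajcomm.synth import make_reference

        topology, ref = make_reference(20)
        series = FrameSeries(np.repeat(ref.coords, 4, axis=0))
        fit = select(topology, "name CA")
        vals, counts, edges = subrange_rmsd(series, topology, ref.coords[0], (1, 20), fit)
        np.testing.assert_allclose(vals, 0.0, atol=1e-10)

    def test_hinge_motion_localizes_to_range(self):
        """Displacing only residues 41–50 by 4.5 Å: range RMSD ≈ 4.5, whole ≪."""
        spec = TwoStateSpec(
            n_residues=60,
            states=[(0.5, 0.0), (0.5, 4.5)],
            displaced_residues=list(range(40, 50)),
            alternating=True,
            noise_sigma=0.0,
            n_frames=10,
            seed=13,
        )
        topology, series, labels = sample_two_state(spec)
        from trajcomm.synth import make_reference

        _, ref = make_reference(60)
        fit = select(topology, "name CA")
        vals, _, _ = subrange_rmsd(series, topology, ref.coords[0], (41, 50), fit)
        whole = rmsd_series(series, ref.coords[0], fit)
        moved = labels == 1
        assert np.allclose(vals[moved], 4.5, atol=0.2)
        assert whole[moved].max() < 0.5 * 4.5

    def test_two_basin_histogram_is_bimodal(self):
        """Basins planted at 2.5 and 4.5 Å from the reference produce a
        bimodal 0.5 Å-bin histogram with modes at those distances."""
        spec = TwoStateSpec(
            n_residues=40,
            states=[(0.5, 2.5), (0.5, 4.5)],
            displaced_residues=list(range(28, 38)),
            alternating=True,
            noise_sigma=0.05,
            n_frames=400,
            seed=14,
        )
        topology, series, labels = sample_two_state(spec)
        from trajcomm.synth import make_reference

        _, ref = make_reference(40)
        fit = select(topology, "name CA")
        vals, counts, edges = subrange_rmsd(series, topology, ref.coords[0], (29, 38), fit)
        # the per-basin means sit at the planted distances
        assert vals[labels == 0].mean() == pytest.approx(2.5, abs=0.15)
        assert vals[labels == 1].mean() == pytest.approx(4.5, abs=0.15)
        # and the 0.5 Å histogram is bimodal with modes at those distances
        top_two = sorted(np.argsort(counts)[-2:])
        centers = (edges[:-1] + edges[1:]) / 2
        assert abs(centers[top_two[0]] - 2.5) <= 0.5
        assert abs(centers[top_two[1]] - 4.5) <= 0.5
        assert counts[top_two].sum() >= 0.9 * len(vals)

    def test_empty_range_raises(self):
        from trajcomm.io import SelectionError
        from trajcomm.synth import make_reference

        topology, ref = make_reference(10)
        series = FrameSeries(np.repeat(ref.coords, 3, axis=0))
        fit = select(topology, "name CA")
        with pytest.raises(SelectionError):
            subrange_rmsd(series, topology, ref.coords[0], (900, 905), fit)
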