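"""Hemodynamic design, OLS fit, FDR, clusters, ROIs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import betaburst as bb
from betaburst.glm import HRF_PEAK_DELAY, HRF_RATIO, HRF_UNDER_DELAY
from oracles import bh_step_up, flood_fill_label


class TestCanonicalHrf:
    def test_zero_at_origin_and_single_sign_change(self):
        h = bb.canonical_hrf(0.1)
        assert h[0] == 0.0
        assert h.max() == pytest.approx(1.0)
        signs = np.sign(h[np.abs(h) > 1e-12])
        assert int((np.diff(signs) != 0).sum()) == 1

    def test_peak_location_matches_fine_grid_oracle(self):
        dt = 0.05
        h = bb.canonical_hrf(dt)
        t_fine = np.arange(0, 32, 0.001)
        closed = sps.gamma.pdf(t_fine, HRF_PEAK_DELAY) \
            - sps.gamma.pdf(t_fine, HRF_UNDER_DELAY) / HRF_RATIO
        t_peak_fine = t_fine[np.argmax(closed)]
        assert abs(dt * np.argmax(h) - t_peak_fine) <= dt

    def test_matches_nilearn_spm_shape(self):
        """Correlates near-perfectly with nilearn's SPM HRF (independent
        parameterization of the same canonical double gamma)."""
        nilearn_hrf = pytest.importorskip("nilearn.glm.first_level.hemodynamic_models")
        tr = 1.0
        ours = bb.canonical_hrf(tr / 16)
        theirs = nilearn_hrf.spm_hrf(tr, oversampling=16, time_length=32.0625)
        n = min(ours.size, theirs.size)
        r = np.corrcoef(ours[:n], theirs[:n])[0, 1]
        assert r > 0.999


def simple_events(rows=()):
    return pd.DataFrame(list(rows), columns=["onset", "duration", "trial_type"])


class TestDesignMatrix:
    def test_no_bursts_zero_column_and_intercept(self):
        d = bb.build_design_matrix(simple_events(), [], n_scans=50, tr=2.0)
        assert np.all(d.column("burst") == 0)
        assert np.all(d.column("intercept") == 1)
        assert d.names[-1] == "intercept"

    def test_single_impulse_equals_sampled_hrf(self):
        tr, mf = 2.0, 16
        dt = tr / mf
        t0 = 40 * dt  # exactly on the microtime grid
        d = bb.build_design_matrix(simple_events(), [t0], n_scans=100, tr=tr)
        hrf = bb.canonical_hrf(dt)
        expected = np.zeros(100)
        for i in range(100):
            k = i * mf - 40
            if 0 <= k < hrf.size:
                expected[i] = hrf[k]
        np.testing.assert_allclose(d.column("burst"), expected, atol=1e-9)

    def test_boxcar_linearity(self):
        ev_a = simple_events([(10.0, 30.0, "0back")])
        ev_b = simple_events([(25.0, 30.0, "0back")])
        ev_ab = pd.concat([ev_a, ev_b], ignore_index=True)
        col_ab = bb.build_design_matrix(ev_ab, [], 120, 2.0).column("0back")
        col_sum = bb.build_design_matrix(ev_a, [], 120, 2.0).column("0back") \
            + bb.build_design_matrix(ev_b, [], 120, 2.0).column("0back")
        np.testing.assert_allclose(col_ab, col_sum, atol=1e-12)

    def test_out_of_window_events_listed(self):
        ev = simple_events([(999.0, 1.0, "0back")])
        with pytest.raises(ValueError, match="999"):
            bb.build_design_matrix(ev, [], n_scans=10, tr=2.0)


class TestFitGlm:
    def test_noiseless_recovery(self, schedule_with_behavior):
        s = schedule_with_behavior
        bursts = np.arange(5.0, s.duration - 5.0, 3.7)
        Y, d, B = bb.synthesize_bold(bursts, s, tr=2.0, n_voxels=4,
                                     true_betas=np.array([0.2, 0.3, 0.4, 0.5, 0.6, 1.0]),
                                     noise_sd=0.0, seed=0)
        fit = bb.fit_glm(Y, d)
        assert np.abs(fit.betas.T - B).max() < 1e-8

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(20)
        s = bb.make_nback_schedule(1, seed=1)
        s = s.with_responses(bb.simulate_behavior(s, seed=2))
        bursts = bb.surrogate_events(300, s.duration - 2, min_gap=0.5, seed=3) + 1.0
        Y, d, _ = bb.synthesize_bold(bursts, s, tr=2.0, n_voxels=1000,
                                     true_betas=np.zeros(6), noise_sd=1.0, seed=4)
        fit = bb.fit_glm(Y, d)
        _, _, p = fit.contrast(d.contrast_vector("burst"))
        assert sps.kstest(p, "uniform").pvalue > 0.01

    def test_contrast_invariance_to_constant_shift(self, schedule_with_behavior):
        s = schedule_with_behavior
        bursts = np.arange(5.0, s.duration - 5.0, 4.1)
        Y, d, _ = bb.synthesize_bold(bursts, s, tr=2.0, n_voxels=3,
                                     true_betas=np.full(6, 0.3), noise_sd=1.0, seed=5)
        f1 = bb.fit_glm(Y, d)
        f2 = bb.fit_glm(Y + 7.5, d)
        ix = d.names.index("intercept")
        keep = [i for i in range(len(d.names)) if i != ix]
        np.testing.assert_allclose(f1.betas[:, keep], f2.betas[:, keep], atol=1e-8)
        np.testing.assert_allclose(f2.betas[:, ix] - f1.betas[:, ix], 7.5, atol=1e-8)

    def test_rank_deficient_warns(self):
        X = np.column_stack([np.ones(30), np.ones(30)])
        with pytest.warns(UserWarning, match="rank deficient"):
            fit = bb.fit_glm(np.random.default_rng(0).normal(size=30), X)
        assert fit.rank_deficient


class TestFdr:
    def test_extremes(self):
        assert bb.fdr_bh(np.full(50, 0.001), q=0.05).all()
        assert not bb.fdr_bh(np.full(50, 0.9), q=0.05).any()
        assert bb.fdr_bh([], q=0.05).size == 0

    def test_matches_step_up_oracle(self, rng):
        for _ in range(20):
            p = rng.random(100) ** rng.uniform(0.5, 3)
            np.testing.assert_array_equal(bb.fdr_bh(p, q=0.05),
                                          bh_step_up(p, 0.05))


class TestClusterFilter:
    def test_cube_retained(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:5, 2:5, 2:5] = True
        labels, sizes = bb.cluster_filter(mask, k_min=20)
        assert sizes.tolist() == [27]
        assert (labels == 1).sum() == 27

    def test_scattered_voxels_removed(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[::5, ::5, ::5] = True
        labels, sizes = bb.cluster_filter(mask, k_min=20)
        assert sizes.size == 0
        assert not labels.any()

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        mask = rng.random((12, 12, 12)) < 0.25
        labels, sizes = bb.cluster_filter(mask, k_min=1,
                                          connectivity=connectivity)
        oracle, n = flood_fill_label(mask, connectivity)
        # same partition: compare component memberships as sets of frozensets
        def parts(lab):
            return {frozenset(zip(*np.nonzero(lab == i)))
                    for i in range(1, lab.max() + 1)}
        assert parts(labels) == parts(oracle)
        assert sizes.sum() == mask.sum()


class TestRoiExtract:
    def test_constant_map(self):
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        roi = bb.roi_extract(np.full((10, 10, 10), 2.5), affine,
                             center_mm=(15, 15, 15))
        assert roi.mean == pytest.approx(2.5)

    def test_tiny_radius_single_voxel(self):
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        m = np.zeros((8, 8, 8))
        m[4, 4, 4] = 9.0
        roi = bb.roi_extract(m, affine, center_mm=(12, 12, 12), radius_mm=1.0)
        assert roi.n_voxels == 1
        assert roi.mean == 9.0

    def test_voxel_count_matches_lattice_enumeration(self):
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = -30.0
        m = np.zeros((21, 21, 21))
        roi = bb.roi_extract(m, affine, center_mm=(0.0, 0.0, 0.0), radius_mm=10.0)
        count = sum(
            1
            for i in range(-3, 4) for j in range(-3, 4) for k in range(-3, 4)
            if (3 * i) ** 2 + (3 * j) ** 2 + (3 * k) ** 2 <= 100
        )
        assert roi.n_voxels == count

    def test_empty_sphere_rejected(self):
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        with pytest.raises(ValueError):
            bb.roi_extract(np.zeros((5, 5, 5)), affine,
                           center_mm=(100, 100, 100), radius_mm=1.0)
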