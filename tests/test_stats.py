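"""Statistics suite: metrics, paired tests, screens, calibrations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as hst
from scipy import stats as sps

from cdvim import stats as st


class TestDisplacement:
    def test_three_four_five(self):
        d = st.displacement([3.0, 4.0, 0.0], [0.0, 0.0, 0.0])
        # axes are (ML, AP, SI)
        assert (d.d_ml, d.d_ap, d.d_si) == (3.0, 4.0, 0.0)
        assert d.ed == pytest.approx(5.0)

    def test_identical_points(self):
        d = st.displacement([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d.ed == 0.0 and d.d_ap == 0.0

    @given(hst.integers(min_value=0, max_value=40))
    def test_matches_brute_force_norm(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=3), rng.normal(size=3)
        d = st.displacement(a, b)
        assert d.ed == pytest.approx(np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b))))
        assert d.ed <= np.sqrt(d.d_ap**2 + d.d_ml**2 + d.d_si**2) + 1e-12
        assert d.ed >= max(d.d_ap, d.d_ml, d.d_si) - 1e-12


class TestDispersion:
    def test_hand_arithmetic(self):
        ref = np.zeros(3)
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        s = st.cohort_dispersion(pts, ref)
        assert s.rms_ed == pytest.approx(np.sqrt(2))
        assert s.max_ed == 2.0
        assert s.max_abs_ml == 2.0 and s.max_abs_ap == 0.0

    def test_zero_when_all_points_at_reference(self):
        pts = np.tile([1.0, 2.0, 3.0], (5, 1))
        s = st.cohort_dispersion(pts, [1.0, 2.0, 3.0])
        assert s.rms_ed == s.max_ed == 0.0

    def test_rms_ed_matches_chi_moment(self):
        rng = np.random.default_rng(0)
        sigma = 1.3
        pts = rng.normal(0, sigma, size=(4000, 3))
        s = st.cohort_dispersion(pts, np.zeros(3))
        # E[ed^2] = 3 sigma^2 so RMS ED -> sigma * sqrt(3)
        assert s.rms_ed == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_rigid_translation_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(20, 3))
        ref = rng.normal(size=3)
        t = np.array([4.0, -2.0, 9.0])
        a = st.cohort_dispersion(pts, ref)
        b = st.cohort_dispersion(pts + t, ref + t)
        assert a.rms_ed == pytest.approx(b.rms_ed)
        assert a.max_ed == pytest.approx(b.max_ed)
        assert (a.max_abs_ap, a.max_abs_ml, a.max_abs_si) == pytest.approx(
            (b.max_abs_ap, b.max_abs_ml, b.max_abs_si))

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            st.cohort_dispersion(np.zeros((1, 3)), np.zeros(3))


class TestHemisphericPosition:
    def test_identical_sides_give_null_result(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        res = st.hemispheric_position_test(pts, pts)
        for axis in ("ap", "ml", "si"):
            assert res[axis].statistic == 0.0
            assert res[axis].p_value == 1.0

    def test_constant_offset_reported_exactly(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        shifted = pts + np.array([0.0, 1.0, 0.0])
        res = st.hemispheric_position_test(shifted, pts)
        assert res["ap"].p_value == 0.0
        assert res["ap"].note is not None
        assert res["ap"].extras["mean_difference"] == pytest.approx(1.0)

    def test_ml_axis_uses_absolute_values(self):
        rng = np.random.default_rng(2)
        base = rng.normal(13.0, 1.0, size=12)
        left = np.column_stack([-base, rng.normal(size=12), rng.normal(size=12)])
        right = np.column_stack([base, rng.normal(size=12), rng.normal(size=12)])
        res = st.hemispheric_position_test(left, right)
        # |ML| identical on both sides despite opposite signs
        assert res["ml"].p_value == 1.0

    def test_power_matches_paired_t_oracle(self):
        """Empirical rejection rate under a shifted alternative agrees with
        the closed-form noncentral-t power."""
        rng = np.random.default_rng(3)
        n, delta, sigma, reps = 30, 0.6, 1.0, 1500
        hits = 0
        for _ in range(reps):
            diff = rng.normal(delta, sigma, size=n)
            base = rng.normal(size=n)
            res = st._paired_t("p", base + diff, base)
            hits += res.p_value < 0.05
        nc = delta / (sigma / np.sqrt(n))
        crit = sps.t.ppf(0.975, n - 1)
        power = 1 - sps.nct.cdf(crit, n - 1, nc) + sps.nct.cdf(-crit, n - 1, nc)
        se = np.sqrt(power * (1 - power) / reps)
        assert abs(hits / reps - power) < 4 * se


class TestPitmanMorgan:
    def test_identical_shifted_samples_are_null(self):
        x = np.random.default_rng(0).normal(size=20)
        res = st.pitman_morgan_test(x, x + 5.0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            st.pitman_morgan_test(np.ones(10), np.random.default_rng(0).normal(size=10))

    def test_agrees_with_permutation_oracle(self):
        """t-distribution p within 0.01 of a 10,000-draw sum-difference
        shuffle permutation p across 30 equal-variance bivariate-normal
        cases (n=30 each) — the regime where the permutation reference is
        exact."""
        rng = np.random.default_rng(4)
        worst = 0.0
        for case in range(30):
            rho = rng.uniform(-0.6, 0.6)
            cov = np.array([[1.0, rho], [rho, 1.0]])
            xy = rng.multivariate_normal([0, 0], cov, size=30)
            p_t = st.pitman_morgan_test(xy[:, 0], xy[:, 1]).p_value
            p_perm = st.pitman_morgan_permutation_p(
                xy[:, 0], xy[:, 1], n_perm=10_000,
                rng=np.random.default_rng(1000 + case))
            worst = max(worst, abs(p_t - p_perm))
        assert worst < 0.01

    def test_type_one_error_calibrated(self):
        rate = st.null_rejection_rate("pitman_morgan", n=60, reps=2000,
                                      rng=np.random.default_rng(5))
        se = np.sqrt(0.05 * 0.95 / 2000)
        assert abs(rate - 0.05) < 3 * se

    def test_power_exceeds_null_rate_for_unequal_variances(self):
        rng = np.random.default_rng(6)
        n, reps = 100, 400
        hits = 0
        for _ in range(reps):
            base = rng.normal(size=n)
            x = np.sqrt(2.0) * (np.sqrt(0.5) * base + np.sqrt(0.5) * rng.normal(size=n))
            y = np.sqrt(0.5) * base + np.sqrt(0.5) * rng.normal(size=n)
            hits += st.pitman_morgan_test(x, y).p_value < 0.05
        assert hits / reps > 0.3  # far above the 5% null rate


class TestAtlasOffset:
    def test_symmetric_cloud_is_null(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(200, 3)) + np.array([12.5, -6.0, 0.0])
        res = st.atlas_offset_test(pts, [12.5, -6.0, 0.0])
        for axis in ("ml", "ap", "si"):
            assert res[axis].p_value > 0.001
            assert abs(res[axis].statistic) < 4

    def test_deterministic_offset_degenerate_report(self):
        pts = np.tile([13.5, -6.0, 0.0], (8, 1))
        res = st.atlas_offset_test(pts, [12.5, -6.0, 0.0])
        assert res["ml"].note is not None
        assert res["ml"].extras["mean_offset"] == pytest.approx(1.0)
        assert res["ap"].p_value == 1.0

    def test_p_matches_closed_form_t(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(25, 3)) * 1.5 + np.array([0.4, 0, 0])
        res = st.atlas_offset_test(pts, np.zeros(3))
        ref = sps.ttest_1samp(pts[:, 0], 0.0)
        assert res["ml"].p_value == pytest.approx(ref.pvalue)


class TestConfoundScreen:
    def _tables(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        conf = pd.DataFrame({c: rng.normal(10, 2, size=n) for c in st.CONFOUND_NAMES})
        disp = pd.DataFrame({m: np.abs(rng.normal(size=n)) for m in
                             st.DISPLACEMENT_METRICS})
        return conf, disp

    def test_grid_size_is_twenty(self):
        conf, disp = self._tables()
        res = st.confound_screen(conf, disp, "L")
        assert len(res) == 20
        assert all(r.alpha == st.BONFERRONI_PUBLISHED for r in res)

    def test_exact_linear_relation_flagged(self):
        conf, disp = self._tables()
        disp["ed"] = 2.0 * conf["tiv"].to_numpy()
        res = st.confound_screen(conf, disp, "L")
        hit = [r for r in res if r.name == "L:ed~tiv"][0]
        assert hit.p_value < 1e-12
        assert hit.significant
        assert hit.extras["slope"] == pytest.approx(2.0)

    def test_constant_confound_invalidates_only_its_cells(self):
        conf, disp = self._tables()
        conf["tiv"] = 7.0
        res = st.confound_screen(conf, disp, "R")
        bad = [r for r in res if r.name.endswith("~tiv")]
        good = [r for r in res if not r.name.endswith("~tiv")]
        assert all(np.isnan(r.p_value) and r.note == "constant confound" for r in bad)
        assert all(np.isfinite(r.p_value) for r in good)

    def test_null_calibration(self):
        rate = st.null_rejection_rate("regression_f", n=50, reps=1000,
                                      rng=np.random.default_rng(2))
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(rate - 0.05) < 3.5 * se


class TestPrincipalDirections:
    def test_line_cloud_first_axis(self):
        rng = np.random.default_rng(0)
        pts = np.zeros((50, 3))
        pts[:, 0] = rng.normal(size=50)
        vals, vecs = st.principal_directions(pts)
        assert np.allclose(vecs[0], [1, 0, 0])
        assert vals[1] == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_cloud_equal_eigenvalues(self):
        pts = np.random.default_rng(1).normal(size=(5000, 3))
        vals, _ = st.principal_directions(pts)
        assert vals[0] / vals[2] < 1.2

    def test_anisotropic_axes_recovered_within_5_degrees(self):
        rng = np.random.default_rng(2)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        latent = rng.normal(size=(500, 3)) * np.array([3.0, 2.0, 1.0])
        pts = latent @ q.T
        vals, vecs = st.principal_directions(pts)
        for i in range(3):
            cosang = abs(vecs[i] @ q[:, i])
            assert np.degrees(np.arccos(min(cosang, 1.0))) < 5.0
        assert vals[0] > vals[1] > vals[2]


class TestJacobian:
    def test_unit_field_arithmetic(self):
        jac = np.ones((10, 10, 10))
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask.flat[:100] = True
        affine = np.diag([1.25, 1.25, 1.25, 1.0])
        assert st.integrate_jacobian(jac, mask, affine) == pytest.approx(195.3125)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        jac = rng.random((8, 8, 8)) + 0.5
        mask = rng.random((8, 8, 8)) > 0.5
        affine = np.eye(4)
        v1 = st.integrate_jacobian(jac, mask, affine)
        v2 = st.integrate_jacobian(2 * jac, mask, affine)
        assert v2 == pytest.approx(2 * v1)
        assert v1 == pytest.approx(jac[mask].sum())

    def test_nonpositive_value_rejected(self):
        jac = np.ones((5, 5, 5))
        jac[2, 2, 2] = 0.0
        mask = np.ones((5, 5, 5), dtype=bool)
        with pytest.raises(ValueError):
            st.integrate_jacobian(jac, mask, np.eye(4))


class TestScpPicoCorrelation:
    def test_exact_linear_gives_r_one(self):
        vols = pd.DataFrame({"L": [1.0, 2, 3, 4, 5], "R": [2.0, 4, 6, 8, 10]})
        pico = pd.DataFrame({"L": 0.1 * vols["R"] + 0.02, "R": 0.2 * vols["L"]})
        res = st.scp_pico_correlation(vols, pico)
        assert res["L"].statistic == pytest.approx(1.0)
        assert res["R"].statistic == pytest.approx(1.0)

    def test_contralateral_pairing_enforced(self):
        rng = np.random.default_rng(0)
        n = 200
        scp_r = rng.normal(100, 10, size=n)
        scp_l = rng.normal(100, 10, size=n)  # independent of everything
        pico_l = 0.002 * scp_r + rng.normal(0, 0.005, size=n)
        vols = pd.DataFrame({"L": scp_l, "R": scp_r})
        pico = pd.DataFrame({"L": pico_l, "R": rng.normal(0.2, 0.02, size=n)})
        res = st.scp_pico_correlation(vols, pico)
        assert res["L"].statistic > 0.5  # left tract vs right SCP
        assert abs(res["R"].statistic) < 0.25

    def test_constant_input_rejected(self):
        vols = pd.DataFrame({"L": np.ones(5), "R": np.ones(5)})
        pico = pd.DataFrame({"L": np.arange(5.0), "R": np.arange(5.0)})
        with pytest.raises(ValueError):
            st.scp_pico_correlation(vols, pico)


class TestWilcoxonComparisons:
    def _frames(self, within, between):
        w = pd.DataFrame({m: np.asarray(within, float) for m in
                          st.DISPLACEMENT_METRICS})
        b = pd.DataFrame({m: np.asarray(between, float) for m in
                          st.DISPLACEMENT_METRICS})
        return w, b

    def test_equal_distribution_p_not_extreme(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(60):
            w, b = self._frames(rng.exponential(size=20), rng.exponential(size=20))
            ps.append(st.test_retest_comparison(w, b)["ed"].p_value)
        assert 0.3 < np.median(ps) < 0.7

    def test_uniformly_smaller_within_attains_minimal_p(self):
        n = 10
        base = np.linspace(1.0, 2.0, n)
        w, b = self._frames(base - 0.5, base)
        res = st.test_retest_comparison(w, b)["ed"]
        assert res.p_value == pytest.approx(0.5**n)
        assert res.significant

    def test_identical_vectors_degenerate(self):
        base = np.linspace(1.0, 2.0, 8)
        w, b = self._frames(base, base)
        res = st.test_retest_comparison(w, b)["ed"]
        assert np.isnan(res.p_value)
        assert res.note is not None

    def test_rms_ed_reported(self):
        w, b = self._frames([3.0] * 8, [4.0] * 8)
        res = st.test_retest_comparison(w, b)["ed"]
        assert res.extras["rms_ed_within"] == pytest.approx(3.0)
        assert res.extras["rms_ed_between"] == pytest.approx(4.0)

    def test_volume_asymmetry_medians_and_min_p(self):
        left = np.linspace(90.0, 130.0, 12)
        res = st.volume_asymmetry_test(left, left * 1.5)
        assert res.extras["median_left"] == pytest.approx(np.median(left))
        assert res.p_value == pytest.approx(2 * 0.5**12)
        identical = st.volume_asymmetry_test(left, left)
        assert np.isnan(identical.p_value)

    def test_left_tail_calibration(self):
        rate = st.null_rejection_rate("wilcoxon_left", n=40, reps=1500,
                                      rng=np.random.default_rng(7))
        se = np.sqrt(0.05 * 0.95 / 1500)
        assert abs(rate - 0.05) < 3.5 * se
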