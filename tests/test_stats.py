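"""Rate, rebound and group statistics."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import betaburst as bb


def events_frame(rows):
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])


class TestConditionRates:
    def test_simple_rate(self):
        ev = events_frame([(0.0, 20.0, "rest"), (20.0, 30.0, "0back"),
                           (50.0, 30.0, "1back"), (80.0, 30.0, "2back")])
        bursts = np.linspace(1.0, 19.0, 10)
        r = bb.condition_rates(bursts, ev)
        assert r["rest"] == pytest.approx(0.5)
        assert r["0back"] == r["1back"] == r["2back"] == 0.0

    def test_no_bursts_all_zero(self):
        ev = events_frame([(0.0, 10.0, c) for c in
                           ("rest", "0back", "1back", "2back")])
        assert all(v == 0 for v in bb.condition_rates([], ev).values())

    def test_bursts_outside_intervals_ignored(self):
        ev = events_frame([(10.0, 10.0, "rest"), (30.0, 10.0, "0back"),
                           (50.0, 10.0, "1back"), (70.0, 10.0, "2back")])
        r = bb.condition_rates([5.0, 25.0, 45.0, 99.0], ev)
        assert all(v == 0 for v in r.values())

    def test_poisson_rate_recovery(self):
        ev = events_frame([(0.0, 2000.0, "rest"), (2000.0, 2000.0, "0back"),
                           (4000.0, 2000.0, "1back"), (6000.0, 2000.0, "2back")])
        rng = np.random.default_rng(5)
        n = rng.poisson(0.3 * 8000)
        bursts = np.sort(rng.uniform(0, 8000, n))
        r = bb.condition_rates(bursts, ev)
        band = 2.58 * np.sqrt(0.3 / 2000)   # 99% Poisson band on a rate
        for v in r.values():
            assert abs(v - 0.3) < band * 1.5

    def test_zero_duration_condition_errors(self):
        ev = events_frame([(0.0, 10.0, "rest")])
        with pytest.raises(ValueError, match="0back"):
            bb.condition_rates([1.0], ev)

    def test_translation_invariance(self):
        ev = events_frame([(5.0, 10.0, "rest"), (15.0, 10.0, "0back"),
                           (25.0, 10.0, "1back"), (35.0, 10.0, "2back")])
        bursts = np.array([6.0, 7.5, 16.0, 26.0, 36.0, 44.0])
        r1 = bb.condition_rates(bursts, ev)
        ev2 = ev.copy()
        ev2["onset"] += 100.0
        r2 = bb.condition_rates(bursts + 100.0, ev2)
        assert r1 == r2


class TestEventLockedRate:
    def test_burst_at_each_lock(self):
        locks = np.arange(10.0, 100.0, 10.0)
        curve = bb.event_locked_rate(locks.copy(), locks, window=0.5,
                                     lag_range=(-2.0, 2.0), step=0.05)
        i0 = np.argmin(np.abs(curve.lags))
        assert curve.rate[i0] == pytest.approx(1 / 0.5)
        assert curve.rate.max() == pytest.approx(2.0)

    def test_independent_bursts_flat_curve(self):
        rng = np.random.default_rng(8)
        lam, T = 0.5, 40000.0
        bursts = np.sort(rng.uniform(0, T, rng.poisson(lam * T)))
        locks = rng.uniform(100, T - 100, 10000)
        curve = bb.event_locked_rate(bursts, locks, window=0.5,
                                     lag_range=(-3.0, 3.0), step=0.5)
        assert np.all(np.abs(curve.rate - lam) < 0.05)

    def test_no_bursts_zero_curve(self):
        curve = bb.event_locked_rate([], [5.0, 10.0], window=0.5,
                                     lag_range=(-1.0, 1.0), step=0.1)
        assert np.all(curve.rate == 0)

    def test_empty_locks_rejected(self):
        with pytest.raises(ValueError):
            bb.event_locked_rate([1.0], [])


class TestPMBR:
    def test_one_burst_per_post_window(self):
        resp = np.array([10.0, 20.0, 30.0])
        bursts = resp + 0.7
        res = bb.pmbr(bursts, resp)
        assert res.pmbr == pytest.approx(2.0)
        assert res.post_rate == pytest.approx(2.0)
        assert res.baseline_rate == 0.0
        assert res.n_responses == 3
        # identity pmbr = post - baseline holds exactly
        assert res.pmbr == res.post_rate - res.baseline_rate

    def test_half_open_window_edges(self):
        resp = np.array([10.0])
        assert bb.pmbr(np.array([10.5]), resp).post_rate == pytest.approx(2.0)
        assert bb.pmbr(np.array([11.0]), resp).post_rate == 0.0

    def test_homogeneous_poisson_centered_on_zero(self):
        rng = np.random.default_rng(9)
        vals = []
        for _ in range(300):
            T = 2000.0
            bursts = np.sort(rng.uniform(0, T, rng.poisson(0.4 * T)))
            resp = np.arange(10.0, T - 10.0, 10.0)
            vals.append(bb.pmbr(bursts, resp).pmbr)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-3

    def test_edge_windows_dropped(self):
        resp = np.array([1.0, 50.0])   # first response's baseline precedes t=0
        res = bb.pmbr([], resp, t_start=0.0, t_stop=100.0)
        assert res.n_responses == 1

    def test_pooled_equals_mean_for_equal_windows(self):
        rng = np.random.default_rng(10)
        bursts = np.sort(rng.uniform(0, 500, 200))
        resp = np.arange(20.0, 480.0, 20.0)
        a = bb.pmbr(bursts, resp, method="pooled")
        b = bb.pmbr(bursts, resp, method="mean")
        assert a.pmbr == pytest.approx(b.pmbr)

    def test_consistent_with_rate_curve(self):
        """pmbr equals the event-locked curve averaged over the post and
        baseline windows at matched window/step."""
        rng = np.random.default_rng(11)
        bursts = np.sort(rng.uniform(0, 1000, 400))
        resp = np.arange(20.0, 980.0, 12.0)
        res = bb.pmbr(bursts, resp)
        curve = bb.event_locked_rate(bursts, resp, window=0.5,
                                     lag_range=(-2.75, 0.75), step=0.5)
        post = curve.mean_over(0.75, 0.75)
        base = curve.mean_over(-2.75, -1.75)
        assert res.pmbr == pytest.approx(post - base, abs=1e-12)

    def test_empty_responses_rejected(self):
        with pytest.raises(ValueError):
            bb.pmbr([1.0], [])


class TestGroupCompare:
    def test_identical_groups_null(self):
        a = np.arange(10.0)
        res = bb.group_compare(a, a.copy())
        assert res.statistic == pytest.approx(50.0)  # n^2 / 2
        assert res.effect_size == pytest.approx(0.0)
        t = bb.group_compare(a, a + 0.0, method="t_test")
        assert t.effect_size == pytest.approx(0.0)

    def test_complete_separation(self):
        res = bb.group_compare([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1, abs=1e-9)  # exact 2/20

    def test_exhaustive_permutation_oracle(self, rng):
        """Exact Mann-Whitney p equals enumeration over all group labelings."""
        for _ in range(5):
            a = rng.normal(size=4)
            b = rng.normal(size=4)
            res = bb.group_compare(a, b)
            pooled = np.concatenate([a, b])
            u_obs = sum((x > y) + 0.5 * (x == y)
                        for x in a for y in b)
            stat_dev = abs(u_obs - 8.0)
            count = 0
            total = 0
            for idx in combinations(range(8), 4):
                ga = pooled[list(idx)]
                gb = pooled[[i for i in range(8) if i not in idx]]
                u = sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)
                if abs(u - 8.0) >= stat_dev - 1e-12:
                    count += 1
                total += 1
            assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_welch_t_and_cohens_d(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(1, 1, 30)
        res = bb.group_compare(a, b, method="t_test")
        t, p = sps.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(float(t))
        assert res.p_value == pytest.approx(float(p))
        pooled_sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        assert res.effect_size == pytest.approx((a.mean() - b.mean()) / pooled_sd)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            bb.group_compare([1.0, 1.0, 1.0], [1.0, 1.0], method="t_test")


class TestRmAnova:
    def test_two_conditions_epsilon_is_one(self, rng):
        X = rng.normal(size=(12, 2))
        assert bb.rm_anova_gg(X)["epsilon"] == pytest.approx(1.0)

    def test_null_f_near_one(self):
        rng = np.random.default_rng(13)
        fs = [bb.rm_anova_gg(rng.normal(size=(10, 3)))["F"] for _ in range(300)]
        # E[F] = df2 / (df2 - 2) = 18/16 under the null
        assert abs(np.mean(fs) - 18 / 16) < 0.25

    def test_matches_textbook_ss_decomposition(self, rng):
        """F and epsilon agree with an explicit sums-of-squares oracle and
        with pingouin's repeated-measures ANOVA."""
        pingouin = pytest.importorskip("pingouin")
        X = rng.normal(size=(20, 4)) + rng.normal(size=(20, 1))
        res = bb.rm_anova_gg(X)
        n, k = X.shape
        grand = X.mean()
        ss_cond = n * ((X.mean(0) - grand) ** 2).sum()
        ss_subj = k * ((X.mean(1) - grand) ** 2).sum()
        ss_err = ((X - grand) ** 2).sum() - ss_cond - ss_subj
        F = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
        assert res["F"] == pytest.approx(F, rel=1e-9)
        assert res["partial_eta_sq"] == pytest.approx(
            ss_cond / (ss_cond + ss_err), rel=1e-9)
        long = pd.DataFrame({
            "subj": np.repeat(np.arange(n), k),
            "cond": np.tile(np.arange(k), n),
            "y": X.ravel(),
        })
        pg = pingouin.rm_anova(data=long, dv="y", within="cond",
                               subject="subj", correction=True)
        assert res["F"] == pytest.approx(float(pg["F"][0]), rel=1e-6)
        assert res["epsilon"] == pytest.approx(float(pg["eps"][0]), rel=1e-6)
        assert res["p_gg"] == pytest.approx(float(pg["p_GG_corr"][0]), rel=1e-6)

    def test_missing_cells_rejected(self):
        X = np.ones((5, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            bb.rm_anova_gg(X)


class TestAssociate:
    def test_monotone_relationship(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 9.0])
        rho, _ = bb.associate(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_null_independence(self):
        rng = np.random.default_rng(14)
        rho, _ = bb.associate(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(rho) < 3 / np.sqrt(1000)

    def test_rank_formula_oracle_n7(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.8, 1.8, 9.0])
        rho, _ = bb.associate(x, y)
        d = sps.rankdata(x) - sps.rankdata(y)
        oracle = 1 - 6 * np.sum(d**2) / (7 * 48)
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_covariate_adjustment_removes_confound(self):
        rng = np.random.default_rng(15)
        z = rng.normal(size=500)
        x = 2 * z + rng.normal(size=500)
        y = -3 * z + rng.normal(size=500)
        rho_raw, _ = bb.associate(x, y)
        rho_adj, _ = bb.associate(x, y, covariates=z)
        assert rho_raw < -0.5
        assert abs(rho_adj) < 0.15

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            bb.associate(np.ones(10), np.arange(10.0))
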