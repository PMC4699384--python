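"""Unit and oracle tests for the survival-analysis suite."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from prc2kit import prognosis as pr


# ---------------------------------------------------------------------------
# metagene
# ---------------------------------------------------------------------------

class TestComputeMetagene:
    def test_odd_count_median(self):
        expr = pd.DataFrame({"s1": [1.0, 3.0, 5.0]}, index=["a", "b", "c"])
        assert pr.compute_metagene(expr, ["a", "b", "c"])["s1"] == 3.0

    def test_identical_rows(self):
        row = [2.0, 4.0, 6.0]
        expr = pd.DataFrame([row, row, row], index=["a", "b", "c"],
                            columns=["s1", "s2", "s3"])
        out = pr.compute_metagene(expr, ["a", "b", "c"])
        assert list(out) == row

    def test_brute_force_median_oracle(self, rng):
        expr = pd.DataFrame(rng.normal(size=(54, 100)),
                            index=[f"g{i}" for i in range(54)])
        out = pr.compute_metagene(expr, expr.index)
        for j in range(100):
            col = sorted(expr.iloc[:, j])
            oracle = (col[26] + col[27]) / 2  # sort-based median, n=54
            assert out.iloc[j] == pytest.approx(oracle)

    def test_missing_gene_named(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["a"])
        with pytest.raises(KeyError, match="zzz"):
            pr.compute_metagene(expr, ["a", "zzz"])


# ---------------------------------------------------------------------------
# adjustment
# ---------------------------------------------------------------------------

class TestAdjustToMetagene:
    def test_perfect_fit_zero_residuals(self):
        p = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        marker = 2 * p + 1
        adj = pr.adjust_to_metagene(marker, p)
        assert adj.residuals == pytest.approx(np.zeros(4), abs=1e-12)
        assert adj.slope == pytest.approx(2.0)
        assert adj.intercept == pytest.approx(1.0)

    def test_normal_equations_oracle(self, rng):
        idx = [f"s{i}" for i in range(80)]
        p = pd.Series(rng.normal(size=80), index=idx)
        marker = pd.Series(rng.normal(size=80), index=idx)
        adj = pr.adjust_to_metagene(marker, p)
        X = np.column_stack([np.ones(80), p.to_numpy()])
        beta = np.linalg.solve(X.T @ X, X.T @ marker.to_numpy())
        oracle = marker.to_numpy() - X @ beta
        assert adj.residuals == pytest.approx(oracle, abs=1e-10)

    def test_invariants(self, rng):
        idx = [f"s{i}" for i in range(50)]
        p = pd.Series(rng.normal(size=50), index=idx)
        marker = pd.Series(rng.normal(size=50), index=idx)
        adj = pr.adjust_to_metagene(marker, p)
        assert adj.residuals.sum() == pytest.approx(0.0, abs=1e-9)
        assert np.cov(adj.residuals, p.to_numpy())[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_constant_metagene_error(self):
        p = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            pr.adjust_to_metagene(p * 2, p)


class TestMedianStratify:
    def test_even_split(self):
        out = pr.median_stratify(pd.Series([1, 2, 3, 4]))
        assert list(out) == ["low", "low", "high", "high"]

    def test_ties_go_low(self):
        out = pr.median_stratify(pd.Series([1, 2, 2, 3]))
        assert list(out) == ["low", "low", "low", "high"]

    def test_imbalance_bounded_by_ties(self, rng):
        v = pd.Series(rng.integers(0, 10, size=101).astype(float))
        out = pr.median_stratify(v)
        n_ties = int((v == v.median()).sum())
        assert abs((out == "high").sum() - (out == "low").sum()) <= n_ties + 1

    def test_constant_error(self):
        with pytest.raises(ValueError):
            pr.median_stratify(pd.Series([2.0, 2.0]))


class TestStratifyByCnv:
    def test_mapping(self):
        out = pr.stratify_by_cnv(pd.Series([-1, 0, 1, 0]))
        assert list(out) == ["loss", "neutral", "gain", "neutral"]

    def test_hom_loss_grouped_with_loss(self):
        assert list(pr.stratify_by_cnv(pd.Series([-2, -1]))) == ["loss", "loss"]

    def test_unknown_state(self):
        with pytest.raises(ValueError):
            pr.stratify_by_cnv(pd.Series([5]))


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class TestKaplanMeier:
    def test_no_censoring_equals_empirical(self):
        curve = pr.km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert curve.survival == pytest.approx([0.75, 0.5, 0.25, 0.0])

    def test_all_censored(self):
        curve = pr.km_estimate([1, 2, 3], [0, 0, 0])
        assert np.all(curve.survival == 1.0)

    def test_hand_product_limit_with_censoring(self):
        # events at 1, 3, 4; censored at 2 (n = 4)
        curve = pr.km_estimate([1, 2, 3, 4], [1, 0, 1, 1])
        assert curve.survival_at(1) == pytest.approx(0.75)
        assert curve.survival_at(3) == pytest.approx(0.375)
        assert curve.survival_at(4) == pytest.approx(0.0)

    def test_against_lifelines(self, rng):
        from lifelines import KaplanMeierFitter
        times = rng.exponential(10, size=60)
        events = rng.integers(0, 2, size=60)
        if events.sum() == 0:
            events[0] = 1
        curve = pr.km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10)

    def test_monotone_and_bounded(self, rng):
        times = rng.exponential(5, size=40)
        events = rng.integers(0, 2, size=40)
        events[0] = 1
        curve = pr.km_estimate(times, events)
        assert np.all(np.diff(curve.survival) <= 1e-15)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))

    def test_empty_error(self):
        with pytest.raises(ValueError):
            pr.km_estimate([], [])


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def _logrank_oracle_two_group(times, events, groups):
    """Explicit sum over event times of (O - E)^2 / V for group A."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    a = np.unique(groups)[0]
    O = E = V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & (groups == a)).sum()
        dead = at_risk & (times == t) & (events == 1)
        d = dead.sum()
        d_a = (dead & (groups == a)).sum()
        O += d_a
        E += d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestLogRank:
    def test_identical_groups_null(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1, 1, 1, 1, 1, 1]
        groups = ["a", "a", "a", "b", "b", "b"]
        res = pr.logrank_test(times, events, groups)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.hr("a", "b") == pytest.approx(1.0)

    def test_label_swap_inverts_hr(self, rng):
        times = rng.exponential(5, size=50)
        events = np.ones(50, int)
        groups = np.array(["a"] * 25 + ["b"] * 25)
        r1 = pr.logrank_test(times, events, groups)
        swapped = np.where(groups == "a", "b", "a")
        r2 = pr.logrank_test(times, events, swapped)
        assert r1.hr("a", "b") == pytest.approx(1 / r2.hr("a", "b"))
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_ten_subject_tabulation_oracle(self):
        times = [1, 2, 2, 3, 5, 1, 4, 4, 6, 7]
        events = [1, 1, 0, 1, 1, 1, 1, 0, 1, 0]
        groups = ["a"] * 5 + ["b"] * 5
        res = pr.logrank_test(times, events, groups)
        assert res.chi2 == pytest.approx(
            _logrank_oracle_two_group(times, events, groups), abs=1e-12)

    def test_against_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank
        times = rng.exponential(8, size=80)
        events = rng.integers(0, 2, size=80)
        events[:5] = 1
        groups = np.array(["a", "b"] * 40)
        res = pr.logrank_test(times, events, groups)
        sel = groups == "a"
        ll = ll_logrank(times[sel], times[~sel], events[sel], events[~sel])
        assert res.chi2 == pytest.approx(ll.test_statistic, rel=1e-8)
        assert res.p_value == pytest.approx(ll.p_value, rel=1e-8)

    def test_time_transform_invariance(self, rng):
        times = rng.exponential(5, size=40) + 0.1
        events = rng.integers(0, 2, size=40)
        events[:4] = 1
        groups = np.array(["a", "b"] * 20)
        r1 = pr.logrank_test(times, events, groups)
        r2 = pr.logrank_test(np.log1p(times) ** 3, events, groups)
        assert r1.chi2 == pytest.approx(r2.chi2, rel=1e-10)

    def test_observed_expected_sums(self, rng):
        times = rng.exponential(5, size=30)
        events = np.ones(30, int)
        groups = np.array(["a"] * 10 + ["b"] * 20)
        res = pr.logrank_test(times, events, groups)
        assert sum(res.observed.values()) == pytest.approx(30)
        assert sum(res.expected.values()) == pytest.approx(30)

    def test_single_group_error(self):
        with pytest.raises(ValueError):
            pr.logrank_test([1, 2], [1, 1], ["a", "a"])

    def test_no_event_error(self):
        with pytest.raises(ValueError):
            pr.logrank_test([1, 2], [0, 0], ["a", "b"])


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

def _cox_loglik_oracle(beta, times, events, x):
    """Written-out Efron partial likelihood for brute-force maximization."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for t in np.unique(times[events == 1]):
        D = np.flatnonzero((times == t) & (events == 1))
        R = np.flatnonzero(times >= t)
        d = len(D)
        wR = np.exp(beta * x[R]).sum()
        wD = np.exp(beta * x[D]).sum()
        ll += beta * x[D].sum()
        for el in range(d):
            ll -= np.log(wR - (el / d) * wD)
    return ll


class TestCox:
    def test_perfect_separation_flagged(self):
        times = [1, 2, 3, 4, 5, 6]
        events = [1, 0, 0, 0, 0, 0]
        x = [1, 0, 0, 0, 0, 0]  # covariate separates the only event
        res = pr.cox_univariate(times, events, x)
        assert not res.converged
        assert np.isnan(res.beta)

    def test_grid_search_oracle_eight_subjects(self):
        times = [2.0, 3.0, 5.0, 7.0, 11.0, 13.0, 17.0, 19.0]
        events = [1, 1, 0, 1, 1, 0, 1, 1]
        x = [0.5, -1.2, 0.3, 2.1, -0.7, 1.5, -0.2, 0.9]
        res = pr.cox_univariate(times, events, x)
        grid = np.linspace(-3, 3, 60001)
        lls = [_cox_loglik_oracle(b, times, events, x) for b in grid]
        beta_star = grid[int(np.argmax(lls))]
        assert res.converged
        assert res.beta == pytest.approx(beta_star, abs=1e-4)

    def test_against_lifelines_with_ties(self, rng):
        from lifelines import CoxPHFitter
        n = 120
        x = rng.normal(size=n)
        times = np.round(rng.exponential(np.exp(-0.5 * x)), 1) + 0.1  # ties
        events = rng.random(n) < 0.7
        res = pr.cox_univariate(times, events.astype(int), x)
        df = pd.DataFrame({"t": times, "e": events.astype(int), "x": x})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert res.beta == pytest.approx(cph.params_["x"], abs=1e-5)
        assert res.se == pytest.approx(cph.standard_errors_["x"], abs=1e-4)

    def test_breslow_against_lifelines(self, rng):
        n = 60
        x = rng.normal(size=n)
        times = rng.exponential(np.exp(-0.3 * x))
        events = np.ones(n, int)
        res = pr.cox_univariate(times, events, x, ties="breslow")
        # no ties: breslow == efron
        res_e = pr.cox_univariate(times, events, x, ties="efron")
        assert res.beta == pytest.approx(res_e.beta, abs=1e-8)

    def test_null_beta_near_zero(self, rng):
        n = 200
        times = rng.exponential(5, size=n)
        events = np.ones(n, int)
        betas = []
        for _ in range(10):
            x = rng.permutation(np.arange(n, dtype=float))
            betas.append(pr.cox_univariate(times, events, x).beta)
        assert abs(np.mean(betas)) < 0.005

    def test_time_rescale_invariance(self, rng):
        n = 50
        x = rng.normal(size=n)
        times = rng.exponential(np.exp(-0.4 * x))
        events = np.ones(n, int)
        r1 = pr.cox_univariate(times, events, x)
        r2 = pr.cox_univariate(times * 37.0, events, x)
        assert r1.beta == pytest.approx(r2.beta, abs=1e-8)

    def test_constant_covariate_error(self):
        with pytest.raises(ValueError):
            pr.cox_univariate([1, 2, 3], [1, 1, 0], [2, 2, 2])


# ---------------------------------------------------------------------------
# BH-FDR
# ---------------------------------------------------------------------------

def _bh_oracle(p):
    """Naive O(m^2) step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    q = np.empty(m)
    order = np.argsort(p)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = []
        for rank_j, idx_j in enumerate(order, start=1):
            if rank_j >= rank_pos:
                candidates.append(p[idx_j] * m / rank_j)
        q[idx] = min(min(candidates), 1.0)
    return q


class TestBhFdr:
    def test_step_up_arithmetic(self):
        assert pr.bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p(self):
        assert pr.bh_fdr([0.2]) == pytest.approx([0.2])

    def test_brute_force_oracle(self, rng):
        p = rng.random(100)
        assert pr.bh_fdr(p) == pytest.approx(_bh_oracle(p), abs=1e-12)

    def test_against_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.random(60)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert pr.bh_fdr(p) == pytest.approx(q_sm, abs=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_q_dominates_p(self, pvals):
        q = pr.bh_fdr(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        assert np.all(q <= 1.0)

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            pr.bh_fdr([0.5, 1.5])


# ---------------------------------------------------------------------------
# chromosome scan
# ---------------------------------------------------------------------------

class TestChromosomeScan:
    def _cohort(self, rng, n=80, genes=("g1", "g2", "g3")):
        samples = [f"s{i}" for i in range(n)]
        cnv = pd.DataFrame(0, index=samples, columns=list(genes))
        clinical = pd.DataFrame(
            {"time": rng.exponential(5, n), "event": rng.integers(0, 2, n)},
            index=samples)
        clinical.loc[clinical.index[:5], "event"] = 1
        return cnv, clinical

    def test_no_loss_all_skipped(self, rng):
        cnv, clinical = self._cohort(rng)
        res = pr.chromosome_scan(cnv, clinical, cnv.columns)
        assert res.table["skipped"].all()
        assert res.table["q"].isna().all()

    def test_duplicated_column_identical(self, rng):
        cnv, clinical = self._cohort(rng)
        loss = (rng.random(len(cnv)) < 0.3).astype(int) * -1
        cnv["g1"] = loss
        cnv["g2"] = loss
        res = pr.chromosome_scan(cnv, clinical, ["g1", "g2"])
        t = res.table.set_index("gene")
        assert t.loc["g1", "p"] == pytest.approx(t.loc["g2", "p"])
        assert t.loc["g1", "q"] == pytest.approx(t.loc["g2", "q"])

    def test_planted_arm_recovered(self):
        from prc2kit import synthetic_data as sd
        arm = ("MARKER", "G_0000", "G_0001", "G_0002")
        d = sd.generate_cohort(sd.CohortConfig(
            n_samples=800, n_genes=70, seed=5, lost_arm_genes=arm,
            cnv_loss_prob=0.2, cnv_effect=1.5, beta_resid=-0.8))
        res = pr.chromosome_scan(d.cnv, d.clinical, list(d.cnv.columns))
        t = res.table.set_index("gene")
        assert t.loc[list(arm), "significant"].all()


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

class TestRocAuc:
    def test_perfect_separation(self):
        assert pr.roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_constant_marker(self):
        assert pr.roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_pair_counting_oracle(self, rng):
        marker = rng.normal(size=500)
        outcome = rng.integers(0, 2, size=500)
        outcome[:3] = [0, 1, 0]
        auc = pr.roc_auc(marker, outcome)
        pos = marker[outcome == 1]
        neg = marker[outcome == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)))
        assert 0.4 < auc < 0.6

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            pr.roc_auc([1, 2], [1, 1])
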