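"""Group comparison, ROC, correlations and the monitoring change report."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from renal_mpmri.stats import (
    DECLINE_POLARITY,
    benjamini_hochberg,
    compare_groups,
    correlation_matrix,
    pct_change_report,
    roc_auc,
    slope_correlation,
)


def pairwise_auc_oracle(pos, neg):
    """Exhaustive ordered-pair fraction with half credit for ties."""
    wins = ties = 0
    for p in pos:
        for n in neg:
            wins += p > n
            ties += p == n
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestCompareGroups:
    def test_identical_groups_p_one(self, rng):
        a = rng.lognormal(0, 1, 20)  # skewed: routed to Mann-Whitney
        gc = compare_groups(a, a)
        assert gc.p_value == pytest.approx(1.0, abs=0.02)

    def test_separated_groups_with_permutation_oracle(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(2, 1, 50)
        gc = compare_groups(a, b)
        assert gc.p_value < 1e-4
        # permutation oracle on the mean difference (10^5 shuffles)
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        n_perm = 100_000
        idx = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
        perm = pooled[idx]
        diffs = np.abs(perm[:, :50].mean(axis=1) - perm[:, 50:].mean(axis=1))
        p_perm = (np.sum(diffs >= obs) + 1) / (n_perm + 1)
        assert p_perm <= 1e-4

    def test_moderate_effect_consistent_with_permutation(self, rng):
        # Mann-Whitney asymptotic p tracks a rank permutation oracle
        a = rng.lognormal(0.0, 0.8, 25)
        b = rng.lognormal(0.55, 0.8, 25)
        gc = compare_groups(a, b, force="mann-whitney")
        ranks = sps.rankdata(np.concatenate([a, b]))
        obs = abs(ranks[:25].sum() - ranks.sum() / 2)
        n_perm = 100_000
        idx = np.argsort(rng.random((n_perm, 50)), axis=1)
        sums = np.abs(ranks[idx][:, :25].sum(axis=1) - ranks.sum() / 2)
        p_perm = (np.sum(sums >= obs - 1e-12) + 1) / (n_perm + 1)
        mc_err = 4 * np.sqrt(max(p_perm, 1e-6) * (1 - p_perm) / n_perm)
        assert abs(gc.p_value - p_perm) < mc_err + 0.01

    def test_swap_symmetry(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 2, 15)
        assert compare_groups(a, b).p_value == pytest.approx(
            compare_groups(b, a).p_value, rel=1e-12)

    def test_normality_gate_is_deterministic(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.lognormal(0, 1.5, 30)
        gc = compare_groups(a, b)
        assert gc.test == ("t-test" if gc.shapiro_p_a > 0.05
                           and gc.shapiro_p_b > 0.05 else "mann-whitney")
        assert gc.test == "mann-whitney"

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], n_boot=200)
        assert r.auc == 1.0
        assert r.ci_low <= r.auc <= r.ci_high

    def test_equals_exhaustive_pair_oracle_random(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(2, 10, 2)
            scores = rng.integers(0, 5, n1 + n2).astype(float)
            labels = np.r_[np.ones(n1, bool), np.zeros(n2, bool)]
            r = roc_auc(scores, labels, n_boot=10)
            oracle = pairwise_auc_oracle(scores[:n1], scores[n1:])
            assert r.auc == pytest.approx(oracle, rel=1e-12)

    def test_negating_scores_flips_auc(self, rng):
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.4
        if labels.sum() in (0, 30):
            labels[0] = ~labels[0]
        r1 = roc_auc(scores, labels, n_boot=10)
        r2 = roc_auc(-scores, labels, n_boot=10)
        assert r2.auc == pytest.approx(1.0 - r1.auc, rel=1e-12)
        assert r1.oriented_auc >= 0.5 and r2.oriented_auc >= 0.5

    def test_bootstrap_ci_is_seeded_and_ordered(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False
        a = roc_auc(scores, labels, n_boot=500, seed=7)
        b = roc_auc(scores, labels, n_boot=500, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert 0.0 <= a.ci_low <= a.auc <= a.ci_high <= 1.0


class TestCorrelations:
    def test_self_and_exact_linear(self, rng):
        x = rng.normal(size=40)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1})
        r, p, m = correlation_matrix(df, method="pearson")
        assert r.loc["x", "x"] == 1.0
        assert r.loc["x", "y"] == pytest.approx(1.0, rel=1e-12)
        assert p.loc["x", "y"] < 1e-10

    def test_spearman_equals_pearson_on_midranks(self, rng):
        for _ in range(100):
            x = rng.integers(0, 6, 30).astype(float)
            y = rng.integers(0, 6, 30).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            df = pd.DataFrame({"x": x, "y": y})
            r, _, _ = correlation_matrix(df, method="spearman")
            oracle = sps.pearsonr(sps.rankdata(x), sps.rankdata(y)).statistic
            assert r.loc["x", "y"] == pytest.approx(oracle, rel=1e-10)

    def test_pairwise_complete_missing_data(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(0, 0.5, 30)
        y[:5] = np.nan
        df = pd.DataFrame({"x": x, "y": y})
        r, _, _ = correlation_matrix(df, method="pearson")
        oracle = sps.pearsonr(x[5:], y[5:]).statistic
        assert r.loc["x", "y"] == pytest.approx(oracle, rel=1e-10)

    def test_slope_correlation_constant_flagged(self, rng):
        df = pd.DataFrame({"const": np.ones(20), "ok": rng.normal(size=20)})
        out = slope_correlation(df, rng.normal(size=20)).set_index("measure")
        assert np.isnan(out.loc["const", "spearman_r"])
        assert np.isfinite(out.loc["ok", "spearman_r"])

    def test_slope_correlation_monotone_invariance(self, rng):
        x = rng.lognormal(0, 1, 25)
        slopes = rng.normal(-3, 2, 25)
        r1 = slope_correlation(pd.DataFrame({"m": x}), slopes)
        r2 = slope_correlation(pd.DataFrame({"m": np.log(x)}), slopes)
        assert r1["spearman_r"][0] == pytest.approx(r2["spearman_r"][0],
                                                    rel=1e-12)


def tidy_summaries(values):
    """values: {(subject, group, visit, measure): value} -> tidy frame."""
    return pd.DataFrame(
        [{"subject": s, "group": g, "visit": v, "measure": m, "value": val}
         for (s, g, v, m), val in values.items()])


class TestPctChangeReport:
    def test_basic_arithmetic(self):
        vals = {}
        for i in range(6):
            g = "progressor" if i < 3 else "stable"
            vals[(f"s{i}", g, "baseline", "tkv")] = 100.0
            vals[(f"s{i}", g, "year1", "tkv")] = 90.0
            vals[(f"s{i}", g, "year2", "tkv")] = 80.0
        rep = pct_change_report(tidy_summaries(vals))
        cell = rep.table.query("group=='progressor' and visit=='year1'")
        assert cell["mean_pct_change"].iloc[0] == pytest.approx(-10.0)

    def test_zero_changes_all_no_change(self):
        vals = {}
        for i in range(8):
            g = "progressor" if i < 4 else "stable"
            for v in ("baseline", "year1", "year2"):
                vals[(f"s{i}", g, v, "adc_cortex")] = 2.0
        rep = pct_change_report(tidy_summaries(vals))
        assert (rep.table["category"] == "no-change").all()

    def test_polarity_maps_direction_to_category(self, rng):
        vals = {}
        for i in range(10):
            g = "progressor"
            base_t1, base_adc = 1500.0, 2.0
            vals[(f"s{i}", g, "baseline", "t1_cortex")] = base_t1
            vals[(f"s{i}", g, "baseline", "adc_cortex")] = base_adc
            jitter = 1.0 + rng.normal(0, 0.002)
            vals[(f"s{i}", g, "year1", "t1_cortex")] = base_t1 * 1.10 * jitter
            vals[(f"s{i}", g, "year1", "adc_cortex")] = base_adc * 1.10 * jitter
            vals[(f"s{i}", g, "year2", "t1_cortex")] = base_t1 * 1.20 * jitter
            vals[(f"s{i}", g, "year2", "adc_cortex")] = base_adc * 1.20 * jitter
        rep = pct_change_report(tidy_summaries(vals))
        t = rep.table.set_index(["measure", "visit"])
        # a +10% rise is decline for T1 but improvement for ADC
        assert t.loc[("t1_cortex", "year1"), "category"] == "decline"
        assert t.loc[("adc_cortex", "year1"), "category"] == "improve"

    def test_incomplete_subjects_excluded(self):
        vals = {}
        for i in range(8):
            g = "progressor" if i < 4 else "stable"
            for v in ("baseline", "year1", "year2"):
                vals[(f"s{i}", g, v, "tkv")] = 100.0 - 10 * (v != "baseline")
        del vals[("s0", "progressor", "year2", "tkv")]
        rep = pct_change_report(tidy_summaries(vals))
        assert (rep.table.query("group=='progressor'")["n"] == 3).all()

    def test_category_invariant_to_rescaling(self, rng):
        vals, scaled = {}, {}
        for i in range(10):
            g = "progressor" if i < 5 else "stable"
            for j, v in enumerate(("baseline", "year1", "year2")):
                x = 50.0 * (1 - 0.08 * j) * (1 + rng.normal(0, 0.01))
                vals[(f"s{i}", g, v, "t2star_cortex")] = x
                scaled[(f"s{i}", g, v, "t2star_cortex")] = 1000.0 * x
        r1 = pct_change_report(tidy_summaries(vals))
        r2 = pct_change_report(tidy_summaries(scaled))
        assert list(r1.table["category"]) == list(r2.table["category"])

    def test_polarity_table_covers_all_measures(self):
        from renal_mpmri.phantom import MEASURES
        assert set(DECLINE_POLARITY) == set(MEASURES)


class TestBenjaminiHochberg:
    def test_monotone_and_bounded(self, rng):
        p = rng.random(20)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestExhaustiveAucSmallGroups:
    def test_all_binary_tie_patterns_up_to_six(self):
        # every {0,1} score assignment for all group sizes <= 6
        for n1, n2 in itertools.product(range(1, 7), repeat=2):
            for bits in range(2 ** (n1 + n2)):
                scores = np.array([(bits >> k) & 1 for k in range(n1 + n2)],
                                  dtype=float)
                labels = np.r_[np.ones(n1, bool), np.zeros(n2, bool)]
                r = roc_auc(scores, labels, n_boot=0)
                oracle = pairwise_auc_oracle(scores[:n1], scores[n1:])
                assert r.auc == pytest.approx(oracle, rel=1e-12)
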