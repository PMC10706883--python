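"""Group comparison, ROC prediction, correlation, and longitudinal monitoring.

The analysis mirrors a two-group (progressor vs stable) CKD study design:

* **Baseline comparison** — Shapiro-Wilk normality gate on each group; both
  normal → Welch (unequal-variance) two-sample t-test, otherwise
  Mann-Whitney U; two-sided, α = 0.05, no multiple-testing correction (an
  optional Benjamini-Hochberg helper is provided).
* **Prediction** — ROC AUC of a baseline measure for progression, computed
  by the rank (Mann-Whitney) formulation with mid-ranks for ties; 95% CI by
  stratified bootstrap; p-value from the normal approximation of U.
* **Association** — pairwise correlation matrix across pooled visit rows
  (Pearson when both columns pass normality, Spearman otherwise; either can
  be forced), and Spearman correlations of baseline measures with the eGFR
  slope.
* **Monitoring** — per-subject percentage change from baseline at Year 1
  and Year 2 (complete cases only); a cell is called significant when the
  mean change differs from zero (one-sample t) AND its magnitude exceeds
  the measure's published between-session coefficient of variation; the
  direction is mapped to "decline" or "improve" through the measure's
  decline polarity (TKV↓, ADC↓, T2*↓, perfusion↓, T1↑ = decline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DEFAULT_ALPHA",
    "DEFAULT_CV_TABLE",
    "DECLINE_POLARITY",
    "GroupComparison",
    "ROCResult",
    "ChangeReport",
    "compare_groups",
    "roc_auc",
    "correlation_matrix",
    "slope_correlation",
    "pct_change_report",
    "benjamini_hochberg",
]

DEFAULT_ALPHA = 0.05

#: Published-style short-term between-session CVs (%) used as the
#: detectable-change reference band for each measure.
DEFAULT_CV_TABLE = {
    "tkv": 3.0,
    "t1_cortex": 3.0, "t1_medulla": 3.0,
    "adc_cortex": 4.0, "adc_medulla": 4.0,
    "t2star_cortex": 6.0, "t2star_medulla": 6.0,
    "perfusion_cortex": 12.0, "perfusion_medulla": 12.0,
}

#: Direction of change associated with declining kidney function.
#: "decrease" — a reduction marks decline; "increase" — a rise marks decline.
DECLINE_POLARITY = {
    "tkv": "decrease",
    "adc_cortex": "decrease", "adc_medulla": "decrease",
    "t2star_cortex": "decrease", "t2star_medulla": "decrease",
    "perfusion_cortex": "decrease", "perfusion_medulla": "decrease",
    "t1_cortex": "increase", "t1_medulla": "increase",
}


@dataclass
class GroupComparison:
    measure: str
    n_a: int
    n_b: int
    central_a: float
    dispersion_a: float
    central_b: float
    dispersion_b: float
    test: str  # "t-test" or "mann-whitney"
    shapiro_p_a: float
    shapiro_p_b: float
    p_value: float
    normal: bool


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    higher_predicts_positive: bool
    n_positive: int
    n_negative: int
    n_boot: int
    seed: int

    @property
    def oriented_auc(self) -> float:
        """AUC in the progression-predicting direction (always ≥ 0.5)."""
        return self.auc if self.higher_predicts_positive else 1.0 - self.auc

    @property
    def oriented_ci(self) -> tuple[float, float]:
        if self.higher_predicts_positive:
            return (self.ci_low, self.ci_high)
        return (1.0 - self.ci_high, 1.0 - self.ci_low)

    def ci_excludes_chance(self) -> bool:
        return not (self.ci_low <= 0.5 <= self.ci_high)


@dataclass
class ChangeReport:
    table: pd.DataFrame  # per (group, measure, visit) cells
    pairwise: pd.DataFrame  # between-group and Y1-vs-Y2 comparisons
    alpha: float
    cv_table: dict[str, float] = field(default_factory=dict)


def _safe_shapiro(x: np.ndarray) -> float:
    """Shapiro-Wilk p; constant samples are reported as non-normal (p=0)."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return 0.0
    try:
        return float(sps.shapiro(x).pvalue)
    except ValueError:
        return 0.0


def compare_groups(
    values_a,
    values_b,
    alpha: float = DEFAULT_ALPHA,
    measure: str = "",
    force: str | None = None,
) -> GroupComparison:
    """Normality-gated two-group comparison (Welch t or Mann-Whitney U).

    Both groups passing Shapiro-Wilk at ``alpha`` selects the t-test;
    otherwise Mann-Whitney U (mid-rank ties, asymptotic p).  ``force`` may
    be "t-test" or "mann-whitney" to bypass the gate.  Requires n ≥ 3 per
    group.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("compare_groups requires at least 3 values per group")
    pa, pb = _safe_shapiro(a), _safe_shapiro(b)
    normal = (pa > alpha) and (pb > alpha)
    test = force or ("t-test" if normal else "mann-whitney")

    if test == "t-test":
        p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    else:
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0  # every observation tied: no evidence of a difference
        else:
            p = float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                       method="asymptotic").pvalue)
    if normal:
        ca, da = float(a.mean()), float(a.std(ddof=1))
        cb, db = float(b.mean()), float(b.std(ddof=1))
    else:
        ca, da = float(np.median(a)), float(np.subtract(*np.percentile(a, [75, 25])))
        cb, db = float(np.median(b)), float(np.subtract(*np.percentile(b, [75, 25])))
    return GroupComparison(
        measure=measure, n_a=a.size, n_b=b.size,
        central_a=ca, dispersion_a=da, central_b=cb, dispersion_b=db,
        test=test, shapiro_p_a=pa, shapiro_p_b=pb, p_value=p, normal=normal,
    )


def _auc_from_scores(pos: np.ndarray, neg: np.ndarray) -> float:
    """Rank-based AUC with the mid-rank tie convention: U / (n1 n2)."""
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r1 = ranks[: pos.size].sum()
    u = r1 - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_auc(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> ROCResult:
    """ROC AUC of ``scores`` for predicting the positive class.

    AUC is the probability that a random positive out-scores a random
    negative (ties count ½), equal to the Mann-Whitney U statistic divided
    by n₁n₂.  The CI is a stratified bootstrap percentile interval
    (positives and negatives resampled separately) and the p-value tests
    AUC = 0.5 via the normal approximation of U.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be represented")
    auc = _auc_from_scores(pos, neg)

    if n_boot <= 0:
        p = 1.0 if np.ptp(scores) == 0 else float(
            sps.mannwhitneyu(pos, neg, alternative="two-sided",
                             method="asymptotic").pvalue)
        return ROCResult(auc=auc, ci_low=float("nan"), ci_high=float("nan"),
                         p_value=p, higher_predicts_positive=auc >= 0.5,
                         n_positive=pos.size, n_negative=neg.size,
                         n_boot=0, seed=seed)

    rng = np.random.default_rng(seed)
    bp = pos[rng.integers(0, pos.size, size=(n_boot, pos.size))]
    bn = neg[rng.integers(0, neg.size, size=(n_boot, neg.size))]
    # pairwise comparison form of the mid-rank AUC, vectorised over resamples
    gt = (bp[:, :, None] > bn[:, None, :]).mean(axis=(1, 2))
    eq = (bp[:, :, None] == bn[:, None, :]).mean(axis=(1, 2))
    boot_auc = gt + 0.5 * eq
    q = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boot_auc, [q, 1.0 - q])
    lo, hi = min(lo, auc), max(hi, auc)

    if np.ptp(scores) == 0:
        p = 1.0
    else:
        p = float(sps.mannwhitneyu(pos, neg, alternative="two-sided",
                                   method="asymptotic").pvalue)
    return ROCResult(
        auc=auc, ci_low=float(lo), ci_high=float(hi), p_value=p,
        higher_predicts_positive=auc >= 0.5,
        n_positive=pos.size, n_negative=neg.size, n_boot=n_boot, seed=seed,
    )


def _pairwise_corr(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    else:
        r, p = sps.spearmanr(x, y)
    return float(r), float(p)


def correlation_matrix(
    table: pd.DataFrame,
    method: str = "auto",
    alpha: float = DEFAULT_ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise correlations across pooled rows with per-pair method choice.

    ``method`` is "auto" (Pearson when both columns pass Shapiro-Wilk on
    the pairwise-complete rows, Spearman otherwise), "pearson" or
    "spearman".  Missing data are handled pairwise-complete.  Returns
    (r, p, method) DataFrames; constant columns yield NaN.
    """
    cols = list(table.columns)
    n = len(cols)
    r = pd.DataFrame(np.eye(n), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((n, n)), index=cols, columns=cols)
    m = pd.DataFrame([[""] * n for _ in range(n)], index=cols, columns=cols)
    for i in range(n):
        for j in range(i + 1, n):
            sub = table[[cols[i], cols[j]]].dropna()
            x = sub[cols[i]].to_numpy(dtype=float)
            y = sub[cols[j]].to_numpy(dtype=float)
            if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                rij, pij, mij = np.nan, np.nan, "undefined"
            else:
                if method == "auto":
                    mij = ("pearson"
                           if _safe_shapiro(x) > alpha and _safe_shapiro(y) > alpha
                           else "spearman")
                else:
                    mij = method
                rij, pij = _pairwise_corr(x, y, mij)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
            m.iloc[i, j] = m.iloc[j, i] = mij
    return r, p, m


def slope_correlation(
    measures: pd.DataFrame,
    slopes,
) -> pd.DataFrame:
    """Spearman correlation of each measure column with the eGFR slope.

    Constant measures are flagged (NaN R).  Returns a DataFrame with one
    row per measure: R, p, n.
    """
    slopes = np.asarray(slopes, dtype=float)
    rows = []
    for col in measures.columns:
        x = measures[col].to_numpy(dtype=float)
        keep = np.isfinite(x) & np.isfinite(slopes)
        if keep.sum() < 3 or np.ptp(x[keep]) == 0:
            rows.append({"measure": col, "spearman_r": np.nan,
                         "p_value": np.nan, "n": int(keep.sum())})
            continue
        r, p = sps.spearmanr(x[keep], slopes[keep])
        rows.append({"measure": col, "spearman_r": float(r),
                     "p_value": float(p), "n": int(keep.sum())})
    return pd.DataFrame(rows)


def _one_sample_p(changes: np.ndarray) -> float:
    if changes.size < 2 or np.ptp(changes) == 0:
        return 1.0 if np.allclose(changes, 0) else (0.0 if changes.size >= 2 else 1.0)
    return float(sps.ttest_1samp(changes, 0.0).pvalue)


def pct_change_report(
    summaries: pd.DataFrame,
    cv_table: dict[str, float] | None = None,
    polarity: dict[str, str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    visits: tuple[str, ...] = ("baseline", "year1", "year2"),
) -> ChangeReport:
    """Percentage-change monitoring report with heat-map categories.

    ``summaries`` is tidy with columns (subject, group, visit, measure,
    value).  Only subjects observed at every visit in ``visits`` are
    analysed (complete cases).  For each (group, measure, follow-up visit)
    the per-subject changes ``100 (x_t - x_0)/x_0`` are tested against zero
    (one-sample t) and the cell is categorised:

    * ``no-change`` when p ≥ α or |mean change| ≤ reference CV;
    * otherwise ``decline`` or ``improve`` according to the measure's
      decline polarity.

    Between-group comparisons of the changes at each follow-up, and
    Year 1 vs Year 2 paired comparisons within each group, are returned in
    ``pairwise``.
    """
    cv_table = dict(DEFAULT_CV_TABLE if cv_table is None else cv_table)
    polarity = dict(DECLINE_POLARITY if polarity is None else polarity)
    baseline_visit, *follow_ups = visits

    # Complete-case filter: subject must appear at every visit.
    have = summaries.groupby("subject")["visit"].agg(lambda v: set(v))
    complete = have[have.apply(lambda s: set(visits) <= s)].index
    data = summaries[summaries["subject"].isin(complete)]

    wide = data.pivot_table(index=["subject", "group", "measure"],
                            columns="visit", values="value").reset_index()
    for v in follow_ups:
        wide[f"pct_{v}"] = 100.0 * (wide[v] - wide[baseline_visit]) / wide[baseline_visit]

    rows, pair_rows = [], []
    groups = sorted(wide["group"].unique())
    for measure in sorted(wide["measure"].unique()):
        cv = cv_table.get(measure, np.nan)
        pol = polarity.get(measure, "decrease")
        sub_m = wide[wide["measure"] == measure]
        for v in follow_ups:
            per_group = {}
            for g in groups:
                changes = sub_m.loc[sub_m["group"] == g, f"pct_{v}"].dropna().to_numpy()
                per_group[g] = changes
                if changes.size == 0:
                    continue
                mean = float(changes.mean())
                p = _one_sample_p(changes)
                exceeds = bool(np.isfinite(cv) and abs(mean) > cv)
                if p < alpha and exceeds:
                    declining = (mean < 0) == (pol == "decrease")
                    category = "decline" if declining else "improve"
                else:
                    category = "no-change"
                rows.append({
                    "group": g, "measure": measure, "visit": v,
                    "n": int(changes.size), "mean_pct_change": mean,
                    "sd_pct_change": float(changes.std(ddof=1))
                    if changes.size > 1 else np.nan,
                    "p_vs_zero": p, "reference_cv_pct": cv,
                    "exceeds_cv": exceeds, "category": category,
                })
            if len(groups) == 2 and all(per_group[g].size >= 3 for g in groups):
                gc = compare_groups(per_group[groups[0]], per_group[groups[1]],
                                    alpha=alpha, measure=measure)
                pair_rows.append({
                    "measure": measure, "comparison": f"{groups[0]}_vs_{groups[1]}",
                    "visit": v, "p_value": gc.p_value, "test": gc.test,
                })
        if len(follow_ups) == 2:
            for g in groups:
                gsub = sub_m[sub_m["group"] == g]
                d1 = gsub[f"pct_{follow_ups[0]}"].to_numpy(dtype=float)
                d2 = gsub[f"pct_{follow_ups[1]}"].to_numpy(dtype=float)
                keep = np.isfinite(d1) & np.isfinite(d2)
                if keep.sum() >= 2 and np.ptp(d2[keep] - d1[keep]) > 0:
                    p = float(sps.ttest_rel(d1[keep], d2[keep]).pvalue)
                    pair_rows.append({
                        "measure": measure, "comparison": f"{g}_y1_vs_y2",
                        "visit": "-".join(follow_ups), "p_value": p,
                        "test": "paired-t",
                    })
    return ChangeReport(
        table=pd.DataFrame(rows),
        pairwise=pd.DataFrame(pair_rows),
        alpha=alpha,
        cv_table=cv_table,
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; not applied by default)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
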