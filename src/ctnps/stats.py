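"""Statistical battery for image-quality tables.

Covers the tests run on the ROI Hounsfield-unit and Likert-score tables:
Lilliefors-corrected Kolmogorov-Smirnov normality screening, Levene's
homoscedasticity test, one-way ANOVA (from raw groups or printed summary
statistics), Bonferroni-corrected pairwise comparisons, paired t, the
Wilcoxon signed-rank test with tie-corrected normal approximation, one-way
repeated-measures ANOVA with the Greenhouse-Geisser correction, partial
eta squared, and ordinal descriptives (Mdn (IQR) Mean +- SD).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairwiseComparison",
    "RMAnovaResult",
    "lilliefors_ks",
    "levene_test",
    "oneway_anova",
    "oneway_anova_from_summary",
    "bonferroni_pairwise",
    "paired_t",
    "wilcoxon_signed_rank",
    "rm_anova_gg",
    "partial_eta_sq",
    "summarize_ordinal",
]


@dataclass(frozen=True)
class PairwiseComparison:
    """One Bonferroni-corrected pairwise contrast of group means."""

    group_1: str
    group_2: str
    mean_difference: float
    ci_low: float
    ci_high: float
    adjusted_p: float
    sem: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean_difference <= self.ci_high):
            raise ValueError("confidence interval must bracket the mean difference")
        if not (0.0 <= self.adjusted_p <= 1.0):
            raise ValueError("adjusted p must be a probability")


@dataclass(frozen=True)
class RMAnovaResult:
    """Repeated-measures ANOVA result with Greenhouse-Geisser correction."""

    F: float
    df1: float
    df2: float
    p: float
    epsilon_gg: float
    partial_eta_sq: float


def _ks_distance_to_normal(x: np.ndarray) -> float:
    """KS distance of a sample to the normal with its own mean and SD."""
    n = x.size
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    return float(max(d_plus, d_minus))


def lilliefors_ks(
    sample: Sequence[float], n_reps: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Lilliefors-corrected KS test of normality with a Monte-Carlo null.

    The KS distance is computed against the normal distribution with the
    sample's estimated mean and SD; because parameters are estimated, the
    null distribution of D is simulated (``n_reps`` standard-normal samples
    of the same size, seeded).  Returns ``(D, p)``.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    if x.std(ddof=1) == 0:
        raise ValueError("sample has zero variance")
    d_obs = _ks_distance_to_normal(x)
    rng = np.random.default_rng(seed)
    n = x.size
    sims = rng.standard_normal((n_reps, n))
    sims = np.sort((sims - sims.mean(axis=1, keepdims=True)) / sims.std(axis=1, ddof=1, keepdims=True), axis=1)
    cdf = sps.norm.cdf(sims)
    i = np.arange(1, n + 1)
    d_sim = np.maximum((i / n - cdf).max(axis=1), (cdf - (i - 1) / n).max(axis=1))
    p = (1.0 + np.count_nonzero(d_sim >= d_obs)) / (n_reps + 1.0)
    return d_obs, float(p)


def levene_test(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical (mean-centered) Levene test of equal variances."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    w, p = sps.levene(*arrays, center="mean")
    return float(w), float(p)


def oneway_anova(groups: Sequence[Sequence[float]]) -> tuple[float, int, int, float]:
    """One-way between-groups ANOVA; returns (F, df1, df2, p)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    f, p = sps.f_oneway(*arrays)
    return float(f), k - 1, n_total - k, float(p)


def oneway_anova_from_summary(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int]
) -> tuple[float, int, int, float]:
    """One-way ANOVA from printed group summaries (mean, SD, n) per group."""
    m = np.asarray(means, dtype=float)
    s = np.asarray(sds, dtype=float)
    n = np.asarray(ns, dtype=int)
    if not (m.size == s.size == n.size) or m.size < 2:
        raise ValueError("need matching summaries for >= 2 groups")
    if np.any(n < 2) or np.any(s < 0):
        raise ValueError("each group needs n >= 2 and SD >= 0")
    n_total = int(n.sum())
    grand = float(np.sum(n * m) / n_total)
    ss_between = float(np.sum(n * (m - grand) ** 2))
    ss_within = float(np.sum((n - 1) * s ** 2))
    df1, df2 = m.size - 1, n_total - m.size
    f = (ss_between / df1) / (ss_within / df2)
    return float(f), df1, df2, float(sps.f.sf(f, df1, df2))


def bonferroni_pairwise(
    groups: dict[str, Sequence[float]], alpha: float = 0.05
) -> list[PairwiseComparison]:
    """All ordered pairwise mean differences with Bonferroni adjustment.

    The standard error uses the pooled within-group mean square from the
    one-way ANOVA; confidence intervals use the t distribution on the
    within df at level alpha/(2m) with m = k(k-1)/2 unordered pairs, and
    adjusted p = min(1, m * p_unadjusted).
    """
    labels = list(groups)
    arrays = {lab: np.asarray(groups[lab], dtype=float) for lab in labels}
    if len(labels) < 2 or any(a.size < 2 for a in arrays.values()):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    k = len(labels)
    m = k * (k - 1) // 2
    n_total = sum(a.size for a in arrays.values())
    df_within = n_total - k
    ms_within = sum((a.size - 1) * a.var(ddof=1) for a in arrays.values()) / df_within
    t_crit = sps.t.ppf(1.0 - alpha / (2.0 * m), df_within)
    out: list[PairwiseComparison] = []
    for a_lab in labels:
        for b_lab in labels:
            if a_lab == b_lab:
                continue
            a, b = arrays[a_lab], arrays[b_lab]
            diff = float(a.mean() - b.mean())
            sem = float(np.sqrt(ms_within * (1.0 / a.size + 1.0 / b.size)))
            if sem > 0:
                t_stat = diff / sem
                p_un = 2.0 * sps.t.sf(abs(t_stat), df_within)
            else:
                p_un = 1.0
            out.append(
                PairwiseComparison(
                    group_1=a_lab,
                    group_2=b_lab,
                    mean_difference=diff,
                    ci_low=diff - t_crit * sem,
                    ci_high=diff + t_crit * sem,
                    adjusted_p=min(1.0, m * p_un),
                    sem=sem,
                )
            )
    return out


def paired_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, int, float]:
    """Paired two-sided t test; returns (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    if np.all(a == b):
        return 0.0, a.size - 1, 1.0  # no differences at all
    res = sps.ttest_rel(a, b)
    return float(res.statistic), a.size - 1, float(res.pvalue)


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; ties receive midranks; the two-sided p
    comes from the normal approximation with tie-corrected variance and no
    continuity correction.  Returns ``(W, Z, p)`` where W is the positive
    rank sum.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n < 5:
        raise ValueError("need >= 5 non-zero paired differences")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / 48.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var_w <= 0:
        raise ValueError("degenerate variance (all differences tied to zero)")
    z = (w_pos - mean_w) / np.sqrt(var_w)
    p = 2.0 * sps.norm.sf(abs(z))
    return w_pos, float(z), float(min(1.0, p))


def _gg_epsilon(wide: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of conditions."""
    k = wide.shape[1]
    if k == 2:
        return 1.0
    s = np.cov(wide, rowvar=False)
    c = np.eye(k) - np.ones((k, k)) / k
    sc = c @ s @ c
    num = np.trace(sc) ** 2
    den = (k - 1) * np.trace(sc @ sc)
    eps = float(num / den)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_gg(wide: np.ndarray) -> RMAnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``wide`` is an (n_subjects, k_conditions) matrix with a complete grid.
    Degrees of freedom are multiplied by the GG epsilon estimated from the
    sample covariance of the conditions (epsilon = 1 leaves them unchanged,
    and k = 2 forces epsilon = 1); partial eta squared is reported via the
    F-ratio identity, which is invariant to the correction.
    """
    wide = np.asarray(wide, dtype=float)
    if wide.ndim != 2 or wide.shape[0] < 2 or wide.shape[1] < 2:
        raise ValueError("need an (n_subjects >= 2, k_conditions >= 2) matrix")
    if not np.all(np.isfinite(wide)):
        raise ValueError("repeated-measures grid must be complete and finite")
    n, k = wide.shape
    grand = wide.mean()
    cond_means = wide.mean(axis=0)
    subj_means = wide.mean(axis=1)
    ss_cond = n * float(np.sum((cond_means - grand) ** 2))
    ss_subj = k * float(np.sum((subj_means - grand) ** 2))
    ss_total = float(np.sum((wide - grand) ** 2))
    ss_err = ss_total - ss_cond - ss_subj
    df1_raw, df2_raw = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1_raw
    ms_err = ss_err / df2_raw
    f = ms_cond / ms_err if ms_err > 0 else np.inf
    eps = _gg_epsilon(wide)
    df1, df2 = eps * df1_raw, eps * df2_raw
    p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return RMAnovaResult(
        F=float(f),
        df1=df1,
        df2=df2,
        p=p,
        epsilon_gg=eps,
        partial_eta_sq=partial_eta_sq(f, df1, df2) if np.isfinite(f) else 1.0,
    )


def partial_eta_sq(F: float, df1: float, df2: float) -> float:
    """Partial eta squared from an F statistic: F*df1 / (F*df1 + df2)."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("need F >= 0 and positive degrees of freedom")
    return float(F * df1 / (F * df1 + df2))


def summarize_ordinal(scores: Sequence[float]) -> tuple[float, tuple[float, float], float, float]:
    """Ordinal descriptives: (median, (q1, q3), mean, sample SD)."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 scores (SD undefined otherwise)")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), (float(q1), float(q3)), float(x.mean()), float(x.std(ddof=1))
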