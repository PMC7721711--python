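"""Shared statistical kernels.

Small, exactly specified wrappers used by every analysis stage: one-sample and
paired t tests with effect sizes, Benjamini-Hochberg FDR, repeated-measures
one-way ANOVA, Tukey-Kramer pairwise comparisons on the (RM-)ANOVA error term,
rank-based one-vs-rest AUC, and the Fisher r-to-z transform.

All tests are two-sided. Cohen's d for a one-sample test is mean/sd; for a
paired test it is mean(diff)/sd(diff). Confidence intervals are t-based 95%
intervals on the mean (or mean difference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "one_sample_t",
    "paired_t",
    "fdr_bh",
    "rm_anova_oneway",
    "tukey_kramer",
    "auc_ovr",
    "fisher_z",
    "anderson_darling_normal",
]

R_CLIP = 1.0 - 1e-7


@dataclass
class TestResult:
    """A single statistical test: statistic, df, two-sided p, effect size, CI."""

    statistic: float
    df: float
    p: float
    effect_size: float
    ci_low: float
    ci_high: float
    kind: str = "t"
    zero_variance: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")
        if self.ci_low > self.ci_high:
            raise ValueError("CI lower bound exceeds upper bound")


def _t_result(diffs: np.ndarray, kind: str) -> TestResult:
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 1 or diffs.size < 2:
        raise ValueError("need at least 2 finite observations")
    if not np.all(np.isfinite(diffs)):
        raise ValueError("non-finite values in test input")
    n = diffs.size
    m = diffs.mean()
    sd = diffs.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        # Degenerate sample: infinite t. Report p = 0 (p = 1 if the mean is
        # also 0, up to roundoff) with a flag rather than NaN.
        nonzero = abs(m) > 1e-12
        t = np.inf * np.sign(m) if nonzero else 0.0
        p = 0.0 if nonzero else 1.0
        return TestResult(t, df, p, np.inf * np.sign(m) if nonzero else 0.0,
                          m, m, kind=kind, zero_variance=True)
    se = sd / np.sqrt(n)
    t = m / se
    p = 2.0 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(0.975, df)
    return TestResult(t, df, min(p, 1.0), m / sd, m - tcrit * se, m + tcrit * se,
                      kind=kind)


def one_sample_t(values, mu: float = 0.0) -> TestResult:
    """Classical one-sample t test of ``mean(values) == mu``."""
    return _t_result(np.asarray(values, dtype=float) - mu, kind="one-sample t")


def paired_t(a, b) -> TestResult:
    """Paired t test of ``mean(a - b) == 0``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have identical shape")
    return _t_result(a - b, kind="paired t")


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def rm_anova_oneway(data) -> TestResult:
    """One-way repeated-measures ANOVA on a subjects x conditions matrix.

    Partitions the within-subject variability into a condition effect and a
    subject-by-condition residual; F = MS_cond / MS_error with
    df = (k - 1, (k - 1)(n - 1)). Effect size is partial eta squared
    SS_cond / (SS_cond + SS_error).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D subjects x conditions matrix")
    n, k = X.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing or non-finite cells")
    grand = X.mean()
    ss_cond = n * np.sum((X.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((X.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    tol = 1e-12 * (np.abs(X).max() ** 2 + 1.0)
    if ms_err <= tol:
        effect = ms_cond > tol
        f = np.inf if effect else 0.0
        p = 0.0 if effect else 1.0
        return TestResult(f, df_cond, p, 1.0 if effect else 0.0,
                          np.nan, np.nan, kind="rm-anova", zero_variance=True,
                          extra={"df_error": df_err})
    f = ms_cond / ms_err
    p = sps.f.sf(f, df_cond, df_err)
    eta2 = ss_cond / (ss_cond + ss_err)
    return TestResult(f, df_cond, p, eta2, np.nan, np.nan, kind="rm-anova",
                      extra={"df_error": df_err, "ms_error": ms_err})


def tukey_kramer(data, repeated: bool = True):
    """All pairwise comparisons with studentized-range (Tukey-Kramer) correction.

    ``data`` is a subjects x groups matrix when ``repeated`` is True (the
    error term is the RM-ANOVA residual), or a list of independent group
    arrays otherwise. Returns a list of dicts with group indices, mean
    difference, q statistic and Tukey-adjusted p.
    """
    if repeated:
        X = np.asarray(data, dtype=float)
        n, k = X.shape
        if k < 2:
            raise ValueError("need at least 2 groups")
        anova = rm_anova_oneway(X)
        ms_err = anova.extra.get("ms_error", 0.0)
        df_err = anova.extra["df_error"]
        means = X.mean(axis=0)
        ns = np.full(k, n)
    else:
        groups = [np.asarray(g, dtype=float) for g in data]
        k = len(groups)
        if k < 2:
            raise ValueError("need at least 2 groups")
        ns = np.array([g.size for g in groups])
        means = np.array([g.mean() for g in groups])
        df_err = int(ns.sum() - k)
        ss_err = sum(np.sum((g - g.mean()) ** 2) for g in groups)
        ms_err = ss_err / df_err
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = np.sqrt(ms_err / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            if se == 0.0:
                q = np.inf if diff != 0 else 0.0
                p = 0.0 if diff != 0 else 1.0
            else:
                q = abs(diff) / se
                p = sps.studentized_range.sf(q, k, df_err)
            out.append({"i": i, "j": j, "mean_diff": diff, "q": q,
                        "p": float(min(max(p, 0.0), 1.0)), "df_error": df_err})
    return out


def auc_ovr(evidence, labels, classes=None) -> dict:
    """Rank-based (Mann-Whitney) one-vs-rest AUC per class, ties averaged.

    ``evidence`` is samples x classes; ``labels`` gives the true class per
    sample. Returns {class: auc}; classes absent from labels (or covering all
    samples) get NaN.
    """
    E = np.asarray(evidence, dtype=float)
    labels = np.asarray(labels)
    if classes is None:
        classes = sorted(set(labels.tolist()))
    aucs = {}
    for ci, c in enumerate(classes):
        pos = labels == c
        n_pos = int(pos.sum())
        n_neg = int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            aucs[c] = np.nan
            continue
        ranks = sps.rankdata(E[:, ci])
        u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
        aucs[c] = u / (n_pos * n_neg)
    return aucs


def fisher_z(r):
    """Fisher r-to-z: atanh with |r| clipped at 1 - 1e-7."""
    r = np.clip(np.asarray(r, dtype=float), -R_CLIP, R_CLIP)
    return np.arctanh(r)


def anderson_darling_normal(values) -> dict:
    """Anderson-Darling normality diagnostic (statistic and 5% critical value)."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        res = sps.anderson(np.asarray(values, dtype=float), dist="norm")
    crit = dict(zip(res.significance_level.tolist(), res.critical_values.tolist()))
    return {"statistic": float(res.statistic), "critical_5pct": float(crit.get(5.0, np.nan)),
            "normal_at_5pct": bool(res.statistic < crit.get(5.0, np.inf))}
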