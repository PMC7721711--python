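"""Trial-averaged evidence trajectories and windowed statistics.

Trajectories are built on a 30-TR unshifted window from trial onset. They are
baseline-corrected by subtracting each condition's mean over the first 6 TRs;
removal trajectories additionally subtract the maintain trajectory per
subject. Statistics run on a 15-TR analysis window from the operation onset
(TR 7) to the end of the longest fixation (TR 21), tiled by five 3-TR blocks:
a repeated-measures ANOVA across conditions and FDR-corrected pairwise paired
t tests per block, plus start-point detection (the first block whose evidence
is reliably below zero, or above the empirical baseline for the replacement
item).

The same machinery accepts item-level similarity trajectories — any
subjects x 30 array per condition goes through one code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import TrialTable
from .mvpa import EvidenceSeries
from .stats import fdr_bh, one_sample_t, paired_t, rm_anova_oneway

__all__ = [
    "TRAJECTORY_TRS",
    "BASELINE_TRS",
    "ANALYSIS_BLOCKS",
    "trial_average",
    "baseline_correct",
    "empirical_baseline",
    "removal_trajectories",
    "window_stats",
    "block_means",
    "find_start_point",
    "WindowStats",
]

TRAJECTORY_TRS = 30
BASELINE_TRS = 6
#: five 3-TR blocks tiling TRs 7..21 (1-based, inclusive), as 0-based slices
ANALYSIS_BLOCKS = tuple((6 + 3 * b, 9 + 3 * b) for b in range(5))

REMOVAL_CONDITIONS = ("replace_cat", "suppress", "clear")


def _traj_for_trial(ev: EvidenceSeries, run: int, onset0: int, cls,
                    window: int) -> np.ndarray | None:
    E = ev.runs[run]
    if onset0 + window > E.shape[0]:
        return None
    ci = ev.classes.index(cls)
    return E[onset0:onset0 + window, ci]


def trial_average(evidence: EvidenceSeries, design: TrialTable,
                  target: str = "item_category",
                  conditions=None, window: int = TRAJECTORY_TRS) -> dict:
    """Mean target-class evidence trajectory per condition for one subject.

    ``target`` selects whose category is tracked: the trial item's
    (``item_category``) or the replacement item's (``replacement_category``,
    replace trials only). Trials too close to the run end for a full window
    are excluded with a warning.
    """
    if target not in ("item_category", "replacement_category"):
        raise ValueError("target must be item_category or replacement_category")
    f = design.frame
    if conditions is not None:
        f = f[f["operation"].isin(conditions)]
    per_cond: dict = {}
    n_skipped = 0
    for _, t in f.iterrows():
        if target == "replacement_category":
            if t["operation"] not in ("replace_cat", "replace_subcat"):
                continue
            cls = _catalog().lookup(int(t["replacement_item"]))[0]
        else:
            cls = t["category"]
        traj = _traj_for_trial(evidence, int(t["run"]), int(t["onset"]) - 1,
                               cls, window)
        if traj is None:
            n_skipped += 1
            continue
        per_cond.setdefault(t["operation"], []).append(traj)
    if n_skipped:
        warnings.warn(f"{n_skipped} trial(s) excluded: window past run end")
    return {c: np.mean(np.vstack(v), axis=0) for c, v in per_cond.items()}


_CATALOG = None


def _catalog():
    global _CATALOG
    if _CATALOG is None:
        from .design import StimulusCatalog
        _CATALOG = StimulusCatalog()
    return _CATALOG


def baseline_correct(traj: np.ndarray, n_baseline: int = BASELINE_TRS) -> np.ndarray:
    """Subtract the mean over the first ``n_baseline`` TRs (last axis).

    Idempotent and difference-preserving: between-condition differences at any
    TR are unchanged only when conditions are corrected by their own baseline,
    as done here per trajectory.
    """
    traj = np.asarray(traj, dtype=float)
    if traj.shape[-1] < n_baseline:
        raise ValueError("trajectory shorter than the baseline window")
    return traj - traj[..., :n_baseline].mean(axis=-1, keepdims=True)


def empirical_baseline(evidence: EvidenceSeries, design: TrialTable,
                       seed: int = 0, window: int = TRAJECTORY_TRS) -> np.ndarray:
    """Irrelevant-category evidence trajectory, the replace-new comparator.

    For every suppress and clear trial, one of the two categories *not* shown
    on that trial is sampled (seeded) and its evidence series extracted; the
    average over all such trials (suppress and clear pooled) is returned.
    """
    rng = np.random.default_rng(seed)
    cats = [c for c in evidence.classes]
    f = design.frame[design.frame["operation"].isin(["suppress", "clear"])]
    if f.empty:
        raise ValueError("no suppress/clear trials for the empirical baseline")
    trajs = []
    for _, t in f.iterrows():
        others = [c for c in cats if c != t["category"]]
        cls = others[int(rng.integers(len(others)))]
        traj = _traj_for_trial(evidence, int(t["run"]), int(t["onset"]) - 1,
                               cls, window)
        if traj is not None:
            trajs.append(traj)
    return np.mean(np.vstack(trajs), axis=0)


def removal_trajectories(per_condition: dict) -> dict:
    """Subtract the maintain trajectory from each removal condition's.

    Operates per subject (apply before averaging across subjects). Maintain
    itself maps to identically zero.
    """
    if "maintain" not in per_condition:
        raise ValueError("maintain trajectory required as baseline")
    m = np.asarray(per_condition["maintain"], dtype=float)
    out = {}
    for cond, traj in per_condition.items():
        out[cond] = np.asarray(traj, dtype=float) - m
    return out


def block_means(traj: np.ndarray, blocks=ANALYSIS_BLOCKS) -> np.ndarray:
    """Mean over each 3-TR analysis block; last axis becomes length 5."""
    traj = np.asarray(traj, dtype=float)
    return np.stack([traj[..., a:b].mean(axis=-1) for a, b in blocks], axis=-1)


@dataclass
class WindowStats:
    """Per-block condition means, RM-ANOVA and FDR-corrected pairwise tests."""

    conditions: list
    means: dict                    # condition -> (n_subjects, 5)
    anova: list                    # per block TestResult
    pairwise: pd.DataFrame         # block, cond_a, cond_b, t, df, p, p_fdr, d
    extra: dict = field(default_factory=dict)


def window_stats(per_subject: dict) -> WindowStats:
    """Blockwise statistics over conditions.

    ``per_subject`` maps condition -> (n_subjects x 30) trajectory matrix.
    Per block: RM-ANOVA across conditions and all pairwise two-sided paired t
    tests, FDR-adjusted within block.
    """
    conditions = list(per_subject.keys())
    mats = {c: np.atleast_2d(np.asarray(per_subject[c], dtype=float))
            for c in conditions}
    n_subj = next(iter(mats.values())).shape[0]
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    bm = {c: block_means(mats[c]) for c in conditions}
    anova = []
    rows = []
    for b in range(len(ANALYSIS_BLOCKS)):
        X = np.column_stack([bm[c][:, b] for c in conditions])
        anova.append(rm_anova_oneway(X) if len(conditions) > 1 else None)
        pvals, meta = [], []
        for i in range(len(conditions)):
            for j in range(i + 1, len(conditions)):
                res = paired_t(X[:, i], X[:, j])
                pvals.append(res.p)
                meta.append((conditions[i], conditions[j], res))
        if pvals:
            adj = fdr_bh(pvals)
            for (ca, cb, res), pf in zip(meta, adj):
                rows.append({"block": b + 1, "cond_a": ca, "cond_b": cb,
                             "t": res.statistic, "df": res.df, "p": res.p,
                             "p_fdr": float(pf), "d": res.effect_size,
                             "ci_low": res.ci_low, "ci_high": res.ci_high})
    return WindowStats(conditions, bm, anova, pd.DataFrame(rows))


def find_start_point(per_subject: np.ndarray, mode: str = "below-zero",
                     baseline: np.ndarray | None = None,
                     alpha: float = 0.05):
    """First analysis block where the trajectory is reliably off its comparator.

    ``per_subject`` is (n_subjects x 30). ``below-zero`` runs one-sample t
    tests against 0 and requires a negative mean; ``above-baseline`` runs
    paired t tests against ``baseline`` (n_subjects x 30) and requires a
    positive mean difference. p-values are FDR-adjusted across the 5 blocks;
    returns the 1-based block index or None.
    """
    X = block_means(np.atleast_2d(np.asarray(per_subject, dtype=float)))
    if mode == "below-zero":
        results = [one_sample_t(X[:, b]) for b in range(X.shape[1])]
        signs = [np.mean(X[:, b]) < 0 for b in range(X.shape[1])]
    elif mode == "above-baseline":
        if baseline is None:
            raise ValueError("above-baseline mode needs a baseline trajectory")
        B = block_means(np.atleast_2d(np.asarray(baseline, dtype=float)))
        results = [paired_t(X[:, b], B[:, b]) for b in range(X.shape[1])]
        signs = [np.mean(X[:, b] - B[:, b]) > 0 for b in range(X.shape[1])]
    else:
        raise ValueError("mode must be 'below-zero' or 'above-baseline'")
    adj = fdr_bh([r.p for r in results])
    for b, (pf, ok) in enumerate(zip(adj, signs)):
        if pf < alpha and ok:
            return b + 1
    return None
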