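"""Within-subject multivoxel pattern classification.

The decoding recipe: assign a class label to each usable TR by shifting event
epochs forward by the hemodynamic lag (10 TRs at TR = 0.46 s), trim the first
10 TRs of each run, drop censored TRs, z-score each voxel within run, select
voxels with a one-way ANOVA across classes on the training folds (P < 0.05),
fit one-vs-rest L2-penalized logistic regression, and evaluate with
leave-one-run-out cross-validation. The per-class *evidence* is the sigmoid
output of that class's binary classifier, in [0, 1]. The L2 penalty can be
fixed or found by a two-step search: 8 penalties on an exponential grid from
0 to 10,000, then 10 on a linear grid bracketing the stage-1 winner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression

from .design import TrialTable
from .hemo import DEFAULT_LAG_TRS
from .simulate import VoxelDataset
from .stats import auc_ovr

__all__ = [
    "LabelSeries",
    "FeatureMask",
    "FittedClassifier",
    "EvidenceSeries",
    "CVResult",
    "build_shifted_labels",
    "zscore_runs",
    "stack_usable",
    "anova_feature_select",
    "fit_ovr_logistic",
    "search_penalty",
    "crossvalidate",
    "sliding_window_decode",
    "decode_timeseries",
    "STAGE1_PENALTY_GRID",
]

DEFAULT_TRIM_TRS = 10
STAGE1_PENALTY_GRID = (0.0, 1.0, 5.0, 25.0, 125.0, 625.0, 3125.0, 10000.0)


class LabelOverlapError(ValueError):
    pass


class EmptySelectionError(ValueError):
    pass


@dataclass
class LabelSeries:
    """Per-run, per-TR class labels (None = unlabeled) and usability flags."""

    labels: dict                      # run -> object array (T,)
    usable: dict                      # run -> bool array (T,)
    classes: list
    shift: int
    epoch: str

    @property
    def run_ids(self) -> list[int]:
        return sorted(self.labels.keys())

    def n_labeled(self) -> int:
        return int(sum(((l != None) & u).sum()           # noqa: E711
                       for l, u in zip(self.labels.values(), self.usable.values())))


@dataclass
class FeatureMask:
    indices: np.ndarray
    alpha: float
    fold: object = None

    def __post_init__(self):
        if self.indices.size == 0:
            raise EmptySelectionError("no voxel survived feature selection")


@dataclass
class FittedClassifier:
    """One-vs-rest L2 logistic regression over a feature mask."""

    classes: list
    weights: np.ndarray               # (n_classes, n_selected)
    intercepts: np.ndarray            # (n_classes,)
    lam: float
    mask: FeatureMask

    def evidence(self, X: np.ndarray) -> np.ndarray:
        """Per-class sigmoid evidence, samples x classes, each in [0, 1]."""
        Z = X[:, self.mask.indices] @ self.weights.T + self.intercepts
        return expit(Z)

    def predict(self, X: np.ndarray) -> np.ndarray:
        ev = self.evidence(X)
        return np.asarray(self.classes, dtype=object)[np.argmax(ev, axis=1)]


@dataclass
class EvidenceSeries:
    """Per-run (TR x class) evidence matrices from a fitted decoder."""

    runs: dict                        # run -> (T, n_classes)
    classes: list
    shifted: bool

    def __post_init__(self):
        for r, E in self.runs.items():
            if not np.all(np.isfinite(E)) or E.min() < 0 or E.max() > 1:
                raise ValueError(f"evidence out of [0, 1] in run {r}")


@dataclass
class CVResult:
    accuracy: float
    per_class_accuracy: dict
    auc: float
    per_class_auc: dict
    confusion: np.ndarray             # rows: true class proportions
    classes: list
    lam: float
    n_folds: int
    extra: dict = field(default_factory=dict)


def _epoch_windows(design: TrialTable, epoch: str, label_field: str):
    """Yield (run, start0, stop0, label) half-open 0-based epoch windows."""
    f = design.frame
    if epoch == "operation_fixation":
        for _, t in f.iterrows():
            s = int(t["onset"]) - 1 + int(t["stim_dur"])
            yield int(t["run"]), s, s + int(t["op_dur"]) + int(t["iti"]), t[label_field]
    elif epoch == "stimulus":
        for _, t in f.iterrows():
            s = int(t["onset"]) - 1
            yield int(t["run"]), s, s + int(t["stim_dur"]), t[label_field]
    elif epoch == "localizer_miniblock":
        # triplets of consecutive same-subcategory trials; 31-TR boxcar
        for run, g in f.groupby("run"):
            g = g.sort_values("onset").reset_index(drop=True)
            for i in range(0, len(g), 3):
                block = g.iloc[i:i + 3]
                if block["subcategory"].nunique() != 1:
                    raise ValueError("trials are not grouped in subcategory triplets")
                s = int(block["onset"].iloc[0]) - 1
                yield int(run), s, s + 31, block[label_field].iloc[0]
    else:
        raise ValueError(f"unknown epoch spec {epoch!r}")


def build_shifted_labels(design: TrialTable, epoch: str,
                         label_field: str = "category",
                         shift: int = DEFAULT_LAG_TRS,
                         trim: int = DEFAULT_TRIM_TRS,
                         censored: dict | None = None,
                         classes: list | None = None) -> LabelSeries:
    """Per-TR labels, shifted forward by the hemodynamic lag.

    A neural event at TR t labels TR t + shift; labels shifted past the run
    end are dropped; the first ``trim`` TRs of each run and censored TRs are
    unusable. ``classes`` restricts labelling to a subset (e.g. excluding the
    replace-subcategory condition).
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    labels = {r: np.full(design.run_lengths[r], None, dtype=object)
              for r in design.runs}
    for run, s, e, lab in _epoch_windows(design, epoch, label_field):
        if classes is not None and lab not in classes:
            continue
        T = design.run_lengths[run]
        lo, hi = min(s + shift, T), min(e + shift, T)
        seg = labels[run][lo:hi]
        clash = (seg != None) & (seg != lab)              # noqa: E711
        if np.any(clash):
            raise LabelOverlapError(
                f"shifted epochs overlap with conflicting labels in run {run}")
        labels[run][lo:hi] = lab
    usable = {}
    for r in design.runs:
        u = np.ones(design.run_lengths[r], dtype=bool)
        u[:trim] = False
        if censored is not None and r in censored:
            u[np.asarray(censored[r], dtype=bool)] = False
        usable[r] = u
        labels[r][~u] = None
    found = sorted({l for arr in labels.values() for l in arr if l is not None})
    return LabelSeries(labels, usable, classes=list(classes) if classes else found,
                       shift=shift, epoch=epoch)


def zscore_runs(data: VoxelDataset) -> VoxelDataset:
    """Z-score each voxel within run over its non-censored TRs."""
    runs = {}
    for r, X in data.runs.items():
        good = ~data.censored[r]
        mu = X[good].mean(axis=0)
        sd = X[good].std(axis=0)
        sd[sd == 0] = 1.0
        runs[r] = (X - mu) / sd
    return VoxelDataset(runs, data.tr_seconds, data.coords, data.hemisphere,
                        data.roi_vvs, {r: c.copy() for r, c in data.censored.items()})


def stack_usable(data: VoxelDataset, labels: LabelSeries,
                 runs: list | None = None):
    """Gather labeled, usable TRs into (X, y, run_id) sample arrays."""
    Xs, ys, rs = [], [], []
    for r in (runs if runs is not None else labels.run_ids):
        lab = labels.labels[r]
        keep = (lab != None) & labels.usable[r]           # noqa: E711
        if keep.any():
            Xs.append(data.runs[r][keep])
            ys.append(lab[keep])
            rs.append(np.full(int(keep.sum()), r))
    if not Xs:
        return (np.empty((0, data.n_voxels)), np.empty(0, dtype=object),
                np.empty(0, dtype=int))
    return np.vstack(Xs), np.concatenate(ys), np.concatenate(rs)


def anova_feature_select(X: np.ndarray, y: np.ndarray,
                         alpha: float = 0.05, fold=None) -> FeatureMask:
    """Voxels whose one-way ANOVA across classes gives p < alpha.

    Zero-variance voxels are always excluded. Call with training-fold samples
    only; the fold id is recorded on the mask.
    """
    if len(set(y.tolist())) < 2:
        raise ValueError("need at least 2 classes for feature selection")
    var = X.var(axis=0)
    finite = var > 0
    if not finite.any():
        raise EmptySelectionError("all voxels have zero variance")
    pv = np.ones(X.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = f_classif(X[:, finite], y)
    pv[finite] = np.nan_to_num(p, nan=1.0)
    idx = np.flatnonzero(finite & (pv < alpha))
    return FeatureMask(idx, alpha, fold=fold)


def fit_ovr_logistic(X: np.ndarray, y: np.ndarray, mask: FeatureMask,
                     lam: float = 50.0) -> FittedClassifier:
    """One binary L2 logistic classifier per class (class vs rest).

    Minimizes sum of logistic losses + lam * ||w||^2 / 2 (lam = 0 is
    unpenalized); evidence is sigmoid(w . x + b).
    """
    if lam < 0:
        raise ValueError("penalty must be >= 0")
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to fit")
    Xm = X[:, mask.indices]
    W = np.zeros((len(classes), Xm.shape[1]))
    b = np.zeros(len(classes))
    for i, c in enumerate(classes):
        yi = (y == c).astype(int)
        if lam > 0:
            clf = LogisticRegression(penalty="l2", C=1.0 / lam, solver="lbfgs",
                                     tol=1e-6, max_iter=2000)
        else:
            clf = LogisticRegression(penalty=None, solver="lbfgs", tol=1e-6,
                                     max_iter=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xm, yi)
        W[i] = clf.coef_[0]
        b[i] = clf.intercept_[0]
    return FittedClassifier(classes, W, b, lam, mask)


def crossvalidate(data: VoxelDataset, labels: LabelSeries,
                  lam: float = 50.0, alpha: float = 0.05) -> CVResult:
    """Leave-one-run-out cross-validation.

    Per fold: ANOVA feature selection on the training runs, one-vs-rest fit,
    decoding of the held-out run. Accuracy and AUC are macro-averaged over
    classes; the confusion matrix is row-normalized.
    """
    run_ids = [r for r in labels.run_ids
               if ((labels.labels[r] != None) & labels.usable[r]).any()]  # noqa: E711
    if len(run_ids) < 2:
        raise ValueError("need at least 2 runs with usable labels")
    classes = labels.classes
    cindex = {c: i for i, c in enumerate(classes)}
    K = len(classes)
    conf = np.zeros((K, K))
    ev_all, y_all = [], []
    n_folds = 0
    for test_run in run_ids:
        train_runs = [r for r in run_ids if r != test_run]
        Xtr, ytr, _ = stack_usable(data, labels, train_runs)
        Xte, yte, _ = stack_usable(data, labels, [test_run])
        if yte.size == 0:
            warnings.warn(f"fold {test_run} has no test labels; skipped")
            continue
        mask = anova_feature_select(Xtr, ytr, alpha, fold=test_run)
        clf = fit_ovr_logistic(Xtr, ytr, mask, lam)
        ev = clf.evidence(Xte)
        pred = np.asarray(clf.classes, dtype=object)[np.argmax(ev, axis=1)]
        for t, p in zip(yte, pred):
            conf[cindex[t], cindex[p]] += 1
        # align evidence columns to the global class order
        ev_ordered = np.zeros((ev.shape[0], K))
        for i, c in enumerate(clf.classes):
            ev_ordered[:, cindex[c]] = ev[:, i]
        ev_all.append(ev_ordered)
        y_all.append(yte)
        n_folds += 1
    if n_folds == 0:
        raise ValueError("all folds empty")
    row_sums = conf.sum(axis=1, keepdims=True)
    per_class_acc = {c: (conf[i, i] / row_sums[i, 0]) if row_sums[i, 0] else np.nan
                     for i, c in enumerate(classes)}
    conf_norm = np.divide(conf, row_sums, out=np.zeros_like(conf),
                          where=row_sums > 0)
    aucs = auc_ovr(np.vstack(ev_all), np.concatenate(y_all), classes)
    acc_vals = [v for v in per_class_acc.values() if np.isfinite(v)]
    auc_vals = [v for v in aucs.values() if np.isfinite(v)]
    return CVResult(float(np.mean(acc_vals)), per_class_acc,
                    float(np.mean(auc_vals)), aucs, conf_norm, classes, lam,
                    n_folds)


def search_penalty(data: VoxelDataset, labels: LabelSeries,
                   alpha: float = 0.05,
                   stage1_grid=STAGE1_PENALTY_GRID,
                   stage2_size: int = 10) -> float:
    """Two-step L2 penalty search by cross-validated mean accuracy.

    Stage 1 scans an exponential grid from 0 to 10,000; stage 2 scans a
    linear grid bracketing the stage-1 winner between its grid neighbours.
    Ties break toward the smaller penalty.
    """
    grid1 = sorted(stage1_grid)
    scores = {}
    for lam in grid1:
        scores[lam] = crossvalidate(data, labels, lam=lam, alpha=alpha).accuracy
    best1 = min(grid1, key=lambda l: (-scores[l], l))
    i = grid1.index(best1)
    lo = grid1[i - 1] if i > 0 else grid1[0]
    hi = grid1[i + 1] if i < len(grid1) - 1 else grid1[-1]
    for lam in np.linspace(lo, hi, stage2_size):
        lam = float(lam)
        if lam not in scores:
            scores[lam] = crossvalidate(data, labels, lam=lam, alpha=alpha).accuracy
    return min(scores, key=lambda l: (-scores[l], l))


def decode_timeseries(clf: FittedClassifier, data: VoxelDataset) -> EvidenceSeries:
    """Per-class evidence at every TR of every run (unshifted alignment)."""
    if clf.mask.indices.max() >= data.n_voxels:
        raise ValueError("classifier mask does not fit this dataset's voxel axis")
    return EvidenceSeries({r: clf.evidence(X) for r, X in data.runs.items()},
                          clf.classes, shifted=False)


def sliding_window_decode(data: VoxelDataset, design: TrialTable,
                          label_field: str = "operation",
                          classes: list | None = None,
                          train_window: int = 5,
                          eval_range: tuple[int, int] = (1, 31),
                          shift: int = DEFAULT_LAG_TRS,
                          lam: float = 50.0, alpha: float = 0.05,
                          trim: int = DEFAULT_TRIM_TRS):
    """Sliding-time-window decoding along the trial.

    For each trial-relative TR t in ``eval_range`` (1-based, pre-shift), a
    classifier is trained on samples from the ``train_window`` TRs centred on
    t (shifted by the lag) and decodes TR t of held-out-run trials. Returns a
    list of dicts with per-TR cross-validated accuracy and mean evidence of
    the true class. Trials whose window extends past the run end are skipped
    at that TR.
    """
    if train_window % 2 == 0:
        raise ValueError("train_window must be odd")
    half = train_window // 2
    f = design.frame
    if classes is not None:
        f = f[f[label_field].isin(classes)]
    trials = [(int(t["run"]), int(t["onset"]) - 1, t[label_field])
              for _, t in f.iterrows()]
    run_ids = sorted({r for r, _, _ in trials})
    results = []
    for t_rel in range(eval_range[0], eval_range[1] + 1):
        # gather one sample per trial per window position
        samples = {r: ([], []) for r in run_ids}
        eval_samples = {r: ([], []) for r in run_ids}
        for run, onset0, lab in trials:
            T = design.run_lengths[run]
            w_trs = [onset0 + (t_rel - 1) + d + shift for d in range(-half, half + 1)]
            e_tr = onset0 + (t_rel - 1) + shift
            if min(w_trs) < trim or max(w_trs) >= T or e_tr >= T:
                continue
            for w in w_trs:
                samples[run][0].append(w)
                samples[run][1].append(lab)
            eval_samples[run][0].append(e_tr)
            eval_samples[run][1].append(lab)
        correct, total, ev_true = 0, 0, []
        for test_run in run_ids:
            Xtr = np.vstack([data.runs[r][samples[r][0]]
                             for r in run_ids if r != test_run and samples[r][0]]) \
                if any(samples[r][0] for r in run_ids if r != test_run) else None
            if Xtr is None or not eval_samples[test_run][0]:
                continue
            ytr = np.concatenate([np.asarray(samples[r][1], dtype=object)
                                  for r in run_ids if r != test_run and samples[r][1]])
            if len(set(ytr.tolist())) < 2:
                continue
            try:
                mask = anova_feature_select(Xtr, ytr, alpha, fold=test_run)
            except EmptySelectionError:
                continue
            clf = fit_ovr_logistic(Xtr, ytr, mask, lam)
            Xte = data.runs[test_run][eval_samples[test_run][0]]
            yte = np.asarray(eval_samples[test_run][1], dtype=object)
            ev = clf.evidence(Xte)
            pred = np.asarray(clf.classes, dtype=object)[np.argmax(ev, axis=1)]
            correct += int((pred == yte).sum())
            total += yte.size
            ci = {c: i for i, c in enumerate(clf.classes)}
            ev_true.extend(ev[k, ci[yte[k]]] for k in range(yte.size)
                           if yte[k] in ci)
        results.append({"t": t_rel,
                        "accuracy": correct / total if total else np.nan,
                        "evidence_true": float(np.mean(ev_true)) if ev_true else np.nan,
                        "n": total})
    return results
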