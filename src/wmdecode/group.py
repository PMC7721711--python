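"""Between-subject operation decoding.

Two routes. *Anatomical*: subjects share a voxel axis; the first half of the
runs drives feature selection (top-k voxels by ANOVA F across operations,
subject to a p threshold), PCA reduces the selected features (default 70
components, fit on the training subjects per fold), and a one-vs-rest L2
logistic classifier (fixed penalty 50) is evaluated with
leave-one-subject-out cross-validation on the other half of the runs.
*Hyperaligned*: per-subject top-k voxels per hemisphere are mapped into a
common functional space by a two-pass iterative orthogonal Procrustes
procedure fit on the selection half; the classification half is transformed
with the frozen transforms, PCA-reduced, and cross-validated the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import orthogonal_procrustes
from sklearn.decomposition import PCA
from sklearn.feature_selection import f_classif

from .mvpa import (CVResult, FeatureMask, LabelSeries, fit_ovr_logistic,
                   stack_usable)
from .simulate import VoxelDataset
from .stats import auc_ovr

__all__ = [
    "split_halves",
    "select_group_features",
    "pca_reduce",
    "loso_crossvalidate",
    "hyperalign",
    "AlignmentTransform",
    "hyperaligned_crossvalidate",
]

GROUP_PENALTY = 50.0
GROUP_TOP_K = 10_000
GROUP_ALPHA = 1e-3
HYPER_TOP_K_PER_HEMI = 5_000
HYPER_ALPHA = 5e-3
PCA_COMPONENTS = 70


def split_halves(run_ids: list) -> tuple[list, list]:
    """First half of runs -> selection, second half -> classification."""
    runs = sorted(run_ids)
    h = len(runs) // 2
    if h == 0:
        raise ValueError("need at least 2 runs to split into halves")
    return runs[:h], runs[h:]


def _stack_subjects(datasets: list, labels: list, runs: list):
    Xs, ys = [], []
    for d, l in zip(datasets, labels):
        X, y, _ = stack_usable(d, l, runs)
        Xs.append(X)
        ys.append(y)
    return Xs, ys


def select_group_features(datasets: list, labels: list, selection_runs: list,
                          k: int = GROUP_TOP_K,
                          alpha: float = GROUP_ALPHA) -> FeatureMask:
    """Top-k voxels by ANOVA F across classes on concatenated selection-half
    data; only p < alpha survivors are ranked. If fewer than k survive, all
    survivors are returned with a warning."""
    Xs, ys = _stack_subjects(datasets, labels, selection_runs)
    X, y = np.vstack(Xs), np.concatenate(ys)
    var = X.var(axis=0)
    F = np.full(X.shape[1], -np.inf)
    p = np.ones(X.shape[1])
    finite = var > 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F[finite], p[finite] = f_classif(X[:, finite], y)
    F = np.nan_to_num(F, nan=-np.inf)
    survivors = np.flatnonzero(finite & (p < alpha))
    if survivors.size == 0:
        raise ValueError("no voxel survived group feature selection")
    if survivors.size < k:
        warnings.warn(f"only {survivors.size} voxels survive p < {alpha}; "
                      f"returning all of them")
        top = survivors
    else:
        order = np.argsort(F[survivors])[::-1]
        top = survivors[order[:k]]
    return FeatureMask(np.sort(top), alpha)


def pca_reduce(train: np.ndarray, tests: list, k: int = PCA_COMPONENTS):
    """Fit PCA on training data, project training and test sets."""
    if k > min(train.shape):
        raise ValueError(f"k={k} exceeds min(samples, features)={min(train.shape)}")
    pca = PCA(n_components=k, svd_solver="full")
    tr = pca.fit_transform(train)
    return tr, [pca.transform(t) for t in tests], pca


def _aggregate_folds(folds, classes):
    cindex = {c: i for i, c in enumerate(classes)}
    K = len(classes)
    conf = np.zeros((K, K))
    ev_all, y_all = [], []
    for ev, yte, fold_classes in folds:
        pred = np.asarray(fold_classes, dtype=object)[np.argmax(ev, axis=1)]
        for t, pr in zip(yte, pred):
            conf[cindex[t], cindex[pr]] += 1
        evo = np.zeros((ev.shape[0], K))
        for i, c in enumerate(fold_classes):
            evo[:, cindex[c]] = ev[:, i]
        ev_all.append(evo)
        y_all.append(yte)
    rs = conf.sum(axis=1, keepdims=True)
    per_acc = {c: conf[i, i] / rs[i, 0] if rs[i, 0] else np.nan
               for i, c in enumerate(classes)}
    aucs = auc_ovr(np.vstack(ev_all), np.concatenate(y_all), classes)
    acc = float(np.mean([v for v in per_acc.values() if np.isfinite(v)]))
    auc = float(np.mean([v for v in aucs.values() if np.isfinite(v)]))
    confn = np.divide(conf, rs, out=np.zeros_like(conf), where=rs > 0)
    return acc, per_acc, auc, aucs, confn


def loso_crossvalidate(datasets: list, labels: list,
                       k_features: int = GROUP_TOP_K,
                       k_components: int = PCA_COMPONENTS,
                       lam: float = GROUP_PENALTY,
                       alpha: float = GROUP_ALPHA) -> CVResult:
    """Anatomically aligned leave-one-subject-out operation decoding."""
    n = len(datasets)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    sel_runs, clf_runs = split_halves(datasets[0].run_ids)
    mask = select_group_features(datasets, labels, sel_runs, k_features, alpha)
    Xs, ys = _stack_subjects(datasets, labels, clf_runs)
    Xs = [X[:, mask.indices] for X in Xs]
    classes = sorted({c for y in ys for c in y.tolist()})
    folds = []
    for test in range(n):
        train_idx = [i for i in range(n) if i != test]
        Xtr = np.vstack([Xs[i] for i in train_idx])
        ytr = np.concatenate([ys[i] for i in train_idx])
        k = min(k_components, min(Xtr.shape))
        tr, (te,), _ = pca_reduce(Xtr, [Xs[test]], k)
        fm = FeatureMask(np.arange(tr.shape[1]), 1.0)
        clf = fit_ovr_logistic(tr, ytr, fm, lam)
        folds.append((clf.evidence(te), ys[test], clf.classes))
    acc, per_acc, auc, aucs, conf = _aggregate_folds(folds, classes)
    return CVResult(acc, per_acc, auc, aucs, conf, classes, lam, n,
                    extra={"mode": "anatomical", "mask_size": mask.indices.size})


@dataclass
class AlignmentTransform:
    """Per-subject orthogonal maps into the common template space."""

    transforms: list               # per subject (V_sel, V_sel) orthogonal
    template: np.ndarray           # common-space pattern set (T, V_sel)

    def __post_init__(self):
        for i, R in enumerate(self.transforms):
            if not np.allclose(R.T @ R, np.eye(R.shape[1]), atol=1e-8):
                raise ValueError(f"transform {i} is not orthogonal")


def hyperalign(series: list, reference_index: int = 0) -> AlignmentTransform:
    """Two-pass iterative Procrustes template and per-subject transforms.

    Pass 1 starts from the reference subject (the first with a full dataset)
    and incrementally averages each newly aligned subject into the reference.
    Pass 2 re-aligns every subject to the pass-1 reference; the final template
    is the mean of the pass-2 aligned data. Transforms returned are the
    orthogonal maps onto that final template.
    """
    T0 = series[reference_index].shape[0]
    for X in series:
        if X.shape[0] != T0:
            raise ValueError("time axes differ across subjects")
    ref = series[reference_index].copy()
    order = [reference_index] + [i for i in range(len(series))
                                 if i != reference_index]
    for i in order[1:]:
        R, _ = orthogonal_procrustes(series[i], ref)
        ref = (ref + series[i] @ R) / 2.0
    aligned = []
    for X in series:
        R, _ = orthogonal_procrustes(X, ref)
        aligned.append(X @ R)
    template = np.mean(aligned, axis=0)
    transforms = [orthogonal_procrustes(X, template)[0] for X in series]
    return AlignmentTransform(transforms, template)


def _hemi_selection(dataset: VoxelDataset, label: LabelSeries,
                    selection_runs: list, k: int, alpha: float) -> dict:
    """Per-hemisphere top-k ANOVA voxel indices for one subject."""
    X, y, _ = stack_usable(dataset, label, selection_runs)
    out = {}
    for hemi in ("L", "R"):
        idx = np.flatnonzero(dataset.hemisphere == hemi)
        var = X[:, idx].var(axis=0)
        finite = var > 0
        F = np.full(idx.size, -np.inf)
        p = np.ones(idx.size)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F[finite], p[finite] = f_classif(X[:, idx[finite]], y)
        F = np.nan_to_num(F, nan=-np.inf)
        ok = np.flatnonzero(finite & (p < alpha))
        if ok.size == 0:
            raise ValueError(f"no {hemi}-hemisphere voxel survives p < {alpha}")
        order = np.argsort(F[ok])[::-1]
        out[hemi] = idx[ok[order[:k]]]
    return out


def hyperaligned_crossvalidate(datasets: list, labels: list,
                               k_per_hemi: int = HYPER_TOP_K_PER_HEMI,
                               alpha: float = HYPER_ALPHA,
                               k_components: int = PCA_COMPONENTS,
                               lam: float = GROUP_PENALTY) -> CVResult:
    """Functionally aligned leave-one-subject-out operation decoding.

    Transforms are fit on selection-half time series only; the
    classification half is mapped with the frozen transforms.
    """
    n = len(datasets)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    sel_runs, clf_runs = split_halves(datasets[0].run_ids)
    hemi_series = {"L": [], "R": []}
    hemi_vox = []
    for d, l in zip(datasets, labels):
        vox = _hemi_selection(d, l, sel_runs, k_per_hemi, alpha)
        hemi_vox.append(vox)
        sel = np.vstack([d.runs[r] for r in sel_runs])
        hemi_series["L"].append(sel[:, vox["L"]])
        hemi_series["R"].append(sel[:, vox["R"]])
    # equal voxel counts per hemisphere are required by Procrustes
    aligns = {}
    for h in ("L", "R"):
        kmin = min(X.shape[1] for X in hemi_series[h])
        hemi_series[h] = [X[:, :kmin] for X in hemi_series[h]]
        for v in hemi_vox:
            v[h] = v[h][:kmin]
        aligns[h] = hyperalign(hemi_series[h])
    Xs, ys = [], []
    for s, (d, l) in enumerate(zip(datasets, labels)):
        X, y, _ = stack_usable(d, l, clf_runs)
        parts = [X[:, hemi_vox[s][h]] @ aligns[h].transforms[s]
                 for h in ("L", "R")]
        Xs.append(np.hstack(parts))
        ys.append(y)
    classes = sorted({c for y in ys for c in y.tolist()})
    folds = []
    for test in range(n):
        train_idx = [i for i in range(n) if i != test]
        Xtr = np.vstack([Xs[i] for i in train_idx])
        ytr = np.concatenate([ys[i] for i in train_idx])
        k = min(k_components, min(Xtr.shape))
        tr, (te,), _ = pca_reduce(Xtr, [Xs[test]], k)
        fm = FeatureMask(np.arange(tr.shape[1]), 1.0)
        clf = fit_ovr_logistic(tr, ytr, fm, lam)
        folds.append((clf.evidence(te), ys[test], clf.classes))
    acc, per_acc, auc, aucs, conf = _aggregate_folds(folds, classes)
    return CVResult(acc, per_acc, auc, aucs, conf, classes, lam, n,
                    extra={"mode": "hyperaligned"})
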