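"""Item-level representational similarity and encoding fidelity.

Voxel selection and weighting follow a two-step GLM procedure on the
localizer, restricted to the VVS-like region. Step one models category
mini-blocks (31-TR boxcars, HRF-convolved) and keeps, per category, voxels
whose target-vs-nontargets t contrast passes p < 0.05 (one-sided) with a
10-voxel cluster extent. Step two is an LS-A GLM with one regressor per item
(54 regressors); each item's t contrast against the other 53 supplies signed
voxel weights w_v on its category's mask.

An item's *template* is the mean of its five presentation-epoch patterns
(shifted by the hemodynamic lag) multiplied elementwise by w_v. Similarity
between a template and a measured pattern (weighted with the same w_v) is
Pearson r, Fisher z-transformed. The z similarity between a study trial's
weighted pattern and the presented item's template is that trial's
*encoding fidelity* F; the mean similarity to the 17 other same-category
templates ("related") and the 36 different-category templates ("others")
provide the contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .design import CATEGORIES, StimulusCatalog, TrialTable
from .hemo import DEFAULT_LAG_TRS, convolve_columns, double_gamma_hrf
from .simulate import VoxelDataset
from .stats import fisher_z

__all__ = [
    "GLMResult",
    "ItemTemplate",
    "fit_category_glm",
    "select_category_voxels",
    "fit_item_glm_lsa",
    "build_item_templates",
    "localizer_rsa",
    "encoding_fidelity",
    "item_timecourse",
]

CLUSTER_EXTENT = 10
_STRUCT6 = ndimage.generate_binary_structure(3, 1)   # 6-connectivity


class EmptyMaskError(ValueError):
    pass


@dataclass
class GLMResult:
    """OLS fit of a voxelwise GLM: betas, residual variance and (X'X)^-1."""

    names: list
    betas: np.ndarray            # (n_regressors, V)
    xtx_inv: np.ndarray
    sigma2: np.ndarray           # (V,) residual variance
    dof: int

    def t_contrast(self, c: np.ndarray) -> np.ndarray:
        """Voxelwise t statistic for contrast vector ``c`` over the betas."""
        c = np.asarray(c, dtype=float)
        eff = c @ self.betas
        var = self.sigma2 * float(c @ self.xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 0, eff / np.sqrt(var), 0.0)
        return t


def _ols_glm(X: np.ndarray, Y: np.ndarray, names: list) -> GLMResult:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the caller
        _, R = np.linalg.qr(X)
        bad = [names[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-10]
        raise ValueError(f"rank-deficient design matrix; collinear columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / max(dof, 1)
    return GLMResult(names, beta, np.linalg.inv(X.T @ X), sigma2, dof)


def _concat_runs(data: VoxelDataset):
    runs = data.run_ids
    Y = np.vstack([data.runs[r] for r in runs])
    offsets, off = {}, 0
    for r in runs:
        offsets[r] = off
        off += data.runs[r].shape[0]
    return Y, offsets, off


def _boxcar_regressors(design: TrialTable, total_trs: int, offsets: dict,
                       events) -> np.ndarray:
    """events: iterable of (run, start0, stop0, column); returns boxcars."""
    ncol = max(e[3] for e in events) + 1
    X = np.zeros((total_trs, ncol))
    for run, s, e, col in events:
        off = offsets[run]
        T = design.run_lengths[run]
        X[off + s: off + min(e, T), col] = 1.0
    return X


def _convolve_per_run(X: np.ndarray, design: TrialTable, offsets: dict,
                      tr_seconds: float) -> np.ndarray:
    kernel = double_gamma_hrf(tr_seconds)
    out = np.zeros_like(X)
    for r in design.runs:
        off = offsets[r]
        T = design.run_lengths[r]
        out[off:off + T] = convolve_columns(X[off:off + T], kernel)
    return out


def _run_intercepts(design: TrialTable, offsets: dict, total: int) -> np.ndarray:
    Z = np.zeros((total, len(design.runs)))
    for i, r in enumerate(design.runs):
        Z[offsets[r]: offsets[r] + design.run_lengths[r], i] = 1.0
    return Z


def fit_category_glm(data: VoxelDataset, design: TrialTable,
                     nuisance: np.ndarray | None = None) -> GLMResult:
    """Category mini-block GLM on the localizer (31-TR HRF-convolved boxcars).

    One regressor per category plus run intercepts (and an optional nuisance
    matrix, e.g. motion parameters for real data).
    """
    Y, offsets, total = _concat_runs(data)
    cat_col = {c: i for i, c in enumerate(CATEGORIES)}
    events = []
    f = design.frame
    for run, g in f.groupby("run"):
        g = g.sort_values("onset").reset_index(drop=True)
        for i in range(0, len(g), 3):
            block = g.iloc[i:i + 3]
            s = int(block["onset"].iloc[0]) - 1
            events.append((int(run), s, s + 31, cat_col[block["category"].iloc[0]]))
    X = _boxcar_regressors(design, total, offsets, events)
    X = _convolve_per_run(X, design, offsets, data.tr_seconds)
    parts = [X, _run_intercepts(design, offsets, total)]
    names = list(CATEGORIES) + [f"run_{r}" for r in design.runs]
    if nuisance is not None:
        parts.append(nuisance)
        names += [f"nuisance_{i}" for i in range(nuisance.shape[1])]
    return _ols_glm(np.hstack(parts), Y, names)


def _cluster_filter(selected: np.ndarray, coords: np.ndarray,
                    extent: int) -> np.ndarray:
    """Keep only voxels in 6-connected clusters of size >= extent."""
    if extent <= 1 or not selected.any():
        return selected
    shape = tuple(coords.max(axis=0) + 1)
    vol = np.zeros(shape, dtype=bool)
    ix = tuple(coords[selected].T)
    vol[ix] = True
    lab, n = ndimage.label(vol, structure=_STRUCT6)
    sizes = np.bincount(lab.ravel())
    keep_vol = sizes[lab] >= extent
    keep_vol &= vol
    out = np.zeros_like(selected)
    sel_idx = np.flatnonzero(selected)
    out[sel_idx] = keep_vol[tuple(coords[sel_idx].T)]
    return out


def select_category_voxels(glm: GLMResult, data: VoxelDataset,
                           alpha: float = 0.05,
                           cluster_extent: int = CLUSTER_EXTENT) -> dict:
    """Per-category VVS voxel masks from the target-vs-nontargets contrast.

    One-sided (target > nontargets) p < alpha, 10-voxel 6-connected cluster
    extent, restricted to the VVS-like region. Returns {category: bool (V,)}.
    """
    masks = {}
    k = len(CATEGORIES)
    for ci, cat in enumerate(CATEGORIES):
        c = np.zeros(len(glm.names))
        c[ci] = 1.0
        for cj in range(k):
            if cj != ci:
                c[cj] = -1.0 / (k - 1)
        t = glm.t_contrast(c)
        p = sps.t.sf(t, glm.dof)
        sel = (p < alpha) & data.roi_vvs
        sel = _cluster_filter(sel, data.coords, cluster_extent)
        if not sel.any():
            raise EmptyMaskError(
                f"no voxel survived selection for {cat}; relax the threshold")
        masks[cat] = sel
    return masks


def fit_item_glm_lsa(data: VoxelDataset, design: TrialTable,
                     catalog: StimulusCatalog | None = None) -> dict:
    """LS-A item GLM: one HRF-convolved regressor per item, single model.

    Returns {item id: voxelwise t map of the item-vs-other-53 contrast}.
    """
    catalog = catalog or StimulusCatalog()
    items = sorted(catalog.frame["item"].tolist())
    present = set(design.frame["item"].tolist())
    missing = [i for i in items if i not in present]
    if missing:
        raise ValueError(f"items missing from the design: {missing[:5]}...")
    Y, offsets, total = _concat_runs(data)
    col = {it: i for i, it in enumerate(items)}
    events = []
    for _, t in design.frame.iterrows():
        s = int(t["onset"]) - 1
        events.append((int(t["run"]), s, s + int(t["stim_dur"]), col[int(t["item"])]))
    X = _boxcar_regressors(design, total, offsets, events)
    X = _convolve_per_run(X, design, offsets, data.tr_seconds)
    X = np.hstack([X, _run_intercepts(design, offsets, total)])
    names = [f"item_{i}" for i in items] + [f"run_{r}" for r in design.runs]
    glm = _ols_glm(X, Y, names)
    n = len(items)
    tmaps = {}
    for it in items:
        c = np.zeros(len(names))
        c[col[it]] = 1.0
        for jt in items:
            if jt != it:
                c[col[jt]] = -1.0 / (n - 1)
        tmaps[it] = glm.t_contrast(c)
    return tmaps


@dataclass
class ItemTemplate:
    """Weighted localizer reference pattern for one item."""

    item: int
    category: str
    voxels: np.ndarray           # indices into the dataset voxel axis
    weights: np.ndarray          # item t-contrast values on those voxels
    mean_pattern: np.ndarray     # unweighted mean over repetitions
    pattern: np.ndarray          # mean_pattern * weights

    def __post_init__(self):
        if np.allclose(self.weights, 0):
            raise ValueError(f"item {self.item}: all-zero weights (degenerate template)")


def _epoch_pattern(data: VoxelDataset, run: int, onset0: int, dur: int,
                   shift: int) -> np.ndarray | None:
    X = data.runs[run]
    lo, hi = onset0 + shift, onset0 + dur + shift
    if hi > X.shape[0]:
        return None
    return X[lo:hi].mean(axis=0)


def build_item_templates(data: VoxelDataset, design: TrialTable,
                         item_tmaps: dict, category_masks: dict,
                         shift: int = DEFAULT_LAG_TRS,
                         catalog: StimulusCatalog | None = None) -> dict:
    """Weighted item templates from the localizer presentations.

    Template = (mean presentation-epoch pattern over repetitions, lag-shifted)
    x the item's t-contrast weights, on the item's category mask.
    """
    catalog = catalog or StimulusCatalog()
    templates = {}
    for it, tmap in item_tmaps.items():
        cat, _ = catalog.lookup(it)
        vox = np.flatnonzero(category_masks[cat])
        trials = design.frame[design.frame["item"] == it]
        pats = []
        for _, t in trials.iterrows():
            p = _epoch_pattern(data, int(t["run"]), int(t["onset"]) - 1,
                               int(t["stim_dur"]), shift)
            if p is not None:
                pats.append(p[vox])
        if not pats:
            raise ValueError(f"no usable presentation for item {it}")
        if len(pats) < len(trials):
            warnings.warn(f"item {it}: averaging over {len(pats)} of "
                          f"{len(trials)} repetitions")
        w = tmap[vox]
        mean_pat = np.mean(np.vstack(pats), axis=0)
        templates[it] = ItemTemplate(it, cat, vox, w, mean_pat, mean_pat * w)
    return templates


def _weighted_z(template: ItemTemplate, pattern_full: np.ndarray) -> float:
    """Fisher-z correlation of a measured pattern with a template, after
    weighting the pattern with the template's own voxel weights."""
    x = pattern_full[template.voxels] * template.weights
    y = template.pattern
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(fisher_z(np.corrcoef(x, y)[0, 1]))


def localizer_rsa(templates: dict, data: VoxelDataset, design: TrialTable,
                  shift: int = DEFAULT_LAG_TRS,
                  catalog: StimulusCatalog | None = None) -> pd.DataFrame:
    """Similarity of every localizer presentation to every item template.

    Long-format frame with one row per (template, presentation) pair and its
    partition: target (same item), related (same subcategory), same_category,
    or others. NaN similarities (constant patterns) are excluded with a
    warning.
    """
    catalog = catalog or StimulusCatalog()
    rows = []
    n_bad = 0
    for _, t in design.frame.iterrows():
        p = _epoch_pattern(data, int(t["run"]), int(t["onset"]) - 1,
                           int(t["stim_dur"]), shift)
        if p is None:
            continue
        for it, tpl in templates.items():
            z = _weighted_z(tpl, p)
            if np.isnan(z):
                n_bad += 1
                continue
            cat_t, sub_t = catalog.lookup(it)
            if it == int(t["item"]):
                part = "target"
            elif sub_t == t["subcategory"]:
                part = "related_subcategory"
            elif cat_t == t["category"]:
                part = "same_category"
            else:
                part = "others"
            rows.append({"template_item": it, "presented_item": int(t["item"]),
                         "run": int(t["run"]), "partition": part, "z": z})
    if n_bad:
        warnings.warn(f"{n_bad} undefined correlations excluded")
    return pd.DataFrame(rows)


def encoding_fidelity(templates: dict, data: VoxelDataset, design: TrialTable,
                      shift: int = DEFAULT_LAG_TRS,
                      catalog: StimulusCatalog | None = None) -> pd.DataFrame:
    """Per-study-trial encoding fidelity F and the related/others contrasts.

    F is the Fisher-z similarity of the trial's mean presentation-epoch
    pattern (6 TRs, lag-shifted, weighted with the presented item's weights)
    to that item's template. 'related' and 'others' are the mean similarities
    computed the same way with the other items' templates and weights.
    """
    catalog = catalog or StimulusCatalog()
    by_cat = {c: [it for it, tpl in templates.items() if tpl.category == c]
              for c in CATEGORIES}
    rows = []
    n_skipped = 0
    for _, t in design.frame.iterrows():
        p = _epoch_pattern(data, int(t["run"]), int(t["onset"]) - 1,
                           int(t["stim_dur"]), shift)
        if p is None:
            n_skipped += 1
            continue
        item = int(t["item"])
        cat = t["category"]
        target_z = _weighted_z(templates[item], p)
        related = [_weighted_z(templates[it], p) for it in by_cat[cat]
                   if it != item]
        others = [_weighted_z(templates[it], p)
                  for c in CATEGORIES if c != cat for it in by_cat[c]]
        rows.append({"trial": int(t["trial"]), "run": int(t["run"]),
                     "item": item, "category": cat,
                     "operation": t["operation"], "fidelity": target_z,
                     "related": float(np.nanmean(related)),
                     "others": float(np.nanmean(others))})
    if n_skipped:
        warnings.warn(f"{n_skipped} trial(s) excluded: epoch past run end")
    return pd.DataFrame(rows)


def item_timecourse(templates: dict, data: VoxelDataset, design: TrialTable,
                    window: int = 30) -> dict:
    """Per-TR item-template similarity trajectories, grouped by operation.

    For each study trial the z similarity of every TR in a 30-TR unshifted
    window to the presented item's template (weighted pattern) is computed.
    Returns {operation: (n_trials x window) array} ready for the trajectory
    machinery (maintain subtraction, block statistics, start points).
    """
    out: dict = {}
    for _, t in design.frame.iterrows():
        run, onset0 = int(t["run"]), int(t["onset"]) - 1
        X = data.runs[run]
        if onset0 + window > X.shape[0]:
            continue
        tpl = templates[int(t["item"])]
        seg = X[onset0:onset0 + window][:, tpl.voxels] * tpl.weights
        y = tpl.pattern
        ys = y.std()
        zs = np.full(window, np.nan)
        for k in range(window):
            if seg[k].std() > 0 and ys > 0:
                zs[k] = fisher_z(np.corrcoef(seg[k], y)[0, 1])
        out.setdefault(t["operation"], []).append(zs)
    return {op: np.vstack(v) for op, v in out.items()}
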