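"""Classifier importance maps.

A voxel is *important* for an operation only when its mean z-scored activity
during that operation and its classifier weight share a sign: positive-map
voxels are active above average and weighted positively, negative-map voxels
below average and weighted negatively. Voxels with opposing polarities get an
importance of zero. The importance magnitude is the activity-weight product
(the convention of the importance-map method this follows). Group maps
z-score each subject's map over the combined absolute-value distribution,
re-sign, average over subjects, keep the top percentage of magnitudes
separately for the positive and negative maps, and remove 6-connected
clusters smaller than the extent threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .mvpa import FittedClassifier, LabelSeries
from .simulate import VoxelDataset

__all__ = ["ImportanceMap", "compute_importance", "group_threshold"]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class ImportanceMap:
    """Signed per-voxel importance for one operation (subject or group level)."""

    operation: str
    values: np.ndarray            # signed; 0 where polarities disagree
    level: str = "subject"

    @property
    def positive(self) -> np.ndarray:
        return np.clip(self.values, 0, None)

    @property
    def negative(self) -> np.ndarray:
        return np.clip(self.values, None, 0)


def compute_importance(clf: FittedClassifier, data: VoxelDataset,
                       labels: LabelSeries, operation: str) -> ImportanceMap:
    """Subject-level importance map: sign-agreeing activity-weight products.

    ``data`` should be the z-scored dataset the classifier was trained on;
    the mean activity is taken over the operation's labeled usable TRs.
    Unselected voxels have zero weight, hence zero importance.
    """
    if operation not in clf.classes:
        raise ValueError(f"classifier has no class {operation!r}")
    acts = []
    for r in labels.run_ids:
        lab = labels.labels[r]
        keep = (lab == operation) & labels.usable[r]
        if keep.any():
            acts.append(data.runs[r][keep])
    if not acts:
        raise ValueError(f"operation {operation!r} absent from labels")
    a = np.vstack(acts).mean(axis=0)
    w = np.zeros(data.n_voxels)
    w[clf.mask.indices] = clf.weights[clf.classes.index(operation)]
    agree = np.sign(a) == np.sign(w)
    vals = np.where(agree & (w != 0), a * w, 0.0)
    return ImportanceMap(operation, vals, level="subject")


def _polarity_threshold(vals: np.ndarray, coords: np.ndarray, top_pct: float,
                        extent: int, positive: bool) -> np.ndarray:
    part = np.clip(vals, 0, None) if positive else -np.clip(vals, None, 0)
    sel = part > 0
    if sel.any() and top_pct < 100:
        cut = np.percentile(part[sel], 100 - top_pct)
        sel &= part >= cut
    if extent > 1 and sel.any():
        shape = tuple(coords.max(axis=0) + 1)
        vol = np.zeros(shape, dtype=bool)
        vol[tuple(coords[sel].T)] = True
        lab, _ = ndimage.label(vol, structure=_STRUCT6)
        sizes = np.bincount(lab.ravel())
        keep = sizes[lab[tuple(coords.T)]] >= extent
        sel &= keep
    out = np.zeros_like(vals)
    out[sel] = vals[sel]
    return out


def group_threshold(maps: list, coords: np.ndarray, top_pct: float = 5.0,
                    cluster_extent: int = 10) -> ImportanceMap:
    """Group-level map from per-subject maps on a shared lattice."""
    if len(maps) < 2:
        raise ValueError("need at least 2 subject maps")
    op = maps[0].operation
    zs = []
    for m in maps:
        if m.operation != op:
            raise ValueError("maps belong to different operations")
        v = m.values
        nz = v != 0
        if not nz.any():
            zs.append(np.zeros_like(v))
            continue
        # normalize by the spread of the combined |importance| distribution;
        # centering is not applied so a voxel never flips polarity
        sd = np.abs(v[nz]).std()
        zs.append(v / (sd if sd > 0 else 1.0))
    g = np.mean(zs, axis=0)
    pos = _polarity_threshold(g, coords, top_pct, cluster_extent, True)
    neg = _polarity_threshold(g, coords, top_pct, cluster_extent, False)
    out = pos + neg
    if not np.any(out):
        warnings.warn("no voxel survived group thresholding; empty map")
    return ImportanceMap(op, out, level="group")
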