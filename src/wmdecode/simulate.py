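"""Synthetic multivoxel time series with planted ground truth.

The generator builds a 3-D voxel lattice with an ellipsoidal brain mask, left
and right hemispheres split at the mid-x plane, and a contiguous
posterior-ventral block tagged as a ventral-visual-stream-like (VVS) region.
Category, subcategory and item patterns live on category-specific voxel
support inside the VVS block (an ``overlap`` parameter controls how much
support categories share); each operation has a whole-lattice pattern active
during the operation screen and the following fixation.

During the study task the stimulus components decay after the operation
instruction with operation-specific dynamics: by default maintain keeps the
signal, replace removes it fastest and raises the replacement item's
components, clear is intermediate, and suppress keeps the category component
nearly intact while the item component decays late. A per-operation
*proactive-interference* multiplier scales the stimulus components of the
NEXT trial whenever its category matches the current one, planting a
recoverable same-minus-different encoding-fidelity pattern.

Neural signal is turned into a BOLD-like series either by a pure fixed lag
(default 10 TRs, exactly matching the analyses' label shift) or by
double-gamma HRF convolution, then i.i.d. Gaussian noise of width ``sigma``
is added.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

from .design import CATEGORIES, SUBCATEGORIES, OPERATIONS, TR_SECONDS, \
    LOC_FIXATION_TRS, StimulusCatalog, TrialTable
from .hemo import DEFAULT_LAG_TRS, convolve_columns, double_gamma_hrf

__all__ = [
    "OperationDynamics",
    "GroundTruthConfig",
    "GroundTruth",
    "VoxelDataset",
    "make_ground_truth",
    "simulate_subject",
    "simulate_group",
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class OperationDynamics:
    """Post-instruction dynamics of the held item's components.

    ``decay_onset`` is the delay (TRs, from operation-screen onset) before
    decay starts; half-lives are in TRs (``inf`` = no decay); ``rise_rate``
    is the exponential approach rate (per TR) of the replacement item's
    components on replace trials.
    """

    decay_onset: float = 0.0
    item_half_life: float = np.inf
    category_half_life: float = np.inf
    rise_rate: float = 0.0

    def __post_init__(self):
        if self.decay_onset < 0 or self.rise_rate < 0:
            raise ConfigurationError("dynamics parameters must be non-negative")
        if self.item_half_life <= 0 or self.category_half_life <= 0:
            raise ConfigurationError("half-lives must be positive")


def _default_dynamics() -> dict[str, OperationDynamics]:
    replace = OperationDynamics(decay_onset=0.0, item_half_life=1.5,
                                category_half_life=1.5, rise_rate=0.5)
    return {
        "maintain": OperationDynamics(),
        "replace_subcat": replace,
        "replace_cat": replace,
        "clear": OperationDynamics(decay_onset=0.0, item_half_life=2.5,
                                   category_half_life=2.5),
        # suppression spares the coarse category signal (nearly sustained)
        # while the item-specific component decays late
        "suppress": OperationDynamics(decay_onset=6.0, item_half_life=4.0,
                                      category_half_life=30.0),
    }


def _default_interference() -> dict[str, float]:
    # multiplier on the next trial's item/subcategory amplitude when its
    # category matches this trial's category
    return {"maintain": 0.30, "replace_subcat": 0.30, "replace_cat": 0.30,
            "clear": 0.30, "suppress": 1.70}


@dataclass
class GroundTruthConfig:
    shape: tuple[int, int, int] = (14, 14, 14)
    a_cat: float = 1.0
    a_sub: float = 0.5
    a_item: float = 0.35
    a_op: float = 0.8
    sigma: float = 0.6
    overlap: float = 0.0
    lag_mode: str = "pure"          # "pure" (fixed lag) or "hrf"
    lag_trs: int = DEFAULT_LAG_TRS
    censor_fraction: float = 0.0
    dynamics: dict = field(default_factory=_default_dynamics)
    interference: dict = field(default_factory=_default_interference)

    def __post_init__(self):
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be > 0")
        if int(np.prod(self.shape)) == 0:
            raise ConfigurationError("empty lattice")
        if not (self.a_cat >= self.a_sub >= self.a_item >= 0):
            raise ConfigurationError("amplitudes must satisfy a_cat >= a_sub >= a_item >= 0")
        if not 0.0 <= self.overlap <= 1.0:
            raise ConfigurationError("overlap must be in [0, 1]")
        if self.lag_mode not in ("pure", "hrf"):
            raise ConfigurationError("lag_mode must be 'pure' or 'hrf'")
        self.dynamics = {k: (v if isinstance(v, OperationDynamics)
                             else OperationDynamics(**v))
                         for k, v in self.dynamics.items()}


@dataclass
class GroundTruth:
    """Planted patterns and dynamics for one simulated brain."""

    config: GroundTruthConfig
    coords: np.ndarray                 # (V, 3) lattice coordinates of mask voxels
    hemisphere: np.ndarray             # (V,) 'L' / 'R'
    roi_vvs: np.ndarray                # (V,) bool
    category_patterns: dict            # cat -> unit vector (V,)
    subcategory_patterns: dict         # (cat, sub) -> unit vector
    item_patterns: dict                # item id -> unit vector
    operation_patterns: dict           # op -> unit vector

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]


@dataclass
class VoxelDataset:
    """Per-run (TR x voxel) matrices plus lattice/ROI metadata."""

    runs: dict                          # run -> (T, V) float array
    tr_seconds: float
    coords: np.ndarray
    hemisphere: np.ndarray
    roi_vvs: np.ndarray
    censored: dict = field(default_factory=dict)   # run -> (T,) bool

    def __post_init__(self):
        V = self.coords.shape[0]
        for r, X in self.runs.items():
            if X.shape[1] != V:
                raise ConfigurationError(f"run {r} voxel axis mismatch")
            if r not in self.censored:
                self.censored[r] = np.zeros(X.shape[0], dtype=bool)
            good = ~self.censored[r]
            if not np.all(np.isfinite(X[good])):
                raise ConfigurationError(f"non-finite data outside censored TRs in run {r}")

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    @property
    def run_ids(self) -> list[int]:
        return sorted(self.runs.keys())

    def voxel_subset(self, idx: np.ndarray) -> "VoxelDataset":
        return VoxelDataset({r: X[:, idx] for r, X in self.runs.items()},
                            self.tr_seconds, self.coords[idx],
                            self.hemisphere[idx], self.roi_vvs[idx],
                            {r: c.copy() for r, c in self.censored.items()})

    def save_h5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["tr_seconds"] = self.tr_seconds
            f.create_dataset("coords", data=self.coords)
            f.create_dataset("hemisphere", data=np.array(
                [h.encode() for h in self.hemisphere]))
            f.create_dataset("roi_vvs", data=self.roi_vvs)
            g = f.create_group("runs")
            c = f.create_group("censored")
            for r, X in self.runs.items():
                g.create_dataset(str(r), data=X)
                c.create_dataset(str(r), data=self.censored[r])

    @classmethod
    def load_h5(cls, path) -> "VoxelDataset":
        with h5py.File(path, "r") as f:
            runs = {int(k): v[()] for k, v in f["runs"].items()}
            cens = {int(k): v[()].astype(bool) for k, v in f["censored"].items()}
            return cls(runs, float(f.attrs["tr_seconds"]), f["coords"][()],
                       np.array([h.decode() for h in f["hemisphere"][()]]),
                       f["roi_vvs"][()].astype(bool), cens)

    def to_nifti(self, shape: tuple[int, int, int]):
        """One 4-D NIfTI image per run on the originating lattice, plus a mask."""
        import nibabel as nib
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        mask = np.zeros(shape, dtype=np.int8)
        ix = tuple(self.coords.T)
        mask[ix] = 1
        imgs = {}
        for r, X in self.runs.items():
            vol = np.zeros(shape + (X.shape[0],), dtype=np.float32)
            vol[ix[0], ix[1], ix[2], :] = X.T
            imgs[r] = nib.Nifti1Image(vol, affine)
        return imgs, nib.Nifti1Image(mask, affine)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ConfigurationError("degenerate zero pattern")
    return v / n


def make_ground_truth(config: GroundTruthConfig | None = None, seed: int = 0,
                      catalog: StimulusCatalog | None = None) -> GroundTruth:
    """Draw the planted patterns for one subject, deterministically per seed."""
    config = config or GroundTruthConfig()
    catalog = catalog or StimulusCatalog()
    rng = np.random.default_rng(seed)

    nx, ny, nz = config.shape
    gx, gy, gz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    ell = ((gx - cx) / (nx / 2.0)) ** 2 + ((gy - cy) / (ny / 2.0)) ** 2 \
        + ((gz - cz) / (nz / 2.0)) ** 2
    mask = ell <= 1.0
    coords = np.argwhere(mask)
    V = coords.shape[0]
    if V == 0:
        raise ConfigurationError("empty lattice mask")
    hemisphere = np.where(coords[:, 0] < nx / 2.0, "L", "R")
    # posterior-ventral block: large y (posterior), small z (ventral)
    roi_vvs = (coords[:, 1] >= ny // 2) & (coords[:, 2] < (2 * nz) // 3)
    if roi_vvs.sum() < 30:
        roi_vvs = np.ones(V, dtype=bool)

    vvs_idx = np.flatnonzero(roi_vvs)
    # category supports are spatially contiguous slabs of the VVS block
    # (category selectivity clusters in space); an overlap fraction of
    # randomly drawn VVS voxels is shared between all categories
    order = np.lexsort((coords[vvs_idx, 2], coords[vvs_idx, 1], coords[vvs_idx, 0]))
    blocks = np.array_split(vvs_idx[order], 3)
    n_shared = int(round(config.overlap * len(vvs_idx)))
    shared = rng.permutation(vvs_idx)[:n_shared]

    def support_pattern(sup: np.ndarray, positive: bool = False) -> np.ndarray:
        v = np.zeros(V)
        draw = rng.standard_normal(len(sup))
        v[sup] = np.abs(draw) if positive else draw
        return _unit(v)

    category_patterns, subcategory_patterns, item_patterns = {}, {}, {}
    for ci, cat in enumerate(CATEGORIES):
        sup = np.concatenate([blocks[ci], shared]) if n_shared else blocks[ci]
        # category selectivity is a positive activation over a contiguous
        # support (so one-sided contrasts and cluster correction behave as
        # they do on real data); finer-grained patterns are signed
        category_patterns[cat] = support_pattern(sup, positive=True)
        for sub in SUBCATEGORIES[cat]:
            subcategory_patterns[(cat, sub)] = support_pattern(sup)
            for item in catalog.items_of(cat, sub):
                item_patterns[int(item)] = support_pattern(sup)
    # operation (control) signals live outside the visual ROI, like the
    # frontoparietal sources that carry operation information in real data;
    # this also keeps them out of the category decoder's voxel support
    op_sup = np.flatnonzero(~roi_vvs)
    if op_sup.size < 10:
        op_sup = np.arange(V)
    operation_patterns = {op: support_pattern(op_sup) for op in OPERATIONS}

    return GroundTruth(config, coords, hemisphere, roi_vvs, category_patterns,
                       subcategory_patterns, item_patterns, operation_patterns)


def _decay(t_rel: np.ndarray, onset: float, half_life: float) -> np.ndarray:
    """Exponential decay multiplier; 1 before ``onset``, half-life in TRs."""
    if np.isinf(half_life):
        return np.ones_like(t_rel, dtype=float)
    m = np.ones_like(t_rel, dtype=float)
    after = t_rel >= onset
    m[after] = np.exp(-np.log(2.0) * (t_rel[after] - onset) / half_life)
    return m


def _rise(t_rel: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return np.zeros_like(t_rel, dtype=float)
    return 1.0 - np.exp(-rate * (t_rel + 1.0))


def simulate_subject(design: TrialTable, truth: GroundTruth, seed: int = 0,
                     catalog: StimulusCatalog | None = None) -> VoxelDataset:
    """Render one subject's BOLD-like runs from a trial table and ground truth."""
    cfg = truth.config
    catalog = catalog or StimulusCatalog()
    rng = np.random.default_rng(seed)
    V = truth.n_voxels
    runs, censored = {}, {}

    for run in design.runs:
        T = design.run_lengths[run]
        neural = np.zeros((T, V))
        trials = design.trials_in_run(run).sort_values("onset")
        prev_cat, prev_op = None, None
        for pos, (_, tr) in enumerate(trials.iterrows()):
            item = int(tr["item"])
            cat, sub = tr["category"], tr["subcategory"]
            interf = 1.0
            if prev_cat == cat and prev_op is not None:
                interf = cfg.interference.get(prev_op, 1.0)

            onset = int(tr["onset"]) - 1          # 0-based
            stim_end = onset + int(tr["stim_dur"])
            if design.phase == "localizer":
                # attention to the stimulus persists through the jittered ITI
                # (the localizer is modelled as sustained mini-blocks), and the
                # triplet's representation lingers into the fixation block
                stim_end += int(tr["iti"])
                if pos % 3 == 2:
                    stim_end += LOC_FIXATION_TRS
            t_stim = np.arange(onset, min(stim_end, T))
            # lingering previous-trial content modulates how strongly the
            # whole new stimulus is encoded when the categories match
            comp_item = interf * cfg.a_item * truth.item_patterns[item]
            comp_sub = interf * cfg.a_sub * truth.subcategory_patterns[(cat, sub)]
            comp_cat = interf * cfg.a_cat * truth.category_patterns[cat]
            neural[t_stim] += comp_cat + comp_sub + comp_item

            if design.phase == "study":
                op = tr["operation"]
                dyn = cfg.dynamics[op]
                op_start = stim_end
                trial_end = op_start + int(tr["op_dur"]) + int(tr["iti"])
                t_op = np.arange(op_start, min(trial_end, T))
                t_rel = (t_op - op_start).astype(float)
                m_item = _decay(t_rel, dyn.decay_onset, dyn.item_half_life)
                m_cat = _decay(t_rel, dyn.decay_onset, dyn.category_half_life)
                neural[t_op] += (m_cat[:, None] * (comp_cat + comp_sub)
                                 + m_item[:, None] * comp_item)
                neural[t_op] += cfg.a_op * truth.operation_patterns[op]
                if op in ("replace_cat", "replace_subcat") and np.isfinite(tr["replacement_item"]):
                    new_item = int(tr["replacement_item"])
                    ncat, nsub = catalog.lookup(new_item)
                    new_comp = (cfg.a_cat * truth.category_patterns[ncat]
                                + cfg.a_sub * truth.subcategory_patterns[(ncat, nsub)]
                                + cfg.a_item * truth.item_patterns[new_item])
                    neural[t_op] += _rise(t_rel, dyn.rise_rate)[:, None] * new_comp
                prev_cat, prev_op = cat, op
            else:
                prev_cat, prev_op = cat, None

        if cfg.lag_mode == "pure":
            bold = np.zeros_like(neural)
            lag = int(cfg.lag_trs)
            if lag < T:
                bold[lag:] = neural[: T - lag]
        else:
            kernel = double_gamma_hrf(design.tr_seconds)
            bold = convolve_columns(neural, kernel)
        bold = bold + cfg.sigma * rng.standard_normal(bold.shape)

        cens = np.zeros(T, dtype=bool)
        if cfg.censor_fraction > 0:
            n_c = int(round(cfg.censor_fraction * T))
            cens[rng.choice(T, size=n_c, replace=False)] = True
        runs[run] = bold
        censored[run] = cens

    return VoxelDataset(runs, design.tr_seconds, truth.coords.copy(),
                        truth.hemisphere.copy(), truth.roi_vvs.copy(), censored)


def simulate_group(designs, config: GroundTruthConfig | None = None,
                   n_subjects: int = 8, seed: int = 0,
                   shared_truth: bool = False):
    """Simulate several subjects. Each gets its own planted patterns unless
    ``shared_truth`` (useful for anatomical between-subject decoding, where
    the voxel axis is assumed aligned)."""
    config = config or GroundTruthConfig()
    rng = np.random.default_rng(seed)
    base = int(rng.integers(2 ** 31 - 10_000))
    out = []
    truth0 = make_ground_truth(config, seed=base) if shared_truth else None
    for s in range(n_subjects):
        truth = truth0 if shared_truth else make_ground_truth(config, seed=base + s)
        datasets = {name: simulate_subject(d, truth, seed=base + 1000 + 17 * s + i)
                    for i, (name, d) in enumerate(designs.items())}
        out.append({"truth": truth, "data": datasets})
    return out


def config_to_dict(config: GroundTruthConfig) -> dict:
    d = asdict(config)
    d["dynamics"] = {k: asdict(v) if isinstance(v, OperationDynamics) else v
                     for k, v in config.dynamics.items()}
    return d
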