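"""Experimental designs: stimulus catalog and trial tables.

Two tasks are modelled. A *localizer* presents each of 54 images (3 categories
x 3 subcategories x 6 exemplars) once per run in subcategory-specific triplets
(3-TR image, 5-10 TR jittered ITI, 13-TR fixation after each triplet, 13-TR
instruction screen at run start). The *central study* presents an image for
6 TRs followed by a 6-TR operation screen (maintain / replace-subcategory /
replace-category / suppress / clear) and a 5-9 TR jittered ITI, with 40-TR
fixation blocks at both ends of each run; each run holds 12 trials per
operation (60 total), balanced over categories.

All onsets and durations are integer TR indices, 1-based, TR = 0.46 s.
Ordering and jitter are drawn from a seeded generator; marginal counts are
deterministic properties of the design.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TR_SECONDS",
    "CATEGORIES",
    "SUBCATEGORIES",
    "OPERATIONS",
    "MAIN_OPERATIONS",
    "InvalidDesignError",
    "StimulusCatalog",
    "TrialTable",
    "build_localizer_design",
    "build_study_design",
    "write_events_tsv",
    "read_events_tsv",
]

TR_SECONDS = 0.46

CATEGORIES = ("face", "fruit", "scene")
SUBCATEGORIES = {
    "face": ("actor", "musician", "politician"),
    "fruit": ("apple", "grape", "pear"),
    "scene": ("beach", "bridge", "mountain"),
}
ITEMS_PER_SUBCATEGORY = 6

OPERATIONS = ("maintain", "replace_subcat", "replace_cat", "suppress", "clear")
#: operations kept for the main analyses (replace_subcat is excluded there)
MAIN_OPERATIONS = ("maintain", "replace_cat", "suppress", "clear")

LOC_STIM_TRS = 3
LOC_ITI_RANGE = (5, 10)          # inclusive, TRs
LOC_FIXATION_TRS = 13            # after each triplet
LOC_INSTRUCTION_TRS = 13         # at run start
STUDY_STIM_TRS = 6
STUDY_OP_TRS = 6
STUDY_ITI_RANGE = (5, 9)         # inclusive, TRs
STUDY_EDGE_FIXATION_TRS = 40     # at both ends of each run
STUDY_TRIALS_PER_OP_PER_RUN = 12


class InvalidDesignError(ValueError):
    """Raised when a requested design cannot satisfy its counterbalancing."""


@dataclass(frozen=True)
class StimulusCatalog:
    """The 54-image stimulus set: 3 categories x 3 subcategories x 6 items."""

    frame: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.frame is None:
            rows = []
            iid = itertools.count(1)
            for cat in CATEGORIES:
                for sub in SUBCATEGORIES[cat]:
                    for _ in range(ITEMS_PER_SUBCATEGORY):
                        rows.append({"item": next(iid), "category": cat,
                                     "subcategory": sub})
            object.__setattr__(self, "frame", pd.DataFrame(rows))
        self.validate()

    def validate(self) -> None:
        f = self.frame
        if len(f) != 54 or f["item"].nunique() != 54:
            raise InvalidDesignError("catalog must contain 54 uniquely numbered items")
        per_sub = f.groupby(["category", "subcategory"]).size()
        if len(per_sub) != 9 or not (per_sub == ITEMS_PER_SUBCATEGORY).all():
            raise InvalidDesignError("catalog must have 3x3 subcategories of 6 items")

    @property
    def n_items(self) -> int:
        return len(self.frame)

    def lookup(self, item: int) -> tuple[str, str]:
        row = self.frame.loc[self.frame["item"] == item]
        if row.empty:
            raise KeyError(f"unknown item id {item}")
        return row["category"].iloc[0], row["subcategory"].iloc[0]

    def items_of(self, category: str, subcategory: str | None = None) -> np.ndarray:
        f = self.frame
        sel = f["category"] == category
        if subcategory is not None:
            sel &= f["subcategory"] == subcategory
        return f.loc[sel, "item"].to_numpy()


@dataclass
class TrialTable:
    """Per-trial records for one task phase plus per-run lengths in TRs."""

    frame: pd.DataFrame
    run_lengths: dict[int, int]
    phase: str
    tr_seconds: float = TR_SECONDS

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        f = self.frame
        for run, g in f.groupby("run"):
            onsets = g["onset"].to_numpy()
            if not np.all(np.diff(onsets) > 0):
                raise InvalidDesignError(f"onsets not strictly increasing in run {run}")
            ends = onsets + g["stim_dur"].to_numpy() + g["op_dur"].fillna(0).to_numpy()
            if np.any(ends[:-1] > onsets[1:]):
                raise InvalidDesignError(f"overlapping trials in run {run}")
            if ends[-1] - 1 > self.run_lengths[run]:
                raise InvalidDesignError(f"trial extends past run {run} end")

    @property
    def runs(self) -> list[int]:
        return sorted(self.frame["run"].unique().tolist())

    def trials_in_run(self, run: int) -> pd.DataFrame:
        return self.frame.loc[self.frame["run"] == run]


def _localizer_run(catalog: StimulusCatalog, run: int, rng: np.random.Generator,
                   trial0: int) -> tuple[list[dict], int]:
    # two triplets per subcategory per run; each exemplar exactly once
    triplets = []
    for cat in CATEGORIES:
        for sub in SUBCATEGORIES[cat]:
            items = rng.permutation(catalog.items_of(cat, sub))
            triplets.append((cat, sub, items[:3]))
            triplets.append((cat, sub, items[3:]))
    order = rng.permutation(len(triplets))
    rows = []
    t = LOC_INSTRUCTION_TRS + 1
    idx = trial0
    for k in order:
        cat, sub, items = triplets[k]
        for item in items:
            iti = int(rng.integers(LOC_ITI_RANGE[0], LOC_ITI_RANGE[1] + 1))
            rows.append({"trial": idx, "phase": "localizer", "run": run,
                         "onset": t, "stim_dur": LOC_STIM_TRS, "op_dur": np.nan,
                         "iti": iti, "item": int(item), "category": cat,
                         "subcategory": sub, "operation": None,
                         "replacement_item": np.nan})
            t += LOC_STIM_TRS + iti
            idx += 1
        t += LOC_FIXATION_TRS
    return rows, t - 1


def build_localizer_design(catalog: StimulusCatalog, n_runs: int = 5,
                           seed: int = 0) -> TrialTable:
    """Localizer trial table: each exemplar once per run, subcategory triplets.

    With the canonical 5 runs this yields 270 trials — 90 per category,
    30 per subcategory, 5 per exemplar.
    """
    if n_runs < 1:
        raise InvalidDesignError("n_runs must be >= 1")
    catalog.validate()
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    lengths: dict[int, int] = {}
    for run in range(1, n_runs + 1):
        run_rows, length = _localizer_run(catalog, run, rng, trial0=len(rows) + 1)
        rows.extend(run_rows)
        lengths[run] = length
    return TrialTable(pd.DataFrame(rows), lengths, phase="localizer")


def _study_item_schedule(catalog: StimulusCatalog, n_runs: int,
                         rng: np.random.Generator) -> dict[str, dict[str, list[int]]]:
    """Per (operation, category): an ordered item list of length 4 * n_runs.

    Items cycle through seeded permutations of the category's 18 exemplars,
    so with >= 5 runs every exemplar appears at least once per operation.
    """
    need = 4 * n_runs
    sched: dict[str, dict[str, list[int]]] = {}
    for op in OPERATIONS:
        sched[op] = {}
        for cat in CATEGORIES:
            items = catalog.items_of(cat)
            pool: list[int] = []
            while len(pool) < need:
                pool.extend(int(i) for i in rng.permutation(items))
            sched[op][cat] = pool[:need]
    return sched


def _pick_replacement(catalog: StimulusCatalog, op: str, item: int,
                      rng: np.random.Generator) -> float:
    cat, sub = catalog.lookup(item)
    if op == "replace_cat":
        other = [c for c in CATEGORIES if c != cat]
        new_cat = other[int(rng.integers(len(other)))]
        pool = catalog.items_of(new_cat)
    elif op == "replace_subcat":
        other = [s for s in SUBCATEGORIES[cat] if s != sub]
        new_sub = other[int(rng.integers(len(other)))]
        pool = catalog.items_of(cat, new_sub)
    else:
        return np.nan
    return int(pool[int(rng.integers(len(pool)))])


def build_study_design(catalog: StimulusCatalog, n_runs: int = 6,
                       seed: int = 0) -> TrialTable:
    """Central-study trial table: 60 trials/run, 12 per operation, 4 per
    operation x category; replace trials carry a replacement item of a
    different subcategory (replace_subcat) or category (replace_cat)."""
    if n_runs < 1:
        raise InvalidDesignError("n_runs must be >= 1")
    catalog.validate()
    rng = np.random.default_rng(seed)
    sched = _study_item_schedule(catalog, n_runs, rng)
    rows: list[dict] = []
    lengths: dict[int, int] = {}
    idx = 1
    for run in range(1, n_runs + 1):
        trials = []
        for op in OPERATIONS:
            for cat in CATEGORIES:
                chunk = sched[op][cat][4 * (run - 1): 4 * run]
                for item in chunk:
                    trials.append((op, item))
        order = rng.permutation(len(trials))
        t = STUDY_EDGE_FIXATION_TRS + 1
        for k in order:
            op, item = trials[k]
            cat, sub = catalog.lookup(item)
            iti = int(rng.integers(STUDY_ITI_RANGE[0], STUDY_ITI_RANGE[1] + 1))
            rows.append({"trial": idx, "phase": "study", "run": run,
                         "onset": t, "stim_dur": STUDY_STIM_TRS,
                         "op_dur": STUDY_OP_TRS, "iti": iti, "item": item,
                         "category": cat, "subcategory": sub, "operation": op,
                         "replacement_item": _pick_replacement(catalog, op, item, rng)})
            t += STUDY_STIM_TRS + STUDY_OP_TRS + iti
            idx += 1
        lengths[run] = t - 1 + STUDY_EDGE_FIXATION_TRS
    return TrialTable(pd.DataFrame(rows), lengths, phase="study")


def write_events_tsv(table: TrialTable, path) -> None:
    """Write a BIDS-style events table (onset/duration in seconds, labels,
    and the TR-index columns carried alongside)."""
    f = table.frame.copy()
    f["onset_s"] = (f["onset"] - 1) * table.tr_seconds
    f["duration_s"] = (f["stim_dur"] + f["op_dur"].fillna(0)) * table.tr_seconds
    cols = ["onset_s", "duration_s"] + [c for c in f.columns
                                        if c not in ("onset_s", "duration_s")]
    out = f[cols].rename(columns={"onset_s": "onset", "duration_s": "duration",
                                  "onset": "onset_tr"})
    out.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path, run_lengths: dict[int, int],
                    tr_seconds: float = TR_SECONDS) -> TrialTable:
    """Read a BIDS-style events table written by :func:`write_events_tsv`."""
    f = pd.read_csv(path, sep="\t", na_values=["n/a"])
    if f.empty:
        raise InvalidDesignError("empty events table")
    f = f.rename(columns={"onset": "onset_s", "duration": "duration_s",
                          "onset_tr": "onset"})
    if "onset" not in f.columns:
        # seconds-only table: snap onsets to the TR grid
        tr_float = f["onset_s"] / tr_seconds
        snapped = np.rint(tr_float)
        if np.any(np.abs(tr_float - snapped) > 0.5):
            import warnings
            warnings.warn("event onsets misaligned by more than 0.5 TR; snapping")
        f["onset"] = snapped.astype(int) + 1
    f = f.drop(columns=[c for c in ("onset_s", "duration_s") if c in f.columns])
    f["operation"] = f["operation"].where(pd.notna(f["operation"]), None)
    phase = f["phase"].iloc[0]
    return TrialTable(f, dict(run_lengths), phase=phase, tr_seconds=tr_seconds)
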