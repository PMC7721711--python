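"""Shared fixtures: small designs and simulated subjects.

Everything is generated at test time from seeds; expensive cohort fixtures
are session-scoped.
"""

import warnings

import numpy as np
import pytest

import wmdecode as w
from wmdecode import mvpa


@pytest.fixture(scope="session")
def catalog():
    return w.StimulusCatalog()


@pytest.fixture(scope="session")
def loc_design(catalog):
    return w.build_localizer_design(catalog, n_runs=2, seed=101)


@pytest.fixture(scope="session")
def loc_design_full(catalog):
    return w.build_localizer_design(catalog, n_runs=5, seed=102)


@pytest.fixture(scope="session")
def study_design(catalog):
    return w.build_study_design(catalog, n_runs=2, seed=103)


@pytest.fixture(scope="session")
def study_design_full(catalog):
    return w.build_study_design(catalog, n_runs=6, seed=104)


@pytest.fixture(scope="session")
def gt_config():
    return w.GroundTruthConfig(shape=(12, 12, 12))


@pytest.fixture(scope="session")
def truth(gt_config):
    return w.make_ground_truth(gt_config, seed=7)


@pytest.fixture(scope="session")
def clean_truth():
    """Near-noiseless ground truth for exactness checks."""
    cfg = w.GroundTruthConfig(shape=(10, 10, 10), sigma=1e-8)
    return w.make_ground_truth(cfg, seed=9)


@pytest.fixture(scope="session")
def subject(loc_design, study_design, truth):
    """One simulated subject at the default noise level, z-scored."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loc = w.zscore_runs(w.simulate_subject(loc_design, truth, seed=11))
        stu = w.zscore_runs(w.simulate_subject(study_design, truth, seed=12))
    return {"localizer": loc, "study": stu}


@pytest.fixture(scope="session")
def op_labels(study_design):
    return w.build_shifted_labels(study_design, "operation_fixation",
                                  "operation", classes=list(w.MAIN_OPERATIONS))


@pytest.fixture(scope="session")
def cat_labels(loc_design):
    return w.build_shifted_labels(loc_design, "localizer_miniblock", "category")


def permute_labels(labels, rng):
    """Shuffle labels among labeled TRs within each run (null model)."""
    new = mvpa.LabelSeries({r: a.copy() for r, a in labels.labels.items()},
                           {r: u.copy() for r, u in labels.usable.items()},
                           labels.classes, labels.shift, labels.epoch)
    for r in new.run_ids:
        lab = new.labels[r]
        idx = np.flatnonzero((lab != None) & new.usable[r])   # noqa: E711
        lab[idx] = lab[idx][rng.permutation(idx.size)]
    return new
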