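"""Configuration and end-to-end orchestration.

``run_pipeline`` executes the whole analysis on simulated subjects —
operation decoding, representation decoding, importance maps, evidence
trajectories, item RSA and the interference suite — and writes tidy CSV/JSON
outputs plus a manifest carrying the configuration hash, so a config file and
its seeds reproduce every number exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as dz
from . import importance as imp
from . import interference as itf
from . import mvpa, rsa, timecourse
from .simulate import (GroundTruthConfig, config_to_dict, make_ground_truth,
                       simulate_subject)

__all__ = ["PipelineConfig", "run_pipeline", "import_bids_like"]


@dataclass
class PipelineConfig:
    design_seed: int = 11
    simulation_seed: int = 22
    analysis_seed: int = 33
    n_subjects: int = 4
    n_localizer_runs: int = 2
    n_study_runs: int = 2
    lattice_shape: tuple = (12, 12, 12)
    sigma: float = 0.6
    penalty: float = 50.0
    search_penalty: bool = False
    feature_alpha: float = 0.05
    out_dir: str = "wmdecode_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        data["lattice_shape"] = tuple(data.get("lattice_shape", (12, 12, 12)))
        return cls(**data)

    def to_file(self, path) -> None:
        d = self.to_dict()
        d["lattice_shape"] = list(d["lattice_shape"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _simulate_cohort(cfg: PipelineConfig):
    catalog = dz.StimulusCatalog()
    gt_cfg = GroundTruthConfig(shape=tuple(cfg.lattice_shape), sigma=cfg.sigma)
    subjects = []
    for s in range(cfg.n_subjects):
        # independent trial orderings per subject, as in a real cohort
        loc = dz.build_localizer_design(catalog, cfg.n_localizer_runs,
                                        cfg.design_seed + s)
        study = dz.build_study_design(catalog, cfg.n_study_runs,
                                      cfg.design_seed + 1000 + s)
        truth = make_ground_truth(gt_cfg, seed=cfg.simulation_seed + 101 * s)
        subjects.append({
            "truth": truth,
            "loc_design": loc,
            "study_design": study,
            "localizer": simulate_subject(loc, truth, seed=cfg.simulation_seed + 7 + s),
            "study": simulate_subject(study, truth, seed=cfg.simulation_seed + 1007 + s),
        })
    return catalog, gt_cfg, subjects


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write a versioned report bundle.

    Returns a dict with the in-memory results and the manifest. Any stage
    failure aborts with an error naming the stage; the manifest then lists
    the outputs written so far.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": cfg.to_dict(), "config_hash": cfg.hash(),
                "outputs": [], "stages": []}
    results: dict = {}

    def _write_csv(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, index=False)
        manifest["outputs"].append(name)

    stage = "simulate"
    try:
        catalog, gt_cfg, subjects = _simulate_cohort(cfg)
        manifest["ground_truth"] = config_to_dict(gt_cfg)
        manifest["stages"].append(stage)

        stage = "decode-operations"
        op_rows, traj_by_subject, item_traj_by_subject = [], [], []
        fid_pairs = []
        importance_maps: dict = {}
        for s, subj in enumerate(subjects):
            loc, study = subj["loc_design"], subj["study_design"]
            zs_study = mvpa.zscore_runs(subj["study"])
            op_labels = mvpa.build_shifted_labels(
                study, "operation_fixation", "operation",
                classes=list(dz.MAIN_OPERATIONS))
            cv = mvpa.crossvalidate(zs_study, op_labels, lam=cfg.penalty,
                                    alpha=cfg.feature_alpha)
            op_rows.append({"subject": s, "accuracy": cv.accuracy, "auc": cv.auc})

            stage = "importance"
            Xop, yop, _ = mvpa.stack_usable(zs_study, op_labels)
            op_clf = mvpa.fit_ovr_logistic(
                Xop, yop, mvpa.anova_feature_select(Xop, yop, cfg.feature_alpha),
                cfg.penalty)
            for op in dz.MAIN_OPERATIONS:
                importance_maps.setdefault(op, []).append(
                    imp.compute_importance(op_clf, zs_study, op_labels, op))

            stage = "decode-representations"
            zs_loc = mvpa.zscore_runs(subj["localizer"])
            cat_labels = mvpa.build_shifted_labels(loc, "localizer_miniblock",
                                                   "category")
            lam = (mvpa.search_penalty(zs_loc, cat_labels, cfg.feature_alpha)
                   if cfg.search_penalty else cfg.penalty)
            Xtr, ytr, _ = mvpa.stack_usable(zs_loc, cat_labels)
            fmask = mvpa.anova_feature_select(Xtr, ytr, cfg.feature_alpha)
            clf = mvpa.fit_ovr_logistic(Xtr, ytr, fmask, lam)
            ev = mvpa.decode_timeseries(clf, zs_study)

            stage = "timecourses"
            trajs = timecourse.trial_average(ev, study,
                                             conditions=list(dz.MAIN_OPERATIONS))
            trajs = {c: timecourse.baseline_correct(t) for c, t in trajs.items()}
            traj_by_subject.append(timecourse.removal_trajectories(trajs))

            stage = "rsa"
            glm = rsa.fit_category_glm(zs_loc, loc)
            masks = rsa.select_category_voxels(glm, zs_loc)
            tmaps = rsa.fit_item_glm_lsa(zs_loc, loc, catalog)
            templates = rsa.build_item_templates(zs_loc, loc, tmaps, masks,
                                                 catalog=catalog)
            fid = rsa.encoding_fidelity(templates, mvpa.zscore_runs(subj["study"]),
                                        study, catalog=catalog)
            tags = itf.tag_pairs(study, catalog)
            fid_pairs.append((fid, tags))
            it_traj = rsa.item_timecourse(templates, zs_study, study)
            item_traj_by_subject.append(it_traj)

        _write_csv(pd.DataFrame(op_rows), "operation_decoding.csv")

        stage = "timecourse-stats"
        per_cond = {c: np.vstack([t[c] for t in traj_by_subject])
                    for c in traj_by_subject[0]}
        ws = timecourse.window_stats(per_cond)
        _write_csv(ws.pairwise, "trajectory_block_tests.csv")
        start_points = {c: timecourse.find_start_point(per_cond[c])
                        for c in per_cond if c != "maintain"}
        (out / "start_points.json").write_text(json.dumps(start_points, default=str))
        manifest["outputs"].append("start_points.json")

        stage = "importance-group"
        coords = subjects[0]["truth"].coords
        imp_rows = []
        for op, maps in importance_maps.items():
            g = imp.group_threshold(maps, coords)
            for v in np.flatnonzero(g.values != 0):
                imp_rows.append({"operation": op, "voxel": int(v),
                                 "x": int(coords[v, 0]), "y": int(coords[v, 1]),
                                 "z": int(coords[v, 2]),
                                 "value": float(g.values[v])})
        _write_csv(pd.DataFrame(imp_rows,
                                columns=["operation", "voxel", "x", "y", "z",
                                         "value"]),
                   "group_importance_maps.csv")

        stage = "item-timecourse"
        item_removal = []
        for trajs in item_traj_by_subject:
            means = {op: m.mean(axis=0) for op, m in trajs.items()
                     if op in dz.MAIN_OPERATIONS}
            means = {op: timecourse.baseline_correct(t)
                     for op, t in means.items()}
            item_removal.append(timecourse.removal_trajectories(means))
        item_cond = {c: np.vstack([t[c] for t in item_removal])
                     for c in item_removal[0]}
        item_starts = {c: timecourse.find_start_point(item_cond[c])
                       for c in item_cond if c != "maintain"}
        (out / "item_start_points.json").write_text(
            json.dumps(item_starts, default=str))
        manifest["outputs"].append("item_start_points.json")

        stage = "interference"
        res = itf.same_minus_different(fid_pairs)
        _write_csv(res.cells, "interference_cells.csv")
        _write_csv(res.delta.reset_index(), "interference_delta.csv")
        boot = itf.bootstrap_balance(fid_pairs, n_iter=200,
                                     seed=cfg.analysis_seed)
        (out / "interference_bootstrap.json").write_text(json.dumps(
            {k: v for k, v in boot.items() if k != "distribution"}))
        manifest["outputs"].append("interference_bootstrap.json")

        results.update({"operation_cv": op_rows, "window_stats": ws,
                        "start_points": start_points, "interference": res,
                        "bootstrap": boot})
    except Exception as e:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results


def import_bids_like(events_path, data_path, run_lengths: dict,
                     tr_seconds: float = dz.TR_SECONDS):
    """Load a BIDS-style events.tsv plus an HDF5 data container.

    Returns (TrialTable, VoxelDataset). NIfTI input is accepted when the
    data path ends in .nii/.nii.gz (one 4-D image; voxels from its nonzero
    mask; a single run).
    """
    from .simulate import VoxelDataset
    table = dz.read_events_tsv(events_path, run_lengths, tr_seconds)
    p = str(data_path)
    if p.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        img = nib.load(p)
        vol = np.asarray(img.dataobj)
        mask = np.any(vol != 0, axis=-1)
        coords = np.argwhere(mask)
        X = vol[mask].T.astype(float)
        run = table.runs[0]
        data = VoxelDataset({run: X}, tr_seconds, coords,
                            np.where(coords[:, 0] < mask.shape[0] / 2, "L", "R"),
                            np.ones(coords.shape[0], dtype=bool))
    else:
        data = VoxelDataset.load_h5(p)
    return table, data
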