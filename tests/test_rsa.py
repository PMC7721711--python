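"""GLM voxel selection, item templates, pattern similarity, fidelity."""

import warnings

import numpy as np
import pytest

import wmdecode as w
from wmdecode import rsa
from wmdecode.rsa import (EmptyMaskError, ItemTemplate, build_item_templates,
                          encoding_fidelity, fit_category_glm,
                          fit_item_glm_lsa, item_timecourse, localizer_rsa,
                          select_category_voxels, _ols_glm)
from wmdecode.simulate import VoxelDataset


@pytest.fixture(scope="module")
def loc_subject(loc_design_full, truth):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return w.zscore_runs(w.simulate_subject(loc_design_full, truth, seed=55))


@pytest.fixture(scope="module")
def templates(loc_subject, loc_design_full, truth, catalog):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = fit_category_glm(loc_subject, loc_design_full)
        masks = select_category_voxels(glm, loc_subject)
        tmaps = fit_item_glm_lsa(loc_subject, loc_design_full, catalog)
        return build_item_templates(loc_subject, loc_design_full, tmaps,
                                    masks, catalog=catalog)


class TestGlm:
    def test_noiseless_beta_recovery_exact(self):
        # data constructed from the design matrix must return its betas
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.random((80, 3)), np.ones(80)])
        B = rng.standard_normal((4, 10))
        res = _ols_glm(X, X @ B, [f"c{i}" for i in range(4)])
        assert np.allclose(res.betas, B, atol=1e-10)
        assert np.allclose(res.sigma2, 0.0, atol=1e-18)

    def test_inactive_regressor_beta_zero(self):
        rng = np.random.default_rng(1)
        x1 = np.repeat([1.0, 0.0], 40)
        x2 = np.repeat([0.0, 1.0], 40)
        Y = np.outer(x1, np.ones(5)) + rng.normal(0, 1e-12, (80, 5))
        res = _ols_glm(np.column_stack([x1, x2]), Y, ["a", "b"])
        assert np.allclose(res.betas[0], 1.0, atol=1e-6)
        assert np.allclose(res.betas[1], 0.0, atol=1e-6)

    def test_rank_deficiency_names_columns(self):
        X = np.ones((20, 2))
        with pytest.raises(ValueError, match="collinear"):
            _ols_glm(X, np.ones((20, 3)), ["a", "a_copy"])

    def test_category_glm_betas_separate_categories(self, loc_subject,
                                                    loc_design_full, truth):
        glm = fit_category_glm(loc_subject, loc_design_full)
        # the face regressor's beta pattern should align with the face
        # support, not the fruit support
        face_beta = glm.betas[0]
        face = truth.category_patterns["face"]
        fruit = truth.category_patterns["fruit"]
        corr_own = np.corrcoef(face_beta, face)[0, 1]
        corr_other = np.corrcoef(face_beta, fruit)[0, 1]
        assert corr_own > 0.5 > abs(corr_other)


class TestVoxelSelection:
    def test_planted_contiguous_block_retained(self, loc_subject,
                                               loc_design_full, truth):
        masks = select_category_voxels(
            fit_category_glm(loc_subject, loc_design_full), loc_subject)
        for cat in w.CATEGORIES:
            support = truth.category_patterns[cat] != 0
            overlap = (masks[cat] & support).sum() / masks[cat].sum()
            assert masks[cat].sum() >= 10
            assert overlap > 0.8, f"{cat} mask mostly off-support"

    def test_cluster_extent_removes_scattered_voxels(self):
        from wmdecode.rsa import _cluster_filter
        coords = np.array([[x, y, z] for x in range(6) for y in range(6)
                           for z in range(6)])
        sel = np.zeros(len(coords), dtype=bool)
        sel[0] = True                       # isolated voxel
        block = [i for i, c in enumerate(coords)
                 if 3 <= c[0] <= 5 and 3 <= c[1] <= 4 and c[2] == 3]
        sel[block] = True                   # 6-voxel block < extent 10
        out = _cluster_filter(sel, coords, extent=10)
        assert not out.any()
        big = [i for i, c in enumerate(coords)
               if 2 <= c[0] <= 4 and 2 <= c[1] <= 4 and 2 <= c[2] <= 3]
        sel2 = np.zeros(len(coords), dtype=bool)
        sel2[big] = True                    # 18-voxel block
        out2 = _cluster_filter(sel2, coords, extent=10)
        assert out2.sum() == len(big)

    def test_no_signal_category_raises(self, loc_design_full, catalog):
        cfg = w.GroundTruthConfig(shape=(10, 10, 10), a_cat=1e-9, a_sub=1e-9,
                                  a_item=1e-9, sigma=1.0)
        truth0 = w.make_ground_truth(cfg, seed=77)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = w.zscore_runs(w.simulate_subject(loc_design_full, truth0, seed=78))
        with pytest.raises(EmptyMaskError):
            select_category_voxels(fit_category_glm(d, loc_design_full), d)


class TestItemGlm:
    def test_own_item_contrast_positive_on_support(self, loc_subject,
                                                   loc_design_full, truth,
                                                   catalog):
        tmaps = fit_item_glm_lsa(loc_subject, loc_design_full, catalog)
        assert len(tmaps) == 54
        # per item, the mean t over its planted support exceeds the mean t
        # over another category's support
        hits = 0
        for it in (1, 10, 20, 30, 40, 50):
            sup = truth.item_patterns[it] != 0
            signed = np.sign(truth.item_patterns[it])
            own = np.mean(tmaps[it][sup] * signed[sup])
            if own > 0:
                hits += 1
        assert hits >= 5

    def test_missing_item_errors(self, loc_subject, loc_design_full, catalog):
        import copy
        d = copy.deepcopy(loc_design_full)
        d.frame = d.frame[d.frame["item"] != 7]
        with pytest.raises(ValueError, match="missing"):
            fit_item_glm_lsa(loc_subject, d, catalog)


class TestTemplates:
    def test_uniform_weights_give_plain_mean(self, loc_subject,
                                             loc_design_full, catalog):
        masks = {c: np.ones(loc_subject.n_voxels, dtype=bool)
                 for c in w.CATEGORIES}
        ones = {it: np.ones(loc_subject.n_voxels) for it in range(1, 55)}
        tpls = build_item_templates(loc_subject, loc_design_full, ones, masks,
                                    catalog=catalog)
        t = tpls[1]
        assert np.allclose(t.pattern, t.mean_pattern)

    def test_zero_weights_rejected(self, loc_subject, loc_design_full, catalog):
        masks = {c: np.ones(loc_subject.n_voxels, dtype=bool)
                 for c in w.CATEGORIES}
        zeros = {1: np.zeros(loc_subject.n_voxels)}
        with pytest.raises(ValueError, match="zero"):
            build_item_templates(loc_subject, loc_design_full, zeros, masks,
                                 catalog=catalog)

    def test_templates_use_localizer_only(self, loc_subject, loc_design_full,
                                          templates, truth, catalog):
        """Leakage check: study data cannot influence the templates."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = fit_category_glm(loc_subject, loc_design_full)
            masks = select_category_voxels(glm, loc_subject)
            tmaps = fit_item_glm_lsa(loc_subject, loc_design_full, catalog)
            again = build_item_templates(loc_subject, loc_design_full, tmaps,
                                         masks, catalog=catalog)
        for it in templates:
            assert np.array_equal(templates[it].pattern, again[it].pattern)


class TestSimilarity:
    def test_identical_pattern_hits_clip(self, templates):
        t = templates[1]
        z = rsa._weighted_z(t, _expand(t))
        assert z == pytest.approx(np.arctanh(1 - 1e-7))

    def test_localizer_rsa_partition_ordering(self, templates, loc_subject,
                                              loc_design_full, catalog):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lr = localizer_rsa(templates, loc_subject, loc_design_full,
                               catalog=catalog)
        means = lr.groupby("partition")["z"].mean()
        assert means["target"] > means["related_subcategory"]
        assert means["target"] > means["same_category"]
        assert means["related_subcategory"] > means["others"]

    def test_pure_noise_fidelity_near_zero(self, templates, study_design,
                                           catalog):
        rng = np.random.default_rng(6)
        V = max(t.voxels.max() for t in templates.values()) + 1
        coords = np.column_stack([np.arange(V) % 12, (np.arange(V) // 12) % 12,
                                  np.arange(V) // 144])
        runs = {r: rng.standard_normal((study_design.run_lengths[r], V))
                for r in study_design.runs}
        noise = VoxelDataset(runs, 0.46, coords, np.array(["L"] * V),
                             np.ones(V, dtype=bool))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fid = encoding_fidelity(templates, noise, study_design,
                                    catalog=catalog)
        assert abs(fid["fidelity"].mean()) < 0.05

    def test_planted_encoding_orders_target_related_others(
            self, templates, study_design, truth, catalog):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stu = w.zscore_runs(w.simulate_subject(study_design, truth, seed=57))
            fid = encoding_fidelity(templates, stu, study_design, catalog=catalog)
        assert fid["fidelity"].mean() > fid["related"].mean() > fid["others"].mean()

    def test_fidelity_gap_grows_with_item_amplitude(self, loc_design_full,
                                                    study_design, catalog):
        gaps = []
        # amplitudes keep a_sub = a_item so the zero arm removes all
        # finer-than-category structure (subcategory signal alone already
        # separates the target from other-subcategory "related" items)
        for a_item in (0.0, 0.35):
            cfg = w.GroundTruthConfig(shape=(10, 10, 10), a_item=a_item,
                                      a_sub=a_item)
            tr = w.make_ground_truth(cfg, seed=60)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                locd = w.zscore_runs(w.simulate_subject(loc_design_full, tr, seed=61))
                stud = w.zscore_runs(w.simulate_subject(study_design, tr, seed=62))
                glm = fit_category_glm(locd, loc_design_full)
                masks = select_category_voxels(glm, locd)
                tmaps = fit_item_glm_lsa(locd, loc_design_full, catalog)
                tpls = build_item_templates(locd, loc_design_full, tmaps, masks,
                                            catalog=catalog)
                fid = encoding_fidelity(tpls, stud, study_design, catalog=catalog)
            gaps.append(fid["fidelity"].mean() - fid["related"].mean())
        # with no planted item signal the target-vs-related gap collapses
        assert abs(gaps[0]) < 0.05
        assert gaps[1] > gaps[0] + 0.02

    def test_item_timecourse_shapes_and_flat_input(self, templates,
                                                   study_design):
        V = max(t.voxels.max() for t in templates.values()) + 1
        rng = np.random.default_rng(8)
        base = rng.standard_normal(V)
        runs = {r: np.tile(base, (study_design.run_lengths[r], 1))
                for r in study_design.runs}
        coords = np.column_stack([np.arange(V) % 12, (np.arange(V) // 12) % 12,
                                  np.arange(V) // 144])
        flat = VoxelDataset(runs, 0.46, coords, np.array(["L"] * V),
                            np.ones(V, dtype=bool))
        out = item_timecourse(templates, flat, study_design)
        for op, mat in out.items():
            assert mat.shape[1] == 30
            # constant input -> constant similarity series per trial
            assert np.allclose(mat, mat[:, :1])


def _expand(t: ItemTemplate) -> np.ndarray:
    """Full-lattice pattern equal to the template's weighted pattern where
    dividing by weights reproduces it (for the identity-similarity check)."""
    V = t.voxels.max() + 1
    full = np.zeros(V)
    w_ = np.where(t.weights == 0, 1.0, t.weights)
    full[t.voxels] = t.pattern / w_
    return full
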