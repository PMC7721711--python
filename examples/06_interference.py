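"""Proactive interference on the next trial's encoding.

For each operation, trial N+1's encoding fidelity is compared between pairs
where items N and N+1 share a category ("same") and pairs where they do not
("different"): Delta = same - different. Removing an item should release
interference; suppression here is planted to spare encoding of related
content, so its Delta is positive while the other operations' are negative.
"""

import warnings

import wmdecode as w
from wmdecode import interference as itf, rsa

catalog = w.StimulusCatalog()
cfg = w.GroundTruthConfig(shape=(12, 12, 12))

pairs = []
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for s in range(8):
        loc = w.build_localizer_design(catalog, 2, seed=30 + s)
        study = w.build_study_design(catalog, 2, seed=60 + s)
        truth = w.make_ground_truth(cfg, seed=90 + s)
        zl = w.zscore_runs(w.simulate_subject(loc, truth, seed=120 + s))
        zs = w.zscore_runs(w.simulate_subject(study, truth, seed=150 + s))
        glm = rsa.fit_category_glm(zl, loc)
        masks = rsa.select_category_voxels(glm, zl)
        tmaps = rsa.fit_item_glm_lsa(zl, loc, catalog)
        templates = rsa.build_item_templates(zl, loc, tmaps, masks,
                                             catalog=catalog)
        fid = rsa.encoding_fidelity(templates, zs, study, catalog=catalog)
        pairs.append((fid, itf.tag_pairs(study, catalog)))

    result = itf.same_minus_different(pairs)
print("same-minus-different encoding fidelity (Delta), mean over 8 subjects:")
for op, val in result.delta.mean().items():
    t = result.t_tests[op]
    print(f"  {op:12s} {val:+.3f}   t({t.df}) = {t.statistic:+.2f}, p = {t.p:.4f}")
print(f"\nRM-ANOVA across operations: F({result.anova.df}, "
      f"{result.anova.extra['df_error']}) = {result.anova.statistic:.2f}, "
      f"p = {result.anova.p:.2e}")
ops = list(result.delta.columns)
print("Tukey-Kramer pairwise contrasts involving suppress:")
for row in result.tukey:
    if ops.index("suppress") in (row["i"], row["j"]):
        print(f"  {ops[row['i']]} vs {ops[row['j']]}: p = {row['p']:.4f}")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    boot = itf.bootstrap_balance(pairs, n_iter=1000, n_sample=15, seed=99)
print("\nbalanced bootstrap (1000 iterations, 15 trials/cell), "
      "suppress-vs-other p-values:")
for k, p in boot["pairwise_p"].items():
    if "suppress" in k:
        print(f"  {k}: p = {p:.4f}")
print("a positive Delta only for suppress replicates the planted pattern: "
      "suppressed items keep interfering with related new encoding")
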