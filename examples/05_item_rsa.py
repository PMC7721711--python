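"""Item-level templates and encoding fidelity.

Category-selective voxels are chosen by a mini-block GLM contrast with
cluster correction; an LS-A GLM (one regressor per item) supplies signed
voxel weights; each item's template is its weighted mean localizer pattern.
A study trial's encoding fidelity F is the Fisher-z correlation between its
weighted presentation pattern and the presented item's template.
"""

import warnings

import wmdecode as w
from wmdecode import rsa

catalog = w.StimulusCatalog()
loc = w.build_localizer_design(catalog, 5, seed=20)
study = w.build_study_design(catalog, 2, seed=21)
truth = w.make_ground_truth(w.GroundTruthConfig(shape=(12, 12, 12)), seed=22)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    zl = w.zscore_runs(w.simulate_subject(loc, truth, seed=23))
    zs = w.zscore_runs(w.simulate_subject(study, truth, seed=24))

    glm = rsa.fit_category_glm(zl, loc)
    masks = rsa.select_category_voxels(glm, zl)
    print("category-selective voxels:",
          {c: int(m.sum()) for c, m in masks.items()})

    tmaps = rsa.fit_item_glm_lsa(zl, loc, catalog)
    templates = rsa.build_item_templates(zl, loc, tmaps, masks, catalog=catalog)

    lr = rsa.localizer_rsa(templates, zl, loc, catalog=catalog)
    print("\nlocalizer self-consistency (mean Fisher-z similarity):")
    for part in ("target", "related_subcategory", "same_category", "others"):
        print(f"  {part:20s} {lr[lr['partition'] == part]['z'].mean():+.3f}")

    fid = rsa.encoding_fidelity(templates, zs, study, catalog=catalog)
print("\nstudy-phase encoding fidelity over",
      len(fid), "trials (mean Fisher-z):")
print(f"  target  {fid['fidelity'].mean():+.3f}")
print(f"  related {fid['related'].mean():+.3f}")
print(f"  others  {fid['others'].mean():+.3f}")
print("target > related > others: the templates identify which specific "
      "image is in working memory, beyond its category")
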