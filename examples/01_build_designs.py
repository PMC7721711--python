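"""Build the localizer and central-study trial tables and check their
counterbalancing arithmetic.

The localizer shows each of 54 images once per run in subcategory triplets;
the study presents 60 trials per run, 12 per working-memory operation.
"""

import wmdecode as w

catalog = w.StimulusCatalog()
localizer = w.build_localizer_design(catalog, n_runs=5, seed=1)
study = w.build_study_design(catalog, n_runs=6, seed=2)

print(f"catalog: {catalog.n_items} items, "
      f"{catalog.frame['category'].nunique()} categories x "
      f"{catalog.frame.groupby('category')['subcategory'].nunique().iloc[0]} "
      f"subcategories x 6 exemplars")

f = localizer.frame
print(f"\nlocalizer: {len(f)} trials over {len(localizer.runs)} runs")
print("  per category:", f.groupby("category").size().to_dict())
print("  per exemplar:", f.groupby("item").size().unique().tolist(), "presentations")

g = study.frame
print(f"\nstudy: {len(g)} trials over {len(study.runs)} runs")
print("  per operation:", g.groupby("operation").size().to_dict())
print("  per operation x category:",
      sorted(g.groupby(["operation", "category"]).size().unique().tolist()))
print("  run lengths (TRs):", study.run_lengths)

# Every count above is a deterministic property of the design; only trial
# order and the jittered inter-trial intervals depend on the seed.
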