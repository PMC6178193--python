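"""Subtype classification before/after severity correction, plus MDS.

Runs the pipeline's central comparison: pairwise LDA with paired
leave-one-out CV on uncorrected degeneration maps vs severity-corrected
pattern maps.  Correction removes the severity confound, so subtype pairs
with overlapping severity distributions classify better after it.
"""

import numpy as np

import cerebsig as cs

cohort = cs.simulate(cs.SimulationConfig(grid_shape=(16, 16, 16), seed=0))
mask = cs.gm_mask(atlas=cohort.atlas)
res = cs.run_adjustment(cohort.maps, cohort.table, mask)

report = cs.run_classification_suite(res, cohort.table)
print("Cross-validated accuracies (paired leave-one-out folds):")
print(report.to_frame().round(3).to_string(index=False))

ids = cohort.table.subject_id.tolist()
X = np.array([res.degeneration[s].values for s in ids])
emb = cs.embed_mds(X, dims=2)
print(f"\nMDS of uncorrected maps: dim 1 explains "
      f"{100 * emb.variance_fractions[0]:.1f}% of variance "
      "(the overall-severity axis dominates before correction).")

pat_ids = [s for s in ids if s in res.pattern and not s.startswith("HC")]
Xc = np.array([res.pattern[s].values for s in pat_ids])
embc = cs.embed_mds(Xc, dims=2, correction_state="corrected")
print(f"MDS of corrected patterns: dim 1 explains "
      f"{100 * embc.variance_fractions[0]:.1f}% — variance now spreads over "
      "the pattern axes that separate subtypes.")
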