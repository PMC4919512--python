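"""Recover a planted temporal ordering of pathological factors.

Generates a synthetic longitudinal cohort in which the five imaging factors
have DS (disease-state) effects of decreasing magnitude — vascular strongest,
structural weakest — then runs the full analysis and prints the recovered
ordering next to the planted one.
"""

import mfdpm

cfg = mfdpm.SyntheticConfig(
    n_subjects=200, n_visits=4, n_regions=6, noise_sd=1.0, seed=1
)
cohort, truth = mfdpm.generate_cohort(cfg)
print(f"cohort: {cohort['subject_id'].nunique()} subjects, "
      f"{cohort['biomarker_id'].nunique()} biomarkers, {len(cohort)} records")

result = mfdpm.analyze(cohort, variants=("fixed_robust",))

print("planted order:  ", " > ".join(truth.planted_factor_order))
print("recovered order:", " > ".join(result.factor_order))
print("\nhierarchical matrix (% of region-time points where the column factor")
print("exceeds the row factor in abnormality):")
print(result.hierarchy.percentages.round(1))
print("\ntotal abnormality indices (1 = most abnormal biomarker):")
print(result.index_table["total"].groupby(
    result.index_table.index.str.split("__").str[0]
).mean().sort_values(ascending=False).round(3))
# The factor with the largest planted DS effect ends up with the largest
# area under its abnormality curve, so the recovered order matches.
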