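"""Bootstrap confidence bands for abnormality trajectories.

Resamples subjects with replacement (B = 200 here for speed; 500 by
default), reruns the whole pipeline per replicate, and prints the mean and
95% band of the total abnormality index per biomarker plus the stability of
the recovered factor ordering.
"""

import mfdpm
from mfdpm.bootstrap import bootstrap_pipeline

cfg = mfdpm.SyntheticConfig(
    n_subjects=150, n_visits=3, n_regions=2,
    factor_names=("vascular", "amyloid", "structural"),
    scalar_biomarker_names=("mmse",), noise_sd=1.0, seed=3,
)
cohort, truth = mfdpm.generate_cohort(cfg)

result = bootstrap_pipeline(cohort, B=200, seed=3, variants=("fixed_robust",))
print(f"successful replicates: {result.n_successful}/{result.n_resamples}\n")

print("total abnormality index, bootstrap mean [2.5%, 97.5%]:")
idx = result.indices
for bm in idx.index:
    m = idx.loc[bm, ("mean", "total")]
    lo = idx.loc[bm, ("lo", "total")]
    hi = idx.loc[bm, ("hi", "total")]
    print(f"  {bm:24s} {m:5.3f}  [{lo:5.3f}, {hi:5.3f}]")

print("\nfactor-ordering frequencies across replicates:")
for order, freq in sorted(result.order_frequencies.items(),
                          key=lambda kv: -kv[1]):
    print(f"  {' > '.join(order):40s} {freq:.2f}")
# Narrow bands and a dominant ordering frequency indicate the planted
# effect-size gaps are well resolved at this cohort size.
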