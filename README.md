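# mfdpm — multifactorial data-driven disease-progression modelling

`mfdpm` reconstructs per-biomarker aging/disease trajectories from
longitudinal multimodal cohorts, quantifies how abnormal each biomarker
becomes relative to healthy aging, and derives a data-driven temporal
ordering of pathological factors. It is aimed at researchers studying
late-onset neurodegeneration (e.g. Alzheimer's disease) who have regional
imaging biomarkers for several biological factors — vascular, amyloid,
metabolic, functional, structural — plus scalar cognitive and fluid
biomarkers, observed over repeated visits with an ordinal clinical
diagnosis. Because such cohorts are typically access-restricted, the
package ships a first-class synthetic-cohort generator with planted ground
truth (factor ordering, clinical converters, measurement outliers) so every
stage of the analysis is testable end to end.

## The model

Each standardized biomarker observation for subject *j* at visit *m* is
modelled as

    y_jm = x_jm' β + b_j + b_age,j · age_jm + ε_jm

where `x` contains an intercept, the five risk factors — age, disease
state `DS ∈ {1=HC, 2=EMCI, 3=LMCI, 4=LOAD}`, sex, education, apoe-ε4
allele count — and all 10 pairwise interactions (16 coefficients), `b_j`
and `b_age,j` are subject-level random effects and `ε` is noise. Three
nested variants — no random effects (fitted by robust bisquare
regression), random intercept, random intercept + age slope (both fitted
by maximum likelihood) — are compared per biomarker with
`BIC = k ln n − 2 log L`.

The fitted predictor is then **marginalized** over sex, education and
apoe-ε4 (uniform over each covariate's range by default), leaving a
function `g(age, DS)`. Evaluating `g` on a weekly grid of 1,560 ages over
a 30-year window (40–70 y) while `DS` ramps from 1 to a terminal state
(linearly or along a sigmoid) yields characteristic trajectories for the
four clinical transitions HC→HC, HC→EMCI, HC→LMCI, HC→LOAD. The
**abnormality** of a biomarker is `A(t) = |y_disease(t) − y_healthy(t)|`,
and its **total abnormality index** is the area under `A(t)` divided by a
normalization constant `K` (the maximum area across biomarkers), so the
most abnormal biomarker scores exactly 1; intermediate indices truncate
the integral at the EMCI/LMCI stage ages. Factor-level results are a 5×5
**hierarchical matrix** (percentage of region-time points at which one
factor's abnormality exceeds another's), **regional vulnerability
weights** (each region's summed abnormality across factors), and
vulnerability-weighted, globally normalized **factor curves** whose areas
give the temporal ordering. A subject-level bootstrap (B = 500 by default)
provides means and 95% percentile bands for everything.

Before modelling, a three-step quality control removes clinical
converters, drops subjects whose multimodal profile is atypical of their
diagnostic group (leave-one-subject-out Gaussian likelihood below the 10th
within-group percentile), and deletes records whose squared Mahalanobis
distance within their clinical group exceeds the χ² 0.95 quantile.

## Worked example

`examples/simulate_and_order.py` plants a factor ordering via decreasing
DS-effect magnitudes (adjacent gaps 0.25 sd, noise sd 1) and recovers it:

```
cohort: 200 subjects, 34 biomarkers, 27200 records
planted order:   vascular > amyloid > metabolic > functional > structural
recovered order: vascular > amyloid > metabolic > functional > structural

hierarchical matrix (% of region-time points where the column factor
exceeds the row factor in abnormality):
            vascular  amyloid  metabolic  functional  structural
vascular         0.0     16.6        2.7         0.0         0.0
amyloid         83.4      0.0       11.5         0.0         0.0
metabolic       97.3     88.5        0.0         8.6         0.0
functional     100.0    100.0       91.4         0.0         0.0
structural     100.0    100.0      100.0       100.0         0.0
```

Reading the matrix: the `vascular` column exceeds `amyloid` at 83.4% of
region-time points, and every row's entries plus the transposed entries
sum to 100. The per-factor mean total abnormality indices (vascular 0.94 →
structural 0.49) reproduce the planted gaps in normalized units. Other
examples cover quality control on contaminated cohorts
(`quality_control.py`), BIC variant selection (`model_selection.py`) and
bootstrap bands (`bootstrap_bands.py`).

A thin CLI mirrors the library (`mfdpm simulate | qc | fit | trajectories |
abnormality | ordering | bootstrap | run-all`); `mfdpm run-all --config
run.yaml` executes the whole pipeline into a results directory with every
intermediate table, the QC report, the resolved configuration and a run
log.

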