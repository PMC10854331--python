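# moodinstability

Mood instability — fluctuation and deviation away from one's average mood
state — is a core phenotypic feature of bipolar disorder (BD), yet routine
outcome monitoring still focuses on pre/post reductions in symptom-severity
scores. This package implements an instability-first alternative for
longitudinal patient-reported outcome measures (PROMs): it turns bi-monthly
PHQ-9 (depression), ASRM ((hypo)mania) and GAD-7 (anxiety) total scores into
a within-person **rolling-variance instability index**, stratifies
participants into **low / moderate / high instability thresholds** from
ranked percentiles, and fits the downstream mixed-effects models that compare
diagnostic groups and link instability to SF-12 functioning.

It is written for researchers running long observational mood cohorts (BD,
psychiatric-comparison and healthy-control arms) and for methodologists who
want a tested reference implementation of the rolling-variance index. Because
the motivating cohort data are restricted by a Data Use Agreement, the
package ships a seeded synthetic-cohort generator with known ground truth, so
the whole pipeline is reproducible and testable end to end.

## The method

For participant *i* with scores *x*<sub>*i*,1..*T*</sub> on one scale, the
instability series is the trailing sample variance over windows of *k*
consecutive non-missing assessments,

> s²<sub>*i*,*t*</sub> = 1/(k−1) · Σ<sub>j∈window(t)</sub> (x<sub>ij</sub> − x̄<sub>window</sub>)²,  k ∈ {3, 6, 12},

with *k* = 6 (one year of bi-monthly visits) the default; LOESS-based
diagnostics (mean squared error vs. the smooth, SD of the raw series) support
re-deriving *k* on new data by the "lowest MSE, highest SD" rule. Raw
variances are z-scaled against the pooled distribution of all windows of all
participants per scale (the continuous index) and cut at the ranked 60th and
95th percentiles: ≤ 60th percentile is *low*, 61st–94th *moderate*, ≥ 95th
*high*. Group differences in the continuous index are tested with a
random-intercept linear mixed model plus Tukey-adjusted pairwise contrasts;
category membership with Pearson chi-square tests; and functioning with

> SF12<sub>ij</sub> = γ₀₀ + γ₀₁·group<sub>j</sub> + γ₀₂·sex<sub>j</sub> + γ₀₃·race<sub>j</sub> + γ₀₄·age<sub>j</sub> + γ₁₀·threshold<sub>ij</sub> + U₀<sub>j</sub> + R<sub>ij</sub>,

a REML random-intercept model in T-score units (references: HC, male, white,
low). α = 0.001 throughout.

## Worked example

```python
import numpy as np
from moodinstability import (
    SyntheticCohortConfig, generate_cohort, rolling_variance, zscale,
    percentile_thresholds, classify_windows, participant_threshold,
    instability_group_model,
)

cfg = SyntheticCohortConfig(n_bd=60, n_pc=20, n_hc=30, seed=7)
ds, truth = generate_cohort(cfg)

inst = [rolling_variance(s, 6) for s in ds.series_for_scale("PHQ9")]
inst = [s for s in inst if s.windows]
zscale(inst)
th = percentile_thresholds(np.concatenate([s.raw() for s in inst]), "PHQ9")
print(f"cutoffs: low={th.low_cutoff:.2f}, high={th.high_cutoff:.2f}")

for s in inst:
    classify_windows(s, th)
pts = [t for s in inst if (t := participant_threshold(s, th))]
for c in instability_group_model(inst, ds.participants, "PHQ9"):
    print(f"{c.contrast[0]}-{c.contrast[1]}: d={c.standardized_effect:.2f}, "
          f"p={c.p_value:.2g}, significant={c.significant}")
```

prints

```
cutoffs: low=13.90, high=56.40
BD-HC: d=1.09, p=7.2e-11, significant=True
BD-PC: d=0.87, p=3.2e-06, significant=True
PC-HC: d=0.22, p=0.49, significant=False
```

A pooled PHQ-9 rolling variance of 13.9 score² marks the 60th percentile
(moderate-instability cutoff) and 56.4 the 95th (high cutoff) in this
synthetic cohort. The BD group's continuous instability index exceeds the
healthy controls' by about one total SD (d = 1.09) and the psychiatric
comparisons' by 0.87 — both significant at α = 0.001 — while PC and HC do not
differ, matching the generator's built-in BD > PC > HC variance ordering.

The same pipeline runs from the shell:

```bash
mood-instability simulate --preset study-shaped --seed 7 --out cohort.csv
mood-instability run --input cohort.csv --window 6 --out results/
```

which writes per-window and per-participant instability tables, threshold
JSONs, group-contrast / chi-square / functioning-model tables, figures, and a
run manifest sufficient to reproduce every output bit for bit.

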