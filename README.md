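# nrplast

Tools for analyzing training-induced learning and brain plasticity in
two-group (e.g. autistic vs typically developing children) pre/post cognitive
training studies. The package covers the full analysis chain:

* **Behavioral learning metrics** — inverse efficiency score
  (IES = mean correct RT / accuracy), per-child learning rate (OLS slope of
  daily IES on training day), proportional learning gains
  (gain = (post − pre)/pre), and dominant problem-solving strategy
  (memory-based retrieval vs rule-based counting/decomposition) with its
  rate; plus the statistical battery: mixed-design ANOVA with partial
  η², t tests with Cohen's d (d = t/√n), 2×2 χ² with ϕ = √(χ²/N), and
  default-prior (JZS) Bayes factors by numerical integration.
* **Neural representational plasticity (NRP)** — a searchlight statistic of
  how much a local multivoxel activation pattern changed between pre- and
  post-training scans. Within a 6 mm sphere at each gray-matter voxel the
  spatial Pearson correlation *r* between the pre and post t-score patterns
  is Fisher transformed, Z = ½·ln((1+r)/(1−r)), and negated:
  **NRP = −Z = −atanh(r)**. Higher NRP = more representational change;
  strongly negative NRP = stable representations.
* **Group inference** — voxel-wise two-sample t maps and the OLS model
  NRP ~ group + gain + group×gain (gain mean-centered, group coded 0/1), with
  cluster-extent family-wise-error correction by max-cluster-extent
  permutation (label permutation or Freedman–Lane sign flipping), and ROI
  extraction over peak spheres or supplied masks.
* **Moderation analysis** — gain ~ NRP × clinical moderator (e.g. insistence
  on sameness), mean-centered, with simple slopes, median-split labels, and a
  moderator × ROI specificity grid.
* **Synthetic cohorts** — a generator that emulates the study structure
  (group sizes, 5 training days, 14 trained/14 untrained problems,
  group-dependent strategy shift, and paired volumes with
  post = ρ·pre + √(1−ρ²)·ε so the local pattern stability ρ — and its
  coupling to learning gain, with opposite sign by group — is known exactly),
  making every downstream stage testable without restricted clinical data.

## Worked example

```python
import numpy as np
from nrplast import (CohortSpec, EffectRegion, PlasticitySpec, PlasticityGLM,
                     Searchlight, generate_behavior, generate_map_pair,
                     jzs_bayes_factor, mixed_anova)

# behavioral side: simulate a cohort and test the training effect on IES
data = generate_behavior(CohortSpec(seed=7))
ies = data.training.pivot(index="subject_id", columns="day", values="ies")
groups = data.subjects.set_index("subject_id").loc[ies.index, "group"]
print(mixed_anova(ies.to_numpy(), groups).summary())

# imaging side: paired volumes with opposite-sign NRP-gain coupling by group
rng = np.random.default_rng(7)
groups_arr = np.array(["ASD"] * 30 + ["TD"] * 30)
gains = rng.normal(0.06, 0.15, 60)
spec = PlasticitySpec(
    gain_vector=gains, groups=groups_arr, stability_base=0.5, seed=7,
    effect_regions=(EffectRegion(center=(16, 16, 16), radius_mm=8.0,
                                 coupling_by_group={"TD": 0.3, "ASD": -0.3}),))
sl = Searchlight(spec.resolved_mask(), radius_mm=6.0)
maps = [sl.map(generate_map_pair(spec, i)[0]) for i in range(60)]
res = PlasticityGLM(maps, groups_arr, gains).fit()
print(res.summary())
print(jzs_bayes_factor(2.54, 28))
```

This prints the ANOVA table for the training effect (for seed 7: session
F(4, 244) = 692.05, p < 0.001, η²p = 0.92 — the simulated daily IES decline
is strong by construction; group F = 2.38 and interaction F = 0.88, both
n.s.), then the voxel-wise model summary, where the `group:gain` term peaks
at |t| = 5.49 at voxel (15, 17, 14), inside the injected coupling region
(106 of 9328 mask voxels at p < 0.005), and finally the Bayes factor
`2.932` for a paired t = 2.54 at n = 28 ("insufficient" band, just below
moderate evidence).

A thin CLI mirrors the library: `nrplast simulate`, `nrplast behavior`,
`nrplast nrp`, `nrplast group`, `nrplast moderate` (see `--help`).

## Documentation

See `docs/methods.md` for the model, its assumptions, parameter defaults,
numerical choices, and known limitations.
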