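# Methods

This note documents the models and procedures implemented in `nrplast`, the
choices made where the design was genuinely open, and what the synthetic
cohorts can and cannot tell you about real data.

## Behavioral measures

**Inverse efficiency score (IES).** IES = mean correct-trial RT (ms) /
accuracy (fraction). Lower is better; it penalizes fast-but-inaccurate
responding. Undefined at zero accuracy — the subject-day is flagged NaN and
excluded upstream. The per-child **learning rate** is the OLS slope (ms/day)
of daily IES on training day index 1..5; days with missing IES are dropped,
and fewer than two valid days yields a missing value with a warning.

**Learning gain.** gain = (post − pre)/pre, applied to verification-task
accuracy and production-task RT. For RT a negative gain is a speed-up.
Undefined when pre = 0 (flagged).

**Dominant strategy.** Counting and decomposition collapse into
"rule-based"; retrieval is "memory-based". The dominant strategy is the
modal category over correctly solved problems; its rate divides the modal
count by the full problem-set size (14 per condition), not by the number of
correct problems, so children who solve few problems correctly get low
rates. Ties go to memory-based deterministically (a `tie_rule="flag"` switch
excludes them instead); determinism matters for reproducible pipelines and
any fixed rule is defensible since ties carry no signal about direction.

**Run validity.** A task run is invalid when accuracy falls below chance
(50%) or when ≥ 30% of trials received no response (`rule="any"`, the
default; `rule="all"` gives the conjunctive reading, since the two wordings
circulate). Subject-level motion exclusion drops a child only when excessive
motion (any translation > 10 mm, any rotation > 10°, or mean framewise
displacement > 0.5 mm) affects *more than half* of runs; exactly half keeps
the child. Cohort-level intensity outliers are flagged at > 3 SD using
leave-one-out mean and SD, so a single extreme subject cannot inflate the SD
and mask itself (with a plain pooled SD, one value 5 SDs from the rest of a
10-subject cohort would not even reach z = 3).

## Statistical battery

**Mixed-design ANOVA.** Classical sums-of-squares decomposition for a
between factor (two groups) crossed with a complete within factor: the group
term is tested against subjects-within-groups, the session and session×group
terms against the subject-within-group × session error. Complete balanced
within-subject data are required; incomplete designs are rejected rather
than approximated. Degenerate zero-error designs return F = 0 (no effect) or
F = ∞, p = 0 (exact effect), keeping edge cases well defined. Partial eta
squared uses the identity η²p = F·df1/(F·df1 + df2), Cohen's d = t/√n for
paired/one-sample contrasts, and Cohen's f = √(η²p/(1 − η²p)); these
identities exactly invert the reported statistic/effect-size pairs they are
validated against.

**χ² and ϕ.** Pearson chi-square on 2×2 tables without Yates continuity
correction by default (a flag enables it); ϕ = √(χ²/N). The uncorrected
convention is what makes ϕ consistent with the χ² value on the same table.

**JZS Bayes factors.** BF10 for t designs with a Cauchy(0, √2/2) prior on
the standardized effect and Jeffreys prior on variance, computed by adaptive
quadrature of the noncentral-t density over the prior
(`p(t|H1) = ∫ nct(t; df, δ√n_eff) dCauchy(δ)`), with n_eff = n for
paired/one-sample and n₁n₂/(n₁+n₂) for independent samples. The test suite
cross-checks this against the classical variance-inflation (g-prior)
integral and against pingouin to < 1e−6 relative error. Evidence bands:
> 10 strong H1, 3–10 moderate H1, 0.33–3 insufficient, 0.10–0.33 moderate
H0, < 0.10 strong H0.

## Neural representational plasticity

At each mask voxel, the searchlight gathers all in-mask voxels whose
center-to-center world-mm distance (through the volume affine, so
anisotropic voxels are handled) is within the radius (default 6 mm; 123
voxels at 2 mm isotropic in the interior), computes the Pearson correlation
r between the pre and post t-score patches, and assigns
NRP = −atanh(clamp(r)) to the center voxel.

Numerical choices:

* r is clamped to ±(1 − 1e−7) before atanh, keeping identical patterns
  finite (NRP ≈ −8.4) and order preserving.
* Spheres are truncated at the mask; neighborhoods below 10 in-mask voxels
  are marked invalid (tiny-patch correlations are too unstable to interpret),
  as are constant patches (r undefined).
* The optimized implementation groups searchlight centers by neighborhood
  size and reduces along the patch axis; because numpy's pairwise summation
  tree depends only on the reduced length, it reproduces a naive per-voxel
  loop bit for bit (asserted in the tests on an 8×8×8 volume).
* Voxel indices are 0-based; world coordinates come from the affine. The
  `Searchlight` class precomputes the neighbor table once per
  (mask, affine, radius), which is what makes cohort-scale and simulation
  use fast (~12 ms per subject on the 32³ test grid after ~0.3 s of setup).

The upstream t-maps must already be restricted to correctly solved trials;
the module consumes them as given.

## Group inference

The voxel-wise model is OLS NRP ~ 1 + group + gain + group×gain with group
coded 0/1 (reference group 0; TD by default when present) and gain
mean-centered before forming the product, so the group coefficient is the
group difference at average gain. Group-specific simple slopes follow from
the coefficients (reference slope = b_gain; other group = b_gain +
b_interaction). The two-sample map uses the pooled-variance t by default
(Welch via flag). All fits are closed-form linear algebra shared across
voxels and are invariant to subject ordering.

**Cluster correction.** Voxels with two-sided p below the height threshold
(default 0.005) are split by sign and grouped into connected components
(26-connectivity by default, 6 via flag — reported cluster extents depend on
this choice, so it is explicit). Family-wise error control uses the
permutation distribution of the maximum cluster extent: group labels are
permuted for the group term; for regression terms the reduced-model
residuals are sign-flipped per subject and added back to the reduced fit
before refitting (Freedman–Lane). Corrected p = (1 + #{max null extent ≥
observed extent})/(n_perm + 1), which is monotone nonincreasing in extent.
Permutation was chosen over Gaussian-random-field theory deliberately: it
needs no smoothness estimation or distributional assumptions, is exact under
exchangeability, and its error control is directly testable (the suite
verifies FWER ≈ 0.05 over 200 null cohorts). A mandatory seed makes every
correction reproducible.

ROI summaries average the valid NRP voxels inside a 6 mm sphere around a
supplied peak (in world mm) or inside a supplied anatomical mask; both modes
exist because peak-sphere and anatomical-mask extraction answer slightly
different questions. No atlas ships with the package.

## Moderation

gain ~ NRP + moderator + NRP×moderator with mean-centered predictors
(centering decorrelates the main effects from the product and makes the
interaction row directly interpretable — the standard moderation
convention). t = b/se holds exactly; df = n − 4; simple slopes are reported
at moderator mean ± 1 SD with delta-method standard errors. Median splits
label values strictly above the sample median "high", with at-median ties
going to "low" deterministically. The specificity scan refits the model over
every moderator × ROI cell; no multiplicity correction is applied by default
(a Bonferroni flag exists) because the scan is a descriptive specificity
check, not a confirmatory family.

## Synthetic cohorts

The behavioral generator draws daily IES as a linear decline (default
6000 ms on day 1, −800 ms/day, 400 ms noise — several seconds per problem
early in training is realistic for 8–11-year-olds on double+single-digit
addition) with accuracy rising from ~0.75; task gains are Gaussian around
group means (accuracy +0.05/+0.07 for ASD/TD, SD 0.15; RT −0.35 both
groups, SD 0.15 — comparable gains across groups with large RT speed-ups);
RRIB subscores are uniform integers on 0–10. Strategy codes are drawn per
problem as Bernoulli(memory probability) where the post-training probability
is 0.85 or 0.15 according to a subject-level dominance indicator drawn with
the group's shift probability (defaults 0.8 TD / 0.5 ASD): dominance
emerges from the per-problem counts, while the population dominance rate
tracks the specified probability (majority at p = 0.85 over 14 problems
occurs with probability 0.996). Post-training, ASD children keep similar
strategy mixes across trained and untrained problems, while TD children stay
near the pre-training mix for untrained ones.

The imaging generator constructs post = ρ·pre + √(1−ρ²)·ε from independent
unit-variance Gaussian fields, so the population voxel-wise pre/post
correlation equals ρ exactly and mask-mean searchlight NRP converges to
−atanh(ρ) (verified at ρ ∈ {0, 0.3, 0.5, 0.8}). Inside spherical effect
regions ρ varies linearly with the group-centered learning gain and is
clipped to ±0.99; couplings that would drive |ρ| ≥ 1 are rejected with the
offending region named. Fields are i.i.d. across voxels by default so the
closed forms stay exact; an optional Gaussian smoothing kernel (applied to
both fields, which preserves the voxel-wise ρ) emulates the spatial
smoothness of preprocessed maps. The default grid is 32³ at 2 mm with an
ellipsoidal mask (~9300 voxels) so simulations run quickly; full-scale grids
are supported through the spec.

The moderation cohort generator draws ROI NRPs and moderators as independent
standard normals and sets gain = b·(centered NRP × centered moderator) +
noise. The default noise SD 0.8 was calibrated by simulation to ≈ 80% power
for b = −0.8 at n = 19 (the analytic noncentral-t calculation suggests a
larger SD but is optimistic here because the product regressor is random and
heavy-tailed).

**What passing tests do not show.** The generators emulate the *statistical
structure* the pipeline assumes — they do not simulate BOLD time series,
hemodynamics, head motion, spatially structured noise, ADI item responses,
or realistic correlations between ROIs, between moderators, or between
behavior and imaging noise. Parameter-recovery results therefore validate
the estimators under their own assumptions, not robustness to the many ways
real pediatric fMRI data violate them.

## Known limitations

* The mixed ANOVA handles only the complete, two-group designs used here.
* Cluster-level inference inherits the usual caveat that significance
  attaches to the cluster, not to any single voxel within it.
* The permutation engines assume exchangeable subjects (group term) or
  exchangeable residual signs (regression terms); heteroscedastic groups are
  only partially covered by the Welch option.
* Simulation problem sizes in the test suite (32³ grids, 100–500
  replicates, 200 permutations) were chosen to make the Monte-Carlo bands
  informative while keeping the suite quick to run; rates sit well inside
  their bands, so conclusions do not hinge on these sizes.
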