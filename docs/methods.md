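# Methods

## The procedure

The pipeline estimates moderated multilevel mediation on trial-level
psychophysics data. One analysis run consists of:

1. **Trial exclusion**, in fixed order, single pass: (i) trials whose
   modality was misidentified; (ii) trials rated 0; (iii) trials whose
   reaction time lies more than 2 SDs from the subject's own mean,
   computed per modality over the trials surviving (i)–(ii). Each trial is
   counted under exactly one rule, so the report partitions the input.
2. **Centering and standardization.** Intensity level 1/2/3 becomes
   X = −1/0/+1. Ratings and reaction times are z-scored within
   group × modality strata (SD with n−1); the stratum means/SDs are kept
   for back-transformation of effects into NRS points and milliseconds.
3. **Mixed models.** Per group, a mediator model `M ~ X*W + (1 + X | subject)`
   and an outcome model `Y ~ X*W + M + M:W + (1 + X | subject)`, Gaussian,
   REML. The outcome model deliberately has no X:M interaction so that the
   additive decomposition TE = ME + DE holds exactly for every parameter
   draw.
4. **Quasi-Bayesian Monte-Carlo mediation.** n_sims (default 1000)
   independent draws of each model's fixed effects from
   N(β̂, V̂cov(β̂)); per draw and moderator level, ME = a·b, DE = c′,
   TE = ME + DE, prop = ME/TE. Points are draw means (median for prop —
   the ratio is heavy-tailed); CIs are 2.5/97.5 percentiles; an effect is
   significant when its CI excludes 0. Draws with |TE| < 1e−12 are dropped
   from the prop distribution and counted. Modality contrasts subtract the
   pain and touch draw vectors; the two-sided p is twice the smaller sign
   tail (zeros split evenly), floored at 2/n_sims and then reported as an
   inequality.
5. **Permutation group test.** The patients-minus-controls difference in
   proportion mediated is recomputed under subject-level relabelings
   preserving group sizes; p = (#qualifying + 1)/(n_perm + 1), two-sided
   on |difference| by default (`one_sided_exceed` selectable — the
   directional reading of "exceeds"). Preprocessing is done once on the
   original table; permutations relabel the preprocessed data. The
   observed statistic is computed with the same inner Monte-Carlo budget
   (default 200 draws) as the permuted ones, preserving exchangeability.
   Inner draws are re-randomized per permutation by default;
   `reuse_inner_seed=True` shares one set of inner draws across all
   relabelings, making the statistic a deterministic function of the
   labels (the variant that admits exact enumeration at tiny n, with
   identical relabelings cached).
6. **Descriptives.** Mixed between(group) × within(modality, intensity)
   repeated-measures ANOVA on subject cell means — classical univariate SS
   decomposition, each within effect tested against its own
   effect-by-subject error stratum; Greenhouse–Geisser df correction is
   optional (off by default, matching uncorrected univariate tests).
   Pearson correlations with a t-based two-sided p serve per-subject
   covariate checks (e.g., medication load vs mean ratings).

One master seed drives everything: `SeedSequence(master).spawn(3)` yields
the generator, mediation and permutation streams, which spawn further
children in a fixed documented order. Identical config + seed reproduces
every number bit for bit (the run manifest records the config hash).

## The mixed-model engine

Fits are computed by a profiled-REML solver specialized to per-subject
random intercept + intensity slope. Per subject, only the cross-products
X'X, X'y, Z'Z, Z'X, Z'y, y'y are kept; for a given Cholesky factor L of
G/σ², the Woodbury identity gives the V⁻¹-weighted cross-products and
log-determinants from q×q blocks (q ≤ 2, closed-form inverses, numba-
compiled). The fixed effects and σ² are profiled out; the remaining 3
variance parameters are optimized by Nelder–Mead (xatol 1e−3; a `fast`
mode with xatol 1e−2 and warm starts is used inside permutation loops,
where consecutive fits are nearly identical and sub-percent precision in
variance components is ample). Fixed-effect covariance is the standard
model-based σ²(X'V⁻¹X)⁻¹. On optimizer failure the model is refitted with
a random intercept only (reported as non-converged and counted in
permutation diagnostics); if that also fails, an error is raised. Working
on subject-level sufficient statistics makes a permutation cost four small
refits rather than four passes over the raw data — the difference between
minutes and hours for the calibration experiments. Tests cross-check
fixed effects, standard errors and variance components against
statsmodels MixedLM, and against a dense hand-built GLS solution on a toy
design.

Moderator coding is reference (touch = 0, pain = 1) by default; ±0.5
effect coding is available, and per-level paths are invariant to the
choice (tested to 1e−8).

## The synthetic generator

The generator emulates the paradigm: two groups (default 22 subjects
each), 4 blocks × 54 trials (9 per modality × intensity cell), block
orders satisfying the run-length constraints (no more than two equal
intensities, no more than three equal modalities in a row), per-subject
calibrated stimulus magnitudes (defaults at the published group means/SDs,
capped at 600 mJ / 512 mN), a small misidentification rate (4%) and
occasional zero ratings (2%).

The mediation structure lives on standardized latent scales with
X ∈ {−1, 0, +1}:

    M = a·X + u₀ᵢ + u₁ᵢ·X + ε,   Y = c′·X + b·M + v₀ᵢ + v₁ᵢ·X + η

with per-cell (group × modality) paths. Under `behavior_mediates` the
mediator latent maps to reaction time and the outcome latent to ratings;
`perception_mediates` swaps them; `none` severs the b path. RT mapping is
sign-flipped (`rt = rt_mean − rt_sd·latent`, floored at 100 ms): a larger
standardized behavior latent means a faster response, so fitted paths on
z-scores keep conventional signs (stimulus→RT negative, RT-mediated
effects on ratings positive). Ratings map affinely to the anchor scale
(center = middle anchor, scale = half the anchor span) and clip to
[0, 100].

Default paths are factored from the published behavior→perception point
estimates (patients: ME 0.067/DE 0.08 at pain, ME 0.007/DE 0.32 at touch;
controls: 0.05/0.11 and −0.005/0.34), giving proportions mediated of
≈ 45.6%/2.1% (patients) and ≈ 31%/−1.5% (controls). Two consequences are
worth stating plainly:

- With standardized total effects this small (≈ 0.15 z per level for
  pain), per-level mean ratings differ by only a few NRS points. The
  30/50/70 anchors are the *calibration targets* of the paradigm, not the
  realized level means — exactly what the published standardized
  coefficients imply about the real data.
- `true_standardized_effects` gives the closed-form population values of
  the fitted z-scale effects (ME = ±a·b/σ_Y etc., with σ_Y from the
  variance decomposition at Var(X) = 2/3); proportions mediated are
  invariant to all scalings and sign flips.

What the generator does **not** emulate: habituation/sensitization across
blocks, skin-site rotation, RT attention lapses/heavy tails,
subject-specific calibration failure, or any trial-order dependence.
Passing calibration tests on this generator therefore shows the inference
machinery is correct under the model's own assumptions, not that the
model is adequate for any particular real dataset.

Block sequences are sampled by constrained sequential construction
(uniform choice among the remaining trials that keep the run-length
constraints, restart on dead end, bounded restarts). Naive accept–reject
over full permutations has acceptance ≈ 2×10⁻⁵ for the joint constraints;
the sequential sampler is ~10⁴× faster at the cost of not being exactly
uniform over the valid sequences — immaterial here, since no analysis
consumes trial order (replicated experiments disable ordering entirely).

## Numerical and design choices

- **Proportion mediated point = median of per-draw ratios**, near-zero-TE
  draws excluded: the ratio distribution has no moments when TE can cross
  zero. The published work does not state its point-estimate convention;
  this one is robust and documented.
- **Independent mediator/outcome model draws**: the models are fitted
  separately, so there is no cross-model covariance to respect.
- **RT-outlier pooling** defaults to per-modality (RT distributions differ
  by modality; pooling would bias exclusions toward the slower modality);
  `rt_outlier_pool="all"` preserves the pooled reading of "the individual
  mean". Cells with < 3 surviving trials skip the rule (an SD from < 3
  trials is too unstable to trim on).
- **The ±2 SD RT rule truncates the RT distribution** per subject. When RT
  is the mediator this attenuates the stimulus→RT path by roughly 10–20%
  (selection on the dependent variable) and hence the fitted ME — a
  property of the published procedure itself, not an artifact of this
  implementation. Calibration and recovery experiments that compare
  against closed-form latent truths therefore standardize without the
  exclusion pass and use generator settings with negligible
  clipping/flooring (narrow anchor span, no misidentifications); the full
  pipeline keeps the rule.
- **Permutation +1 correction** keeps p in (0, 1]; Monte-Carlo p floors
  are always reported as inequalities, never as 0.
- **ANOVA df** are conventional (intensity has 2 numerator df at 3
  levels); subjects with an empty cell are dropped listwise.
- **Experiment problem sizes.** The calibration experiments in the test
  suite run at the study's scale (22+22 subjects, 108+108 trials: CI
  coverage over 400 datasets, type-I rate over 1000, proportion recovery
  over 100). The permutation null calibration uses 8+8 subjects × 108
  trials × 200 replicates at 99 permutations, and the enumeration check
  3+3 subjects — sizes chosen to make the null distributions dense enough
  to test while keeping the suite in the minutes range.

## Known limitations

- Inference on fixed-effect paths only; no random a/b paths, no
  treatment–mediator interaction decomposition, no sequential-ignorability
  sensitivity analysis.
- The quasi-Bayesian normal approximation ignores variance-parameter
  uncertainty; at ~22 subjects with > 100 trials each this is negligible
  for level-1 coefficients, but will degrade for much smaller designs.
- Gaussian responses only; ratings clipped at the scale ends and floored
  RTs mildly violate normality at the defaults (< ~2% of draws affected).
- The permutation test assumes exchangeable subjects under the null; no
  covariate-constrained permutation schemes are provided.
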