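# Methods

This note documents the statistical procedures implemented in promkit,
the numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Graded response model

Samejima's GRM for ordered categories: cumulative category probabilities
are two-parameter logistic curves, P*ₖ(θ) = σ(α(θ − βₖ)), and category
probabilities are their differences. One discrimination α > 0 and K−1
strictly increasing thresholds per item.

**Calibration** is marginal maximum likelihood by EM. The latent prior
is N(0,1) and fixes the scale (latent variance = 1). Integrals use 61
equally spaced quadrature nodes on [−6, 6] weighted by the normal
density and renormalized (the span keeps the prior's truncated tail mass
near 1e-9, so extreme response patterns score without truncation bias);
this grid is shared by calibration, EAP
scoring, MPWI item selection, and the S-X² rest-score recursion so that
every stage is internally consistent. The E-step computes per-person
posteriors over the nodes and accumulates expected category counts per
node; the M-step runs up to 3 guarded Newton iterations per item in an
unconstrained parametrization (log α; first threshold; log threshold
increments), with the Hessian obtained by finite differences of the
analytic gradient and step-halving so the expected log-likelihood never
decreases (a generalized EM step — this is what makes the marginal
log-likelihood path monotone). Convergence: maximum absolute parameter
change < 1e-4, cap 500 cycles; non-convergence sets a flag rather than
raising. Starting values are α = 1 and probit transforms of the
cumulative category proportions. Unobserved categories are collapsed to
consecutive codes before fitting and the mapping is stored on the model
(`category_maps_`), so later scoring re-applies it.

α is bounded to [e⁻³, e²·²] and thresholds to [−8, 8] inside the M-step;
these bounds are only active for degenerate items (e.g. near-empty
extreme categories) and keep the EM trajectory finite.

**Scoring** is EAP: posterior mean and SD over the grid. An all-missing
row returns the prior (θ̂ = 0, SE ≈ 1). T = 50 + 10·θ̂. SE(θ) is stored
in θ units throughout; only the reference-value crosswalk additionally
prints 10·SE for display on the T metric.

**Anchor vs local parameters.** Scoring accepts any `ItemParameters`
object, so an "anchor" calibration (the role played by the official
scoring-service parameters, which are not public) can be supplied
separately from locally fitted parameters
(`GradedResponseModel.from_parameters`). The pipeline fits local
parameters for reliability/efficiency work and uses the generating bank
as the anchor for reference values, mirroring the usual division.

**Marginal reliabilities.** The theoretical coefficient integrates the
approximate posterior variance 1/(1 + I(θ)) against the N(0,1) prior
(the prior contributes one unit of information); the empirical
coefficient is Var(θ̂)/(Var(θ̂) + mean SE²) over the observed score
table. Both are in [0,1] and agree when the sample actually is the
calibration population; ceiling-skewed samples push the empirical value
below the theoretical one because poorly measured persons concentrate
where the test has little information.

## Assumption checks

- **Polychoric correlations**: thresholds from inverse-normal cumulative
  marginals; pairwise ρ by ML on the bivariate-normal contingency model.
  The bivariate normal CDF uses the Drezner–Wesolowsky single-integral
  form with 24-point Gauss–Legendre (abs. error ~1e-7), which keeps the
  253 pairs of a 23-item bank fast. Indefinite matrices are projected to
  the nearest PSD correlation matrix before factoring (logged).
- **One-factor fit**: minres (least-squares) loadings; χ² from the ML
  discrepancy F = log|Σ̂| − log|S| + tr(SΣ̂⁻¹) − p scaled by (n−1);
  df = p(p−3)/2; baseline = zero-correlation model. CFI/TLI/RMSEA are
  therefore *unscaled* analogues of the robust (WLSMV-style) indices and
  are labelled as such in the report; the verdict thresholds
  (CFI/TLI ≥ 0.95, RMSEA ≤ 0.06, SRMR ≤ 0.08) are unchanged. Robust
  corrections would need the full weight matrix of the polychoric
  estimates, which is out of scope.
- **Local independence**: residuals r_ij − λᵢλⱼ; pairs > 0.20 flagged,
  reported as "count (percentage of pairs)".
- **Exploratory bifactor**: minres extraction of m oblique group factors
  (default m = 2, configurable — the right m is genuinely unknown a
  priori), varimax by Kaiser's pairwise rotations (the pairwise form
  escapes the symmetric saddle points where gradient updates stall),
  promax (power 4) with factor reflection, a second-order general factor
  on the factor correlations, then Schmid–Leiman orthogonalization.
  ECV = Σλ_g²/Σλ² and ωₕ = (Σλ_g)²/total summed-scale variance. The
  algebraic route (`bifactor_indices_from_loadings`) is exact and is the
  oracle the data route is tested against.
- **Mokken scalability**: H_ij = cov/cov_max with cov_max from the
  comonotone coupling of the observed marginals (sorted-sample
  matching); Hᵢ and H are ratio-of-sums aggregates. H = 1 on Guttman
  data exactly.
- **Monotonicity**: rest-score groups of at least max(n/10, 50) persons;
  a violation is a decrease of P(X ≥ k) across adjacent groups that
  exceeds 0.03 *and* is significant by a one-sided two-proportion z-test
  at α = 0.05. Both the group-size rule and the minimum violation follow
  common Mokken practice; GRM-generated data produce zero violations
  under these settings.
- **Invariant item ordering**: HT is the H coefficient of the transposed
  matrix restricted to person pairs with distinct totals (vectorized via
  sorted-row products). Bands: < 0.30 inaccurate, 0.30–0.39 low,
  0.40–0.49 medium, ≥ 0.50 high accuracy. Reported descriptively only —
  IIO is not an assumption of the GRM.

## Item fit (S-X²)

The generalized Orlando–Thissen statistic conditions on the rest score.
The model-implied rest-score distribution is the convolution of the
other items' category probability vectors per quadrature node,
marginalized against the prior; it matches exhaustive pattern
enumeration to machine precision on small banks (tested). Observed and
expected (rest score × category) counts are collapsed until every
expected cell ≥ 1 — from the distribution tails inward, categories
within a row before score rows; totals are preserved exactly.
df = Σ_rows(cells − 1) − K (the item's K free parameters), floored so
that items with df < 1 are reported untestable instead of given
p-values. Misfit flags at p < 0.001. Under the generating model the
empirical flag rate is well below 1% (tested over 200 replicates).

The plot-data helper bins persons by EAP θ̂ (default 10 quantile bins,
empty bins merged and recorded) and compares observed category
proportions with model-expected proportions at the bin mean; the
"negligible misfit" heuristic requires max |obs − exp| below 0.10 with
logically ordered expected curves.

## DIF

Per item, three nested proportional-odds (cumulative logit) models on
the observed categories: θ̂; θ̂ + group; θ̂ + group + θ̂×group. Fitting
is BFGS with an analytic gradient in an order-preserving
parametrization; the fit agrees with an independent ordered-logit
implementation to ~1e-3 (tested). McFadden R² = 1 − ℓ/ℓ₀ with ℓ₀ the
closed-form intercept-only likelihood. Uniform DIF effect =
R²(M2) − R²(M1), non-uniform = R²(M3) − R²(M2); their sum is the total
by construction. Flag at > 0.02. Multi-level covariates are scanned
pairwise and aggregated by the mean R² (pairwise rows retained).
The matching variable is the EAP θ̂ from all items, single pass;
iterative purification is deliberately not the default because the
threshold-based flagging the pipeline reports does not depend on it for
the effect sizes of interest, and a purified scan can be composed from
the same primitives if needed. Separation in a proportional-odds fit
triggers a lightly ridged refit and a convergence flag.

Impact: re-fit without flagged items, re-score, report mean/max absolute
T-score difference, % of persons with ≥ 1 T-point change, mean SE and %
reliable before/after, and both TCCs. For CAT, the replay additionally
reports whether flagged items were ever administered and their
information rank at each person's final θ̂.

## CAT

Post-hoc replay: first item = argmax information at θ = 0; then argmax
of ∫I_j(θ)·posterior(θ)dθ (MPWI) over unadministered items on the
shared grid; responses are read from the stored row; EAP after every
administration. Stopping: SE ≤ 0.32 once ≥ 4 items were given (the
minimum takes precedence even if the SE criterion was already met
earlier), otherwise at max_items = short-form length. Ties in selection
break at the lowest item index so replays are bit-for-bit deterministic.

## Evaluation

- Ceiling exclusion removes persons at the best-possible-functioning raw
  extreme: the *minimum* raw sum for symptom-coded measures, the
  *maximum* for function-coded ones.
- Efficiency E = (1 − SE²)/n_items; SE > 1 floors E at 0 (prior-
  dominated scores). Relative efficiency is the ratio of mean
  efficiencies; uncertainty by percentile bootstrap over persons (1,000
  resamples, seeded). The percentile method is used because only the
  resample count, not the CI construction, is conventionally fixed.
- Construct validity: observed Pearson |r| against hypothesized bounds
  (moderate > 0.30, strong > 0.50, etc.), with mismatches marked.
- Reference values: mean (SD) T per subgroup (total, child sex, parent
  sex) plus n; single-item measures are summarized by raw mean (SD)
  without IRT. The version crosswalk scores identical responses under
  two anchor sets/subsets and flags the reduced subset as provisional;
  dropping items can only increase mean SE (information additivity).

## Synthetic data

The generator emulates a general-population parent-proxy survey:

- **Banks**: 5–23 items, 5 categories, discriminations uniform on
  (0.9, 3.0) (loadings ≈ 0.5–0.9), bank thresholds spanning (−2.5, 2.5)
  by default. The emulated catalog (`study_measures`) mirrors eight
  measures with their published bank/short-form sizes, and gives the
  mobility-like measure a function-coded direction with a low threshold
  span (−3.0, 0.5) so precision degrades exactly where its heavy ceiling
  sits.
- **Traits**: N(0,1) by default (optionally skew-normal); a
  `ceiling_mass` fraction of persons is relocated into a narrow
  N(μ±2.5, 0.25²) component at the best-functioning end — this
  reproduces an excess of best-possible raw scores without fully
  degenerate response rows. Per-measure ceiling masses (1.7%–37.1%)
  are derived from the reported subgroup sizes after ceiling exclusion
  at n = 529.
- **Responses**: exact GRM category draws; DIF specs add a uniform
  threshold shift and/or a discrimination multiplier for one group on
  one item; a zero-effect spec reproduces the no-DIF data bit-for-bit
  under the same seed. Surveys with forced completion are emulated: no
  missing cells.
- **Legacy instrument**: a second latent trait, bivariate-normal with
  the study trait at a target correlation, drives 5-category items that
  are reverse-scored to the classical 0–100 metric
  (score = (K−1−response)·100/(K−1), higher = better functioning).
- **Reference subsample**: two-phase stratified selection — phase 1
  repeatedly draws from the stratum with the largest count deficit
  against the target margins, phase 2 fills the remainder at random;
  covariates whose achieved proportions deviate more than 2.5% from the
  margins are flagged (infeasible strata produce exactly such flags).
- A single study seed fans out to per-stage child seeds (CRC-stable, all
  below 2³¹), so stages are individually reproducible.

What it does **not** emulate: real item wording or content,
multidimensional traits, missing data or satisficing response styles,
panel-recruitment selection effects, and cross-language DIF. Passing
tests therefore demonstrate that the *procedures* behave correctly under
the model and the stated departures (ceiling, DIF), not that any real
instrument has these properties.

## Problem sizes in the default test run

Recovery checks run at n = 5,000 (large-sample) and n = 529 (the survey
scale). The type-I item-fit simulation uses 200 replicates at n = 2,000;
the DIF null uses 200 label permutations and the power check 100
simulated replicates at n = 500 per group; CAT properties use 1,000
persons; polychoric oracles use n = 10,000. These sizes put Monte-Carlo
error comfortably below the asserted tolerances.

## Known limitations

- Fit indices are unscaled; they coincide with robust-corrected values
  only approximately, although all verdicts use the conventional cutoffs.
- The theoretical marginal reliability uses the 1/(1 + I(θ)) posterior-
  variance approximation, which slightly understates the variance for
  very short tests.
- The EM M-step is a generalized (ascent) step, not a full maximizer per
  cycle; this trades a few extra cycles for robustness.
- Proportional-odds DIF models treat the matching θ̂ as fixed; no
  purification by default.
- The bifactor analysis is exploratory with a fixed group-factor count;
  confirmatory bifactor models are out of scope.
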