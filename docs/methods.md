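# Methods

This note documents the models, algorithms and design choices behind
`phyloscreen`, at the level of detail a user needs to judge what the
package computes and what its validation does and does not show.

## Data model

The unit of observation is one assay reading on one uniquely identified
sample, carried as a tidy long table: `sample_id, phylum, genus,
bioregion, category, assay_id, response`. Responses are
percent-of-control (dimensionless, ≥ 0, lower = more active); raw
readings with a control column are normalized on read as
`100·raw/control` (control must be strictly positive). The constituent
assays of a bioassay category — by default cytotoxicity (3 assays),
antimicrobial (4) and CNS-protective (2) — are treated as repeated
measures of one sample-level activity per category, and every category
is compiled and analysed independently end to end.

## Hit calling

Within a category, the activity threshold is `mean − 1·SD` of the
normalized responses, the comparison inclusive at equality. Choices
worth spelling out:

- **Pooling.** By default all constituent assays' values are pooled
  before the mean/SD (`pooling="pooled"`); a per-assay variant computes
  one threshold triple per assay. Both are defensible readings of a
  category-level "overall mean and standard deviation" over repeated
  measures; the pooled form follows the order of operations in the
  protocol this package reproduces and is what the tests pin down.
- **Combination rule.** A sample's per-assay flags are combined into
  the category call by `any` (default — active on any constituent hit,
  the sensitive screening convention), `all`, or `mean` (mean response
  vs threshold). The rule is surfaced in configuration and recorded on
  every call row.
- **SD denominator.** Sample SD (n−1). At screening-library sizes the
  difference from the population SD is negligible; at tiny n it is the
  conventional choice for an estimated mean.
- **Degenerate scopes.** Fewer than two in-scope values is an error; a
  zero-variance scope sets the threshold to the mean and warns (all
  values then sit at or below threshold under the inclusive rule).
- **Ragged panels.** Samples measured in only part of a category's
  panel are called on the available assays and counted in
  `calls.attrs["n_partial_samples"]`.

A caution on monotonicity: with thresholds *held fixed*, lowering any
response can only create hits. If thresholds are *recomputed* after a
perturbation, other samples' calls can legitimately flip (lowering one
value drags the mean down and inflates the SD, so the threshold can
drop below a previously-hit response). The perturbed sample itself can
never flip to inactive — `x − mean(x) + sd(x)` is increasing in `x` —
and that is the property the tests assert.

Cell summaries count distinct sample ids per (taxon, bioregion,
category) and report `100·n_active/n_tested`; empty cells are absent
rather than zero-filled.

## Bayesian models

**Hierarchical tier.** Per-sample category-level indicators:

    y_i ~ Bernoulli(p_i)
    logit(p_i) = mu + a[taxon(i)] + b[bioregion(i)] + u[cell(i)]
    a, b sum-to-zero fixed effects;  u_c ~ Normal(0, sigma_cell)
    mu, free a's, free b's ~ Normal(0, 100);  sigma_cell ~ Uniform(0, 100]

Sum-to-zero coding (last level = −sum of the rest) makes the marginal
means invariant to level ordering and decorrelates the intercept from
the effects. Samples in one cell share a linear predictor, so the
likelihood reduces to per-cell binomial counts — the sufficient
statistics the sampler operates on. The binary-call response is one
reading of a protocol that modelled "actual bioassay results"; this
package commits to it and does not claim to replicate any unpublished
model code.

**Main-effects tier.** Observed cell percentages with one fixed factor:

    pct_c ~ Normal(mu + e[level(c)], sigma_resid)

same prior structure; `sigma_fixed` can pin the residual SD (used by
the conjugate validation scenario). Its credible intervals can extend
outside [0, 100]; reported bounds are truncated for display with the
untruncated values retained in `*_raw` columns.

The priors — Normal(0, sd 100) coefficients, Uniform(0, 100] scales —
are the BUGS-era "non-informative" conventions, and both are
configurable (`prior_coef_sd`, `prior_sd_upper`).

## Sampler

The core is component-wise adaptive random-walk Metropolis
(Metropolis-within-Gibbs): each iteration sweeps the parameter vector,
proposing Gaussian moves component by component and accepting by the
Metropolis rule, with each move evaluated incrementally in
O(affected cells). Proposal scales adapt toward 44% acceptance (the
1-D optimum) in 50-iteration batches during burn-in only, by a decaying
Robbins–Monro update on the log scale, so the post-burn-in kernel is
fixed. Chains initialize overdispersed as a deterministic function of
`seed + chain`; identical inputs and seed give identical draws.

Three kernel refinements, all standard and all motivated by the
(cell-effects, σ) *scale funnel* — the direction along which plain
component-wise moves are slowest:

1. **Exact conditional draws for scale parameters.** Under the uniform
   prior, σ⁻² | rest is Gamma((m−1)/2, Σ²/2) truncated to the prior
   support; it is drawn exactly by inverse-CDF once per iteration (the
   draw is clamped to the truncated support, guarding against CDF
   round-off when the in-support tail mass underflows).
2. **A joint rescale move** proposing `(u, σ) → (c·u, c·σ)`,
   `c = exp(ε)`: the Normal prior's quadratic term is invariant, so the
   MH log-ratio is just the likelihood change plus ε (prior and
   Jacobian terms net out). ε's scale self-adapts during burn-in. The
   running Σu² is refreshed exactly (`math.fsum`) at each call —
   incremental tracking loses all precision during large rescales.
3. **Within-iteration kernel composition.** The hierarchical model
   runs three full component scans per iteration, with the
   scale block (six rescale attempts plus the σ conditional draw)
   interleaved before each scan and at the start. Interleaving matters:
   back-to-back rescale attempts from an unchanged u-configuration
   saturate quickly, while alternating them with component scans lets
   the scale and shape of the random-effect vector relax together. How
   the sweep kernel is composed per iteration is a sampler design
   choice (BUGS-family samplers likewise apply different update schemes
   per node); it reduces the per-iteration autocorrelation that
   post-hoc thinning must absorb.

Without these, σ_cell's lag-1 autocorrelation sits at ≈0.98–0.997 at
the full schedule and no thinning factor up to 20 restores
independence; with them, every parameter passes the 0.1 rule after
thinning by 20 in all three default categories.

## Diagnostics

`diagnose` computes, per parameter: lag-1 autocorrelation on the
concatenated post-burn-in thinned chains (each chain centred by its own
mean; only within-chain lag products are pooled, so chain seams
contribute nothing), split R-hat and bulk ESS via ArviZ. The run passes
iff every |lag-1 autocorrelation| < 0.1 and every R-hat < 1.05;
constant-parameter chains and chains that accepted no post-burn-in
moves are explicit failures. If only the autocorrelation rule fails,
the smallest factor in {2, 5, 10, 20} whose thinned chains pass is
recommended, and `auto_thin` applies it. Concatenation matters: at
thin 20 the per-chain estimate (750 draws) has a pure-noise maximum
across ~150 parameters near the 0.1 limit itself, which would make the
rule unsatisfiable by construction; pooling across chains (2,250
draws) puts the noise floor near 0.06.

R-hat replaces a visual convergence assessment in the original
protocol; a visual check is not testable, the numeric one is.

## Marginal means and lineage roll-ups

For the hierarchical tier, a taxon's marginal mean per draw is the
average of `expit(mu + a_t + b_r)` over the observed levels of the
other factor with the cell effect at zero — the *typical* cell —
scaled to percent; `integrate_cell_noise=True` instead integrates the
cell effect over Normal(0, σ) with 21-point Gauss–Hermite quadrature
(the noise-integrated mean of a low probability is pulled toward 50%,
so the two summaries answer slightly different questions). The grand
mean is the per-draw average over levels; intervals are equal-tailed
2.5/97.5 percentiles of the draw vectors.

Lineage roll-ups map each taxon to its phylogenetic lineage
(plant/algae; Early-Metazoan = Porifera; Early-Eumetazoan = Cnidaria;
Deuterostome = Echinodermata, Chordata; non-Deuterostome = Bryozoa,
Mollusca, Annelida, Crustacea — shipped as an editable TSV, with a
binary deuterostome-including-ancestral-phyla grouping for the animal
phyla only). The default roll-up averages member phyla's per-draw
marginal means with equal weight, propagating the posterior; a
sample-size-weighted `pooled` variant is provided. "CI excludes the
grand mean" statements in the validation are operationalized as
interval disjointness — the level's 95% CI not overlapping the grand
mean's own 95% CI — the way such statements are read off an interval
plot; a point comparison would mis-state the joint null property across
ten bioregions (~5% per-level false exclusions compound to ~40% per
dataset).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with a ground-truth ledger for recovery tests:

- 13 phyla × 10 coded bioregions (no code "9") × 3 categories with
  3+4+2 constituent assays — the screening-programme design.
- Per-cell sample counts: Negative-Binomial(mean 16, shape 2) by
  default — strongly imbalanced, and totalling ≈18–19k records, the
  scale of the real library; balanced integers or explicit per-cell
  maps are available. No claim is made of matching the real library's
  (unpublished) per-cell counts.
- Latent activity: `Bernoulli(expit(mu + phylum + bioregion + z_cell))`
  with one noise draw `z_cell ~ Normal(0, 0.25)` per cell (matching the
  model's cell-level random effect), `mu = logit(0.15)` baseline
  prevalence, a +1.5 logit Porifera effect and null bioregion effects —
  the qualitative findings of the study this package reproduces, as
  ground truth.
- Responses: active samples centre at `100 − 40`, inactive at 100, with
  Normal(0, 15) per-assay noise, truncated at 0. All assays of a
  category share the sample's latent state (the repeated measure);
  noise is independent per assay.
- Draw order is fixed (cell sizes → cell noise → latent states →
  responses) and a single seeded `numpy` Generator drives everything,
  so identical config+seed is byte-identical. Genus labels are assigned
  round-robin within phylum (`{phylum}_g{k}`), giving zero genus-level
  heterogeneity by construction. Samples are generated independently
  per category; since every analysis is per-category, no downstream
  stage depends on cross-category sample identity.

What the generator does **not** emulate: plate/batch structure, spatial
coordinates, depth or season, dose–response, within-species ecological
variability, or genus-level effect heterogeneity. Passing recovery
tests therefore show the *inference machinery* is correct under the
assumed structure — not that real screening data satisfy that
structure.

## Validation scenarios and problem sizes

The test suite exercises, at sizes chosen to keep the default run in
the tens of minutes on one CPU:

- exact brute-force equivalence of the entire scoring path on 1,000
  ragged random records (all pooling × rule combinations);
- the hand-computed threshold example ([100,100,100,60] → 70, one hit,
  inclusive at equality);
- sampler correctness against a 2-D standard-normal target, the
  normal-normal conjugate closed form (3×5,000 draws; mean and CI
  endpoints within 3 Monte-Carlo SEs) and a dense-grid numeric
  posterior for a two-level model (within 0.5 percentage points);
- frequentist calibration: 95% CI coverage over 200 simulated datasets
  at a reduced 3×2,000/500 schedule, required within 95% ± 4%;
- qualitative recovery over 50 replicate screens (cell_n = 40,
  3×1,200/400): the Porifera interval separates from the grand mean and
  no bioregion's does, in ≥ 90% of replicates. These scenarios generate
  with zero cell noise so that the stated null actually holds in
  realization — with cell noise on, a bioregion's 13 realized cell
  effects average to a genuinely nonzero deviation that the model
  correctly flags;
- genus/phylum consistency: with zero genus heterogeneity, per-phylum
  averages of genus-level marginal means within 2 percentage points of
  the phylum-level analysis;
- feasibility: the full ≈19k-record library analysed at the published
  3×20,000/5,000 schedule for all three categories in well under 15
  minutes, passing the autocorrelation rule after automatic thinning.

## Known limitations

- The exact likelihoods of the original analysis were never published;
  the two tiers here are the minimal structures consistent with its
  description, and no equivalence to the original model code is
  claimed.
- The Bernoulli/Normal tiers ignore overdispersion sources other than
  the cell random effect.
- Thresholds are category-global; assay-level drift within a category
  is only addressed by the per-assay pooling option.
- The main-effects tier treats cell percentages as homoscedastic
  Normal, ignoring their binomial denominator; it is the deliberately
  simple second tier, not the primary inference.
- MCMC scalability is adequate for hundreds of parameters (genus-level
  fits, ~440 parameters, run in tens of seconds at reduced schedules)
  but the sampler is pure Python; thousands of taxa would need a
  different engine.
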