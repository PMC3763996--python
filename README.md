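# phyloscreen

Statistical analysis of natural-product bioactivity screening across
taxonomy and biogeography.

Large marine biodiscovery programmes screen thousands of organism
extracts — sponges, corals, algae, ascidians and more, collected across
coded bioregions — in panels of bioassays (cytotoxicity against tumour
cell lines, antimicrobial growth inhibition, CNS-target inhibition).
The scientific questions are distributional: *which phyla are enriched
for bioactive samples? do any collection bioregions stand out once
taxonomy is accounted for? does phylogenetic lineage (deuterostomes and
their ancestral phyla versus non-deuterostomes) organise the signal?*
`phyloscreen` implements the full analysis chain for questions of this
shape, together with a synthetic-library generator with known ground
truth so every stage can be validated end to end.

## The method

**Hit calling.** Each assay reading is normalized to its control,
`response = 100·raw/control`, so lower values mean stronger activity.
Within a bioassay category the overall mean and sample SD of the pooled
responses define the activity threshold

&nbsp;&nbsp;&nbsp;&nbsp;*T = x̄ − s*,

and a sample is *active* in a category if any of its constituent-assay
responses is ≤ *T* (the constituent assays are repeated measures of one
latent activity; the combination rule is configurable). Calls are
aggregated into (taxon × bioregion) data cells as percent active.

**Models.** Two Bayesian tiers, fitted by a bespoke
Metropolis-within-Gibbs sampler:

- *Hierarchical tier* — per-sample activity indicators:
  `y_i ~ Bernoulli(p_i)`,
  `logit(p_i) = μ + a_taxon(i) + b_region(i) + u_cell(i)`,
  with sum-to-zero fixed effects, a `Normal(0, σ_cell)` random effect
  per data cell, `Normal(0, 100)` priors on coefficients and a
  `Uniform(0, 100]` prior on σ.
- *Main-effects tier* — observed cell percentages:
  `pct_c ~ Normal(μ + e_level(c), σ)` with a single fixed factor.

Inference follows the screening-study protocol: 3 chains × 20,000
iterations after a 5,000-iteration burn-in; sample independence is
enforced by requiring every parameter's lag-1 autocorrelation < 0.1
(with automatic thinning), plus split R-hat < 1.05. Results are
*posterior predicted marginal means* per factor level — for a taxon,
the draw-wise average of `expit(μ + a_t + b_r)` over observed
bioregions (cell effect at zero), ×100 — with equal-tailed 95% credible
intervals, and roll-ups of taxa into phylogenetic lineages
(plant/algae, Early-Metazoan, Early-Eumetazoan, Deuterostome,
non-Deuterostome).

## Worked example

```python
import phyloscreen as ps

# a synthetic screening library: 13 phyla x 10 bioregions, one category,
# a +1.5 logit Porifera effect and no bioregion effects
cfg = ps.SimConfig(categories={"CYTOTOX": ("C1", "C2", "C3")},
                   cell_n=40, cell_noise_sd=0.0, seed=1000)
records, truth = ps.generate_screen(cfg)

calls = ps.ActivityScorer().fit_transform(records)   # mean - 1 SD hit calls
calls["taxon"] = calls["phylum"]

model = ps.HierarchicalActivityModel(n_iter=1500, burn_in=500,
                                     random_state=2000)
model.fit(calls)
mm = model.marginal_means("taxon", allow_unconverged=True)
print(mm[["level", "mean", "ci_lower", "ci_upper"]].tail(3).to_string(index=False))
```

prints

```
     level      mean  ci_lower  ci_upper
  Porifera 48.859576 43.105013 54.561375
Rhodophyta 25.987057 21.112789 31.234534
GRAND_MEAN 23.847845 22.474183 25.183146
```

The Porifera marginal mean (≈49% of samples active, CI [43, 55]) sits
far above the grand mean (≈24%, CI [22.5, 25.2]) — the generator's
elevated-sponge condition, recovered from raw simulated plate readings.
With ten bioregions and null regional effects, no bioregion's interval
separates from the grand mean the same way.

A command-line pipeline wraps the same steps
(`phyloscreen all --config config.yaml --seed 7`), writing thresholds,
calls, cell summaries, posterior draws, diagnostics, marginal means and
lineage means as CSVs under a run directory; see `phyloscreen --help`.

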