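# rivergsi

Quantifying how tributary source populations support a main-stem river
fish population, from SNP genotypes to riverscape-level inference.

Migratory salmonids spawn in tributaries and grow in main-stem rivers, so
the adults captured in a large river are a *mixture* of fish born in many
genetically distinct tributary populations. Given baseline genotypes from
known spawning tributaries and mixture genotypes from the main stem, this
package estimates how much each tributary contributes to each river
section, models what drives those contributions (distance, catchment
area, groundwater availability, barriers), and describes the spatial
structure left over. It is aimed at fish ecologists and conservation
geneticists running mixed-stock analyses on dendritic river networks.

## The inference chain

1. **Baseline construction** (`genotypes`, `relatedness`, `baseline`) —
   call-rate (≥ 85%) and locus QC; pairwise relatedness with the
   genotype-similarity moment estimator, classifying pairs with r > 0.4 as
   full siblings and keeping two per family; pairwise and global
   Weir–Cockerham θ (variance components, ratio of sums across loci);
   leave-one-out self-assignment under the Hardy–Weinberg likelihood with
   Dirichlet-posterior allele frequencies; iterative aggregation of
   confusable pairs (self-assignment < 0.7, θ < 0.01, same stream) into
   reporting units; exclusion of tiny leftover collections (n ≤ 5); and a
   gene-dropping simulation that measures per-unit bias of re-estimated
   mixing proportions.
2. **Mixed-stock analysis** (`gsi`) — conditional Bayesian GSI: unit
   allele frequencies fixed at posterior means, latent origins z_i and
   mixing proportions π sampled by Gibbs (π ~ Dirichlet(1/U + counts));
   parametric-bootstrap bias correction of π; z-scores
   z = (log L − μ)/σ flagging fish from sources missing from the
   baseline (±2 SD rule); flow-line dispersal distances.
3. **Composition models** (`dirichlet_model`) — zero-inflated Dirichlet
   regression of section-year compositions under five designs (null,
   section, year, section + year, + interaction), ranked by exact
   leave-one-out cross-validation (elpd_loo).
4. **Contribution drivers** (`zib_model`) — the hierarchical
   zero-inflated beta model: p_rsy is a structural zero with probability
   ω_rsy, otherwise Beta(μ_rsy φ_rsy, (1 − μ_rsy) φ_rsy), with

       logit μ_rsy = α′ + α′_s + α′_r + β₁′ D_rs + β₂′ A_r + β₃′_s G_r + β₄′[C_r]
       logit ω_rsy = α″ + β₁″ D_rs + β₂″ A_r + β₃″ G_r + β₄″[C_r]
       log   φ_rsy = α‴ + β₁‴ D_rs + β₂‴ A_r + β₃‴ G_r + β₄‴[C_r]

   sampled by Hamiltonian Monte Carlo with analytic gradients
   (`mcmc`), with split-R̂/ESS diagnostics, posterior predictive checks,
   and effect curves.
5. **Spatial structure** (`spatial`) — watercourse (tree-path) and
   Euclidean distances, empirical semivariograms of the model's unit
   random intercepts (20 bins, ≥ 21-pair support rule, lowess display
   smooth with span 0.7), an inflection-scale diagnostic, latitude trend
   and region summaries.

A synthetic riverscape generator (`riverscape`) emulates the study
system — 52 tributary populations at 266 SNP loci with global F_ST ≈
0.04, full-sib families, replicate same-stream collections, a six-section
main stem sampled for three years at ~500 adults per year, covariates with
realistic connectivity-category counts, and true contributions drawn from
the zero-inflated beta forward model — so every stage is testable against
known truth. `pipeline.run_pipeline` chains everything with a structured
config, seeds, and a checksummed run report.

## Worked example

The numbered scripts under `analysis/` walk the chain on a reduced
synthetic riverscape (16 populations, 150 loci, 200 fish/year):

```bash
python analysis/01_simulate_riverscape.py
python analysis/02_baseline_construction.py
python analysis/03_mixture_assignment.py
python analysis/04_composition_models.py
python analysis/05_contribution_drivers.py
python analysis/06_spatial_structure.py
```

`02_baseline_construction.py` prints:

```
16 reporting units from 21 collections (3 merges, 2 excluded)
sibling filter pruned 42 fish
global FST = 0.041; 100.0% of pairwise values > 0.01
self-assignment: range 0.72-0.87, weighted mean 0.80
```

— the three planted same-stream replicate pairs merged, the two tiny
collections were excluded, and the realized differentiation matches the
generator's θ. `03_mixture_assignment.py` then reports

```
89.4% of fish assigned to a single unit with > 70% posterior probability
bootstrap-corrected vs raw proportions: Pearson r = 0.998
dispersal: median 22 km, max 106 km
```

and `04_composition_models.py` ranks the five composition hypotheses,
recovering the generator's year-constant truth:

```
 id            model  elpd_loo  elpd_diff
  2          Section       4.3        0.0
  4   Section + Year     -12.2      -16.5
  1             Null     -27.3      -31.6
```

`05_contribution_drivers.py` reports the fitted covariate effects (logit
scale, per SD): distance −0.25 [−0.47, −0.05], area +0.22, waterfall
barrier −1.62 — contributions fall with distance, rise with catchment
size, and are suppressed by barriers, with all 21 posterior predictive
statistics interior.

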