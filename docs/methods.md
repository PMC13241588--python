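# Methods

This note records the models behind `rivergsi`, the choices made where the
design was genuinely open, and what the synthetic riverscape does and does
not emulate.

## Genotype handling and QC

Diploid SNP calls are stored verbatim as two allele codes per locus with a
single internal missing marker; a call is missing all-or-nothing within a
locus. Individuals are retained when genotyped at ≥ 85% of loci (the
filter is applied before locus screening; the order is a convention, since
per-locus missingness is approximately independent of the flagged loci).
Locus screening removes flagged (species-diagnostic, mitochondrial) loci
and loci invariant over the union of retained baseline and mixture
individuals — assessing invariance after individual filtering avoids
zero-frequency alleles downstream. Computation uses an alternate-allele
dosage encoding (0/1/2, −1 missing) with a per-locus allele ordering
shared between baseline and mixture.

## Pairwise relatedness and sibling pruning

Relatedness is estimated from the three observable genotype-similarity
categories at a locus (identical genotypes; one homozygote and one
heterozygote sharing an allele; no allele shared — the "both heterozygous,
one shared allele" category requires three alleles and is impossible for
biallelic SNPs). Writing a_m for the m-th power sums of the reference
allele frequencies, the category probabilities are linear in the pair's
IBD coefficients φ (one gene pair IBD) and Δ (both pairs IBD):

    E[P1] = b + cφ + (1−b)Δ,   E[P2] = d + eφ − dΔ

with b = 2a₂² − a₄, c = a₂ − b, d = 4(a₃ − a₄), e = 2(a₂ − 3a₃ + 2a₄).
For SNP panels this 2×2 system is solved exactly, pooling loci with
information weights w_l ∝ 1/u_l, u_l = 2a₂ − a₃; r = φ/2 + Δ. Loci with
missing calls or monomorphic reference frequencies are skipped and
excluded from `n_loci_used`. Pedigree simulations at 266 loci put
unrelated pairs at r ≈ 0 (±0.02) and full sibs at r ≈ 0.5 (±0.03), with
> 90% of sib pairs above the 0.4 classification threshold and < 2% of
unrelated pairs falsely joined. Reference frequencies come from the pair's
own collection (the screening context); no small-sample bias correction is
applied. Families are connected components of the r > 0.4 graph; the two
members with the highest call rate are retained (ties broken by id).

## Baseline differentiation and aggregation

Weir–Cockerham θ uses per-locus variance components a (among populations),
b (among individuals within populations) and c (within individuals),
summed over loci before the ratio; invariant loci contribute zero
components rather than NaNs, and loci with an uncalled group are masked.
Pairwise θ re-derives the components on each pair.

Self-assignment is leave-one-out: an individual's two gene copies per
locus are subtracted from its group's counts before its Hardy–Weinberg
genotype likelihood is evaluated; frequencies are Dirichlet-posterior
means with a 1/(number of alleles) prior per allele (0.5 for SNPs), and
posteriors use a uniform prior over groups. Aggregation iteratively merges
the lowest-θ qualifying pair, where a pair qualifies when one member's
self-assignment rate is below 0.7 with its largest misassignment flowing
to the other, pairwise θ < 0.01 (strict), and both collections lie on the
same stream; confusion and θ are recomputed after each merge, so the
procedure terminates (each merge reduces the group count by one).
"Confusion is high" needed operationalizing — the rate-below-0.7 +
largest-off-diagonal-partner rule is the package's reading. After
aggregation, units that are still single collections with n ≤ 5 are
excluded and reported.

The accuracy assessment draws true mixing proportions from Dirichlet(1),
gene-drops mixtures (each simulated fish's two alleles per locus sampled
*without replacement* from its unit's observed allele pool and removed
from that unit's counts when its own likelihood is scored), re-estimates
proportions, and summarizes per-unit residuals (mean, SD, zero-overlap).

## Conditional GSI

Mixture decomposition is conditional: unit allele frequencies stay fixed
at their posterior means while a Gibbs sampler alternates latent origins
z_i ~ Categorical(π_u L_iu / Σ) and π ~ Dirichlet(1/U + counts); the
symmetric 1/U prior is scale-free in the number of units. Individual
posteriors are Rao-Blackwellized responsibilities averaged over sweeps.
Defaults (2000 sweeps, 500 burn-in) are desk-scale and configurable; an
independently coded EM fixed point agrees with the Gibbs mean within
±0.02 on well-separated data.

Bootstrap bias correction re-simulates B mixtures of the stratum's size by
gene-dropping with truth = the fitted π, re-estimates, and subtracts the
mean bias (clipping at zero and renormalizing). The correction only
visibly beats the raw estimate per replicate when raw bias dominates
bootstrap noise — with well-separated units the raw estimator is already
nearly unbiased and correction is a no-op; the regime where it matters is
strong unit overlap with skewed truth at small mixture sizes.

z-scores standardize each fish's log-likelihood under its assigned unit by
the exact per-locus mean and variance of the log genotype probability
under Hardy–Weinberg at that unit's frequencies, summed over the fish's
called loci. Fish beyond ±2 empirical SD of the mixture's z distribution
are flagged as potentially from unsampled sources. Because the rule is
empirical, contamination inflates the pooled SD and the *absolute* flag
rate stays near 5–10%; the informative signal is the excess among
truly-unsampled fish. Exact zeros for the regression stage: a unit's
contribution is recorded as 0 when no fish has it as maximum-posterior
assignment and its corrected proportion is below 1/(2·stratum size) —
posterior output never produces literal zeros, so a convention is
required.

Dispersal distance is the flow-line (tree-path) distance between the
section midpoint of capture and the origin unit's network point, over fish
assigned to a single unit above a posterior threshold (default 0.7).

## Zero-inflated Dirichlet composition models

Each section-year composition y (over units, exact zeros allowed) is
modelled with per-component independent structural zeros (probability ψ)
and a Dirichlet on the renormalized survivors with mean ∝ exp(Xβ_c)
(component 0 as reference) and total concentration τ. A stratum with all
mass on one component is the all-others-zero case; one-inflation never
arises as a distinct phenomenon and carries no parameter. Priors:
normal(0, 5) on β, flat on ψ (logit parameterization with Jacobian),
log τ ~ normal(log 10, 2) — a proper stand-in where literal flatness would
be improper. Five designs encode the spatiotemporal hypotheses
(treatment coding, reference = first section/year; the
"sections-differ-in-temporal-variation" hypothesis is the section × year
interaction). Model comparison is exact leave-one-out: each observation is
held out, the model refit (warm-started from the full-data posterior
mean), and its log predictive density scored as the posterior mean
likelihood; elpd differences use pointwise SEs. With ≤ ~18 strata this is
cheap and avoids importance-sampling diagnostics. At desk scale,
independent zero patterns across years act as genuine temporal signal, so
the model-selection consistency experiments keep ψ small (0.05) for the
section-only truth to be identifiable.

When the composition table has many minor units (e.g. 52), the pipeline
can pool all but the top-k contributors into an "other" component before
model comparison (compositional lumping) to keep exact-refit LOO
tractable; k is a config choice recorded in the run report.

## Hierarchical zero-inflated beta contribution model

The two-part likelihood places probability ω_rsy on an exact zero and
(1−ω) Beta(μφ, (1−μ)φ) on p ∈ (0, 1); p = 1 is squeezed to 1 − 10⁻⁶ with a
warning (the model has no one-inflation). Predictors follow the chain: μ
gets hierarchical section and unit intercepts and a section-varying
groundwater slope; ω and φ are fixed-effect-only; there is no year
intercept. Continuous covariates (distance km, area km², groundwater
index) are z-scored over the dataset; coefficients are also reported per
natural unit. Catchment area enters on the raw scale before z-scoring.
Priors: normal(0, 5) on intercepts and slopes, half-normal(0, 2) on the
random-effect SDs (proper weakly-informative stand-ins for
"uninformative"), non-centered parameterization for both intercept sets.

Sampling is Hamiltonian Monte Carlo with hand-derived gradients (digamma
terms for the Beta; chain rule through the logit/log links), dual-averaging
step-size adaptation (target acceptance 0.8), a diagonal mass matrix
estimated in a warmup window, and uniformly jittered trajectory lengths.
Gradients are verified against finite differences in the tests. Split-R̂
and ESS come from arviz; R̂ ≥ 1.01 warns but the fit is returned. At the
study design (936 observations, ~86 parameters) two chains of 700 warmup +
600 draws take seconds and give 95% intervals that cover every generating
fixed effect in ≥ 90% of 20 replicates.

Posterior predictive checks replicate datasets from the joint posterior
(including the fitted random intercepts) and score zero-proportion,
mean-of-nonzero and maximum statistics per section and overall as Bayesian
p-values. One calibration caveat: when the *generating* random-effect
variance is zero, the posterior's nonzero variance estimate legitimately
over-disperses the extreme-value statistic. Effect curves sweep one
covariate over its observed range with the others at their means (0 after
standardization) and random intercepts at zero, per connectivity level and
per section for groundwater.

## Spatial diagnostics

Watercourse distances are tree-path sums on the stream network; Euclidean
distances use planar node coordinates. The empirical semivariogram
γ(h) = Σ(v_i − v_j)²/(2N_h) uses 20 equal-width bins over (0, max]
(equal-count binning available), flags bins with < 21 pairs as
low-support, and attaches a lowess display smooth with span 0.7. The
inflection diagnostic — the distance where the smoothed slope first drops
below half its initial value — recomputes a *lighter* smooth (span 0.35),
because the wide display smooth flattens exactly the short-range sill it
looks for; a pure gradient returns no inflection. Structure is reported
through these summaries rather than a hard broadscale/fine-scale label.
The latitude trend is OLS of unit intercepts on a latitude proxy (planar
northing in the synthetic system) with a 95% CI; region summaries order by
centroid latitude.

## The synthetic riverscape

The generator is the package's study system. Its defaults are the real
design: 52 tributary source populations, 266 SNP loci, global F_ST 0.04,
six 20-km main-stem sections sampled for three years at 500 adults/year,
connectivity counts 39 connected / 3 culvert-or-diversion / 7 low-flow /
3 waterfall, 11 populations sampled as two same-stream collections
(within-pair drift F ≈ 0.003, i.e. pairwise θ ≈ 0.006), six tiny
collections (n ≤ 5) from populations otherwise absent, 15% of baseline
fish in full-sib families (family size 3–5), 2% missing genotype calls,
and 5% of mixture fish drawn from unsampled "ghost" populations.
Population allele frequencies follow the standard F-model: ancestral
p_l ~ Uniform(0.05, 0.95), population frequencies Beta-distributed with
mean p_l and variance θ p_l(1−p_l), clipped 10⁻⁴ from fixation — the
natural simulator when a single global F_ST is the calibration target.
Genotypes are Hardy–Weinberg draws; sib families come from two simulated
parents by Mendelian segregation.

The network is a one-level dendritic tree: a meandering north–south main
stem with one tributary per population attached at a uniform position,
the sampling point 1–8 km up the tributary (emulating
furthest-downstream sampling locations). Catchment areas are lognormal
(median 30 km², σ = 0.8); the groundwater index combines a northward
gradient, regional offsets and noise, clipped to (0, 1). True
contributions come from the zero-inflated beta forward model on the (r, s)
covariate table, with two deliberately *unmodelled* spatial effects added
to the unit-level logit: a south-high latitudinal gradient (−0.5 per SD of
latitude) and regional patches (SD 0.4 over 8 north–south regions) — these
surface downstream as spatially structured random intercepts, giving the
semivariogram and latitude analyses known signal. Nonzero draws are
renormalized within section to a simplex; contributions are held constant
across years by default (the year-constant truth matches the selected
composition model; an iid-per-year mode exists for regression
experiments). Default generating coefficients: distance −0.8, area +0.5,
groundwater +0.3 (common across sections), connectivity offsets 0 /
−1.0 / −0.8 / −1.6 on logit μ; zero model intercept −1.0 with distance
+0.8 and area −0.5; log-precision intercept 3.2 with small covariate
effects.

What the generator does *not* emulate: genotyping error and allelic
dropout; linkage between loci; age/length structure (length classes are
metadata only in the real sampling); temporal variation in contributions;
hybrids (assumed pre-removed, an exclusion list is accepted);
within-tributary spatial sampling structure beyond the two-collection
splits; and the decoupling of watercourse from Euclidean distance that
deep sub-basin branching produces in real riverscapes (all tributaries
hang directly off the main stem, so the two metrics are strongly
correlated here). Passing tests therefore certify the estimators and the
inference chain under clean population-genetic assumptions, not
robustness to genotyping artifacts or real network geometry. A further
consequence of the unmodelled latitude gradient: at pipeline scale the
groundwater slope estimate is partially confounded with latitude (the
groundwater field is itself latitudinal), so its pipeline-level posterior
can shrink toward zero even though direct recovery experiments (no
spatial confounder) show nominal coverage.

## Problem sizes and numerics

Test and acceptance runs scale the samplers, not the designs: GSI Gibbs
1500–2000 sweeps; bootstrap 30–100 replicates; ZIB 2 chains × 700 + 600;
Dirichlet LOO 1 chain × 150 + 130 per refit with warm starts; the bias
assessment 100 simulations × 500 fish (scaled from 500 × 1000). Degenerate
inputs are handled explicitly: singleton groups fall back to prior-mean
frequencies (with a warning), loci with < 2 observed gene copies
gene-drop from a 50:50 pool, all-zero simulated sections are resampled,
z-scores are undefined (NaN, warned) when every assigned locus is fixed,
and non-finite HMC proposals are rejected rather than propagated.
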