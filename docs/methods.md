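# Methods

This note documents the statistical procedures, the simulator's generative
model, and the design decisions behind them. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

One row per individual: id, sex, tactic (`female` / `hooknose` / `jack`),
return year, fork length at maturity (mm), reproductive success (count of
offspring that survived to maturity), dam/sire links, and generation
(`parent` / `offspring`). Invariants enforced at I/O time: tactic is
`female` iff sex is female; lengths positive; rs a nonnegative integer;
parent links resolve to an individual of the right sex; nobody is their own
ancestor; parent-generation years strictly precede offspring-generation
years (overlapping generations are out of scope). Missing parent links
accept common NA tokens and normalize to a single missing sentinel.
Inclusion criteria (length and rs present; wild origin of self and both
parents when an origin table is supplied) run as an explicit pass that
returns per-step row counts rather than dropping rows silently.

Male tactic is taken from the input column when present — upstream
classifications are retained. Only when the column is absent is the length
threshold applied: jack iff length < 500 mm (strictly below; 500 itself is
hooknose), reflecting the bimodal male length distribution in the study
system. The threshold is configurable.

## Selection analysis

Within every analysed subset (pooled, per year, per tactic, per
year × tactic) length is standardized with the subset's own mean and
*sample* SD (n−1 denominator, the convention of selection-gradient
practice and of OLS standard errors), and relative fitness is rs divided
by the subset mean rs. Pooled analyses always standardize on the pooled
subset, never on averages of per-subset statistics. Individuals with
rs = 0 are included throughout.

β ± SE comes from the linear-only OLS of *w* on StdLength; γ ± SE from the
quadratic model (retaining the linear term) with both the coefficient and
its SE doubled. The doubled SE is reported exactly as estimated; the
variance caveat attached to doubling conventions in the literature is
acknowledged but not applied. Because the linear-only β and the joint
quadratic β differ in finite samples, both are exposed (the gradient table
reports the linear-only β, the quadratic fit carries its own joint β).

Significance uses Poisson log-link GLMs of *absolute* rs with
likelihood-ratio (analysis-of-deviance) χ² tests of nested models, never
Wald tests. The χ² columns of the gradient table test StdLength
(`rs ~ x` vs intercept) and StdLength² (`rs ~ x + x²` vs `rs ~ x`).
Deviance tests are invariant to the treatment-coding reference level of
categorical tactic/year (asserted in the tests). The interaction scan
follows a fixed backward sequence: both three-way interactions tested
against the full model; the quadratic three-way dropped; the linear
three-way retested; both dropped; each two-way involving length tested by
single-term deletion. Subsets too small or degenerate for estimation
become NA rows that carry the reason, mirroring how sparse year × tactic
cells are reported in field studies.

Convergence: IRLS capped at 100 iterations, relative tolerance 1e-8;
non-convergence sets a flag on the returned fit, and non-finite parameter
estimates (separation) raise.

## Heritability analysis

Variance screening uses Bartlett's K² across the three tactics plus
two-sided variance-ratio F tests per pair (F = ratio of sample variances,
df = n−1 each).

Each of the nine grid cells regresses the **mean** length of a parent's
offspring of the target tactic on the parent's own length — one unweighted
point per parent regardless of family size. The per-parent-mean choice
follows the published error degrees of freedom, which match one point per
parent rather than one per offspring. Each offspring contributes to both
its dam-cell and its sire-cell regressions.

h² = 2·b<sub>op</sub>, with Falconer's σ<sub>p</sub>/σ<sub>o</sub>
rescaling applied to an intertactical cell iff the pairwise F test between
the two groups rejects at α (default 0.05, configurable). σ<sub>p</sub> is
the sample SD over parent-generation individuals of the parent tactic and
σ<sub>o</sub> over offspring-generation individuals of the offspring
tactic; the trigger F test compares those same two groups. Which
generation's SDs enter the ratio is a documented choice — the source
analyses do not pin it down — and the generation-split version is the one
coherent with regressing offspring on parents. Diagonal (intratactical)
cells are never corrected: the published analysis corrects only
intertactical pairs, and its within-tactic cells test against the plain
0.5 null.

The 95% CI half-width is 1.96·2·se·corr (normal multiplier; the published
CIs reproduce as 3.92·se·corr, not with a t quantile). Two tests per cell:
t = b/se with n−2 df against slope 0 (h² = 0), and
F = ((b − b₀)/se)² with (1, n−2) df against the h² = 1 null slope
b₀ = 0.5/corr. The algebra h² = 2·b·corr, ci = 3.92·se·corr,
b₀ = 0.5/corr holds exactly and is property-tested.

The offspring interaction model (offspring length ~ dam length + sire
length + offspring tactic + dam×tactic + sire×tactic) is fit per offspring
with both parents known, with sequential (type-I) F tests computed by
incremental nested fits so the table follows the equation's own term order
(the formula machinery would otherwise reorder categorical terms). The
published F degrees of freedom are only consistent with per-offspring
rows, so the model is fit that way despite the "mean offspring length"
phrasing in its source description. Maternal and common-environment
effects are deliberately not modelled.

Animal models / REML / MCMC G-matrix estimation are out of scope: at this
pedigree's size and density they are not informative, which is precisely
why the parent–offspring machinery exists.

## Simulator

Breeding values are a standardized 4-vector per individual: female-,
hooknose- and jack-expressed length plus a liability component, drawn for
founders from N(0, R) where the 3×3 length block is **r**<sub>G</sub>
(unit diagonal, PSD; a symmetric eigen square root handles singular
matrices) and the liability is by default uncorrelated with the length
expressions. The liability is its own additive component rather than a
reuse of one of the length expressions: sharing a component would
truncation-select length breeding values within tactics and break the
closed-form expectations the simulator exists to provide.

Phenotype in tactic *t* is μ<sub>t</sub> + √h²<sub>t</sub>·σ<sub>t</sub>·a<sub>t</sub> + e
with environmental variance (1−h²<sub>t</sub>)·σ²<sub>t</sub>. Males are
jacks iff √h²<sub>L</sub>·a<sub>L</sub> + √(1−h²<sub>L</sub>)·ε exceeds
the standard-normal quantile implied by the target jack fraction
(liability h² defaults to 0.9, the reported heritability of the salmonid
maturation threshold). Offspring receive the mid-parent vector plus an
independent Mendelian deviate with covariance R/2, conserving
breeding-value variance. rs is Poisson with
log E[rs] = b0<sub>t</sub> + b1<sub>t</sub>·x + b2<sub>t</sub>·x², x the
within-tactic standardized length; dams and sires are sampled
independently with probability ∝ rs, and parents' emitted rs is the
*realized* offspring count (the study's fitness metric is "offspring that
returned", which conflates parent reproduction and offspring survival —
the simulator reproduces that property on purpose).

Default parameters are the study conditions: 301 dams, 322 sires, 18%
jacks, 775 offspring; length means 733/735/423 mm; phenotypic SDs
48/74.5/44.8 mm, derived from the printed female SE (1.84·√681 ≈ 48) and
the printed variance ratios (female:hooknose 0.415, hooknose:jack 2.77;
the implied female:jack ratio 1.15 matches the printed value); per-tactic
h² at the published point estimates 0.36/0.87/0.47; fitness intercepts
log(2.61)/log(2.80)/log(1.21) from the per-tactic mean rs, linear terms
0.142/0.239/0.098 from the pooled-years gradients, and half the printed γ
as weak curvature. r<sub>G</sub> defaults to the identity (the study found
no intertactical heritability).

Under this model the expected single parent–offspring slope is h²/2 within
a tactic and the corrected intertactical h² equals
r<sub>G</sub>(o,p)·h<sub>o</sub>·h<sub>p</sub> — the central end-to-end
recovery property, checked in the acceptance tests.

What the simulator does *not* emulate: the hard 500-mm split between jack
and hooknose lengths (liability-threshold tactics give slightly
overlapping length tails, unlike threshold-classified field data);
year-varying selection; overlapping generations; maternal effects;
hatchery/wild origin structure; non-Poisson overdispersion of rs beyond
what the mixture over lengths induces. Passing tests therefore demonstrate
correctness of the estimators under an additive tactic-structured
architecture, not robustness to those field complications.

Randomness: one `numpy.random.Generator` (PCG64) seeded from the config,
threaded founders → founder fitness → mating/segregation → offspring
fitness in a fixed call order; liability noise is drawn for every
offspring (not just males) so the stream layout is independent of the
realized sex ratio. Same config + seed is byte-identical.

## Problem sizes and numerical choices

Calibration runs use 1000 dams × 1000 sires (one third jacks) with 8000
offspring — roughly one regression point per dam in the dense cells — over
100 seeds; size/power calibrations of the deviance and slope tests use
1000 Monte-Carlo replicates (n = 100 per subset under the null, 1000 per
tactic for power). These sizes give Monte-Carlo standard errors a few
times smaller than the tolerances they are checked against.

OLS paths are asserted against explicit-sum/normal-equations oracles at
1e-10 and likelihood fits against direct numerical maximization at 1e-6
(1e-4 for the negative binomial, whose oracle is a derivative-free
optimizer). Degenerate inputs (constant lengths, all-zero rs, single
factor levels, < 3 families in a cell, zero-variance groups) raise typed
errors or become NA rows with reasons rather than propagating NaNs.
Pedigree CSVs are written with `%.17g` so write → read round-trips floats
exactly.

## Known limitations

- Selection-gradient SEs ignore the count nature of fitness (classical OLS
  theory, as in the source analyses); the GLM χ² columns are the
  inferential statements.
- The grid's cells are not independent (each offspring appears in a dam
  and a sire cell; each parent in up to three cells); no joint inference
  across cells is attempted.
- The variance-correction trigger is a per-cell frequentist screen at a
  configurable α; near the threshold the corrected/uncorrected decision is
  discontinuous, which is inherent to the published procedure.
- With heritable liability, a sire's tactic and his sons' tactics are
  correlated, so cell family counts (not estimates) depend on the liability
  h²; cells involving jacks are the sparsest, as in the field data.
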