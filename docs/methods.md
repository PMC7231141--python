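# Methods

## Pipeline model

The discovery funnel treats a multi-ancestry cohort with genotypes
G ∈ {0,1,2}ⁿˣᵖ (additive alt-allele dosage, missing coded separately),
a sample→population panel, gene expression Y (log-intensity), and gene
coordinates (1-based inclusive).

**Variant QC.** A variant is excluded when imputation r² < `r2_min`
(default 0.25; variants without an r² are treated as directly genotyped
and pass), MAF < `maf_min` (default 0.10), or HWE p < `hwe_p_min`
(default 10⁻⁴). All three are strict-inequality exclusions, so boundary
values pass. HWE uses the 1-df Pearson χ² against expected counts
(np̂², 2np̂q̂, nq̂²); a conditional exact test is available and is
recommended (a logged warning fires) when any expected genotype count
is below 5, where the asymptotic test is anticonservative. Frequencies
are pooled over the analysis samples. HWE testing offers two scopes:
pooled, and per-population (fail if any population deviates; the
reported statistic is the worst population's). The *pipeline* default
is per-population: pooling structured ancestries induces a Wahlund
heterozygote deficit proportional to the between-population frequency
variance, so a pooled HWE screen preferentially removes exactly the
strongly differentiated variants that step 2 is designed to find.
`qc_filter` called directly defaults to pooled, matching the simplest
single-cohort reading.

**Differentiation.** Per variant, a 2×K table of ref/alt allele counts
per population; Pearson χ² of independence with df = K−1 (allele
counts, not 3×K genotype counts — the quantity of interest is the
alt-allele frequency). No continuity correction (counts here are
hundreds). A variant is *selected* when p < 0.001 (strict) and the
target population's alt frequency is the strict maximum or minimum
across populations. "Preferential prevalence" has no canonical
numerical definition; the strict extremum is the weakest directional
reading and is applied symmetrically to both alleles.

**cis association.** SNP–gene distance is 0 inside the gene body, else
the distance to the nearer gene boundary; a pair is cis when distance ≤
window (inclusive). The shipped default window is 1 Mb: the package's
own reference pair table contains associations at 640–725 kb, which a
500 kb window would exclude; 500 kb remains available as a parameter.
Each pair is fit by OLS with intercept on pairwise-complete
observations (≥ 3 required, non-constant dosage and expression;
anything else is flagged untestable and excluded from the FDR set
rather than entered as p = 1). BH adjustment is applied once, globally,
across all pairs of a run — the conservative and simplest convention —
with rejection iff q ≤ α (default 0.05). No covariates and no dominance
term: the model is deliberately the plain additive regression.

## Synthetic cohort generator

`simulate_genotypes` implements the Balding–Nichols model: ancestral
frequency p ~ U(0.2, 0.8) per SNP; each population draws its frequency
from Beta with mean p and variance F·p(1−p); individuals are
Binomial(2) draws, so within-population HWE holds by construction.
Defaults — 3 populations (CEU/CHB/JPT labels) × 200 samples, 935 SNPs,
background F = 0.01, 4 differentiated SNPs at F = 0.25 — reproduce the
shape of a HapMap-style three-panel analysis with a small
ancestry-enriched minority. The ancestral range (0.2, 0.8) reflects the
common variants that survive a MAF ≥ 0.1 screen.

Differentiated SNPs are *directionally* enriched: only the target
population drifts at `fst_differentiated`, and its draw is conditioned
on |f_target − p| ≥ `min_target_divergence` (default 0.2, rejection
sampling). This emulates ascertainment: enriched loci in a real study
are, by definition, the ones observed to diverge in the target
ancestry. An unconditioned symmetric draw leaves the target population
at the frequency extremum only 2/3 of the time and frequently produces
negligible divergence, which would make "planted" truth unrecoverable
by any method — the conditioning defines the study condition rather
than tuning it.

Imputation r² is U(0.25, 1) with a configurable fraction
(`low_r2_fraction`, default 0.05) drawn from U(0.20, 0.25), so the r²
filter has work to do. Expression is Σ β·dosage over planted effects
plus N(0, σ²) noise (σ default 1; planted β default 1 — chosen for test
power, as no effect sizes are published for the motivating loci).
Survival times are exponential with hazard h₀·exp(γ·x) (defaults
h₀ = 0.02 events/month, γ = 0.5 per expression unit) with independent
exponential censoring (0.015/month, ≈ 40% censoring at these scales).
All generators are pure functions of (config, seed); substreams for
genotypes/expression/survival are derived from the seed.

What the generator does **not** emulate: linkage disequilibrium between
SNPs (each SNP drifts independently — so "fine-mapping" behavior is not
testable), admixed individuals, probe-level microarray noise, batch
effects, and genotyping error. Passing tests therefore demonstrate the
statistical machinery under ideal sampling, not robustness to
real-data artifacts. One consequence of structure without LD: because
all target-enriched SNPs correlate with population membership, they
correlate with each other, and a drifted SNP near a gene whose true
eQTL is elsewhere can show a genuine (confounded) association — visible
in the worked example and a faithful reproduction of why plain
regression on structured cohorts is anticonservative.

A corollary of background F = 0.01 at 200 samples/population: the
expected allele-count χ² for a background SNP is ≈ (K−1)(1+2NF) ≈ 10,
so a substantial minority of background SNPs genuinely clears p < 0.001
(the funnel reports ~150 differential SNPs, not 4). Funnel validation
therefore asserts recovery of the planted SNPs and significance of
their cis pairs, not the absence of other selections.

## Downstream statistics

Quantile normalization maps each sample's values onto the mean order
statistics across samples, averaging reference values over within-
sample ties; afterwards all columns share one sorted multiset. Wilcoxon
rank-sum uses exact enumeration for ≤ 20 untied observations, else the
tie-corrected normal approximation with continuity correction. Median
dichotomization sends ties at the median to "low" (deterministic group
sizes; the tie direction is a convention). Kaplan–Meier is the product-
limit estimator over distinct event times; the median is the earliest
time with S ≤ 0.5, else "not reached". The log-rank test sums observed
minus expected events with hypergeometric variance. The Cox fit
maximizes the Breslow partial likelihood by Newton–Raphson with
step-halving; convergence at max|score| < 10⁻⁸ within 50 iterations,
standard errors from the inverse observed information; no events,
collinear covariates, or divergence (perfect separation) are surfaced,
never silently returned. Breslow tie handling is the simplest
consistent choice; with continuous times it coincides with Efron.

## Validation design and problem sizes

Fixed-seed simulations back every stochastic claim: 10,000 null
regressions at n = 100 for calibration and KS uniformity; 200
replicates × 1,000 tests (10% non-null, β = 0.8) for empirical FDR of
the BH step; 500 replicates for OLS effect recovery; 5,000 SNPs at
F = 0.1 for the variance-based F_ST estimator (which uses the K−1
sample-variance denominator — the 1/K version is biased low by the
factor (1−1/K)); 100 replicate cohorts for planted-funnel recovery. The
regression p-value is cross-checked against a 10⁵-draw permutation null
at n = 50, where the permutation and t reference distributions agree
within Monte-Carlo resolution (at n ≈ 10 they differ systematically by
up to a few percent — the permutation null conditions on the realized
dosages — so tiny-n agreement beyond that is not a meaningful target).
The Cox fit is cross-checked against an independent survival
implementation to 10⁻⁴ on tie-free data. `scripts/acceptance.py` reruns
these analyses at moderately reduced replicate counts chosen to keep a
single-CPU run in a few minutes.

## Known limitations

- No LD, no admixture, no relatedness: sample exchangeability within
  populations is assumed everywhere.
- The regression stage fits no population covariates; on structured
  cohorts it inherits the confounding discussed above by design.
- Batch-effect correction is out of scope; the normalization stage is
  quantile normalization only.
- PFS/OS interval construction from calendar dates is out of scope; the
  survival API consumes already-coded (time, event) records.
- The exact HWE test is conditional (given allele counts); its p-values
  are discrete and conservative at small n.
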