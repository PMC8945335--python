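# Methods

This note documents the models behind `issrpop`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical conventions that matter when interpreting output.

## Data model

The universal input is a complete individuals × loci 0/1 band matrix with
one population label per individual. A missing-data sentinel (−9) is
reserved in the container, but every statistics module rejects matrices
containing it: the dominant-marker estimators below assume complete data,
and silent imputation would bias the band-absence fractions they all
start from. The GenAlEx dialect implements only the minimal binary layout
(numeric header, population names, one row per individual) needed for a
lossless round trip; the STRUCTURE dialect writes one row per individual
with integer-recoded populations plus comment lines preserving the
population names, so all three dialects round-trip bit-exactly.

Geographic coordinates are planar kilometres. Lon/lat input is projected
equirectangularly at the populations' mean latitude; over the few-km
extents this package targets, the distortion is negligible, and only
relative distances enter the analysis (the Mantel test uses log
distances).

## Allele frequencies and diversity

For a dominant biallelic locus under Hardy–Weinberg, the band-absent
phenotype is the recessive homozygote, so its sample fraction `x`
estimates `q²`. The naive `√x` is biased at survey-scale n; the
Lynch–Milligan Taylor-expansion estimator

    q̂ = √x · [1 − Var(x̂)/(8x²)]⁻¹,  Var(x̂) = x(1−x)/n

is used throughout, with two guards: `x = 0` short-circuits to `q̂ = 0`
(no division by zero), and the result is clamped to [0, 1] (the
correction factor can misbehave when `x` is tiny relative to 1/n; the
clamp keeps such loci usable instead of propagating nonsense). The
estimator needs n ≥ 2 per population and the simulation check in the test
suite shows bias < 0.02 at n = 500.

He = 2pq and Shannon I = −(p ln p + q ln q) are means over loci of the
estimated allele frequencies; He for a biallelic locus is bounded by 0.5.
Because dominant-data programs disagree on whether Shannon information
should use allele or phenotype frequencies, a `on_band_freqs` flag
switches to raw band frequencies; the default uses allele frequencies so
He and I share one frequency estimate. %P applies the 95% criterion to
the *phenotypic* band frequency (a locus is polymorphic when its
commonest band state is at frequency ≤ 0.95), which is what band-based
software reports.

Allele counts interpret "alleles" the way band-based packages do: per
locus a population shows 1 state (monomorphic) or 2 (polymorphic), summed
over loci (Na); a private allele is a band present in exactly one
population; Ne is the mean of 1/(p² + q²). With ~60 loci and ~56%
polymorphism this yields Na near 90–100, the familiar scale for ISSR
surveys of this size.

The exact differentiation test builds a populations × {band, no band}
table per locus: two populations use Fisher's exact test (full
hypergeometric enumeration); more use a Monte-Carlo exact test — ≥ 10,000
tables sampled with fixed margins (Patefield's algorithm via
`scipy.stats.random_table`), p = (1 + #{P(T) ≤ P(obs)})/(1 + B). Loci
monomorphic overall have a single attainable table and p = 1. Per-locus
p-values combine across loci by Fisher's method.

## Differentiation and gene flow

Nei's partition uses Hs = mean over populations of 2pq and
Ht = 2p̄(1−p̄) at the mean frequency, per locus; Gst sums components over
loci (excluding loci with Ht = 0, where the ratio is undefined). Gst is
computed on Lynch–Milligan frequencies so it shares the same estimate as
He; raw band frequencies are available by passing frequencies built from
them.

AMOVA uses squared Euclidean distances between band vectors (identical
to Hamming counts on 0/1 data), the standard sums-of-squares partition
from the distance matrix, and the one-level variance-component estimator
with coefficient n₀ (the weighted average sample size). Φst =
σ²a/(σ²a+σ²w). Significance permutes individuals among populations with
population sizes fixed (the convention of band-matrix software), with an
add-one p-value so p is never 0. Populations of one individual are
rejected (the within-group df would collapse). The test suite verifies
the components against an independent centroid-deviation computation and
checks that null p-values are approximately uniform.

Crow–Aoki gene flow applies Nm = ((1/Gst) − 1)/(4α) with
α = (n/(n−1))², the island-model estimate corrected for a finite number
of demes; Gst = 0 is rejected (unbounded flow). Note this formula is
steep: Gst near 0.4–0.5 maps to Nm near 0.2–0.3, well below one migrant
per generation.

Pairwise Φst runs a two-population AMOVA per pair (negative estimates
floored at 0), and the Slatkin linearization Fst/(1−Fst) feeds the
Mantel test; Fst = 1 produces an infinite linearized value with a
warning. The Mantel statistic is the Pearson correlation over
upper-triangle pairs of log₁₀ distance vs linearized Fst; the null
permutes population labels of the genetic matrix (rows and columns
jointly), one-sided toward positive isolation by distance, the standard
alternative for IBD. Spearman's ρ and a pair-bootstrap 95% interval are
reported alongside. At least 4 populations are required for the
permutation null to mean anything (4! = 24 distinct relabelings).

## Structure inference

The minimum spanning network is a Kruskal MST under a deterministic
(weight, label) edge order, after which every non-tree edge whose weight
equals the bottleneck (maximum edge weight) on the tree path between its
endpoints is restored — the usual tie-retention convention, so a set of
equidistant genotypes appears as a cycle rather than an arbitrary tree.

PCA is covariance-based (columns centred, not scaled — band variables
share a scale) with a sign convention (largest-magnitude loading
positive) for reproducibility. DAPC discovers groups with seeded k-means
(25 restarts) over k = 1..min(10, n−1), choosing k by
BIC = n ln(WSS/n) + k ln n. Group discovery runs in the full PC space
— with few retained dimensions this BIC under-penalizes extra clusters,
and the reference DAPC practice likewise reserves dimension reduction
for the discriminant step — while the discriminant analysis uses the
smallest PC count explaining ≥ 80% variance, yielding ≤ k−1 discriminant
functions.

The admixture model works directly on band phenotypes: cluster-by-locus
band frequencies θ_kl ~ Beta(1,1), per-individual admixture
q_i ~ Dirichlet(1,…,1), allocations z_il ~ Categorical(q_i), and
band_il ~ Bernoulli(θ_{z_il,l}). This is a deliberate simplification of
genotype-based admixture samplers (which model the recessive allele
explicitly): it has the same mixture geometry, is far cheaper, and
recovers cluster membership reliably at the data scales this package
targets, but its θ estimates are band frequencies, not allele
frequencies. A Gibbs sampler (numba-compiled) alternates the full
conditionals; L(K) is the posterior mean of the z-marginalized data
log-likelihood over thinned post-burn-in draws, and Q is the posterior
mean admixture after resolving label switching by optimal assignment of
θ vectors against the first retained draw. Default chains are 2,000
burn-in / 5,000 sampling iterations (thinning 10) — deliberately short;
convergence at this scale is fast because the posterior is sharply
multimodal only across label permutations, which the alignment step
handles. Longer chains are a parameter away.

Evanno's ΔK = |L″(K)|/sd(L(K)) over replicate runs grouped by K needs at
least 3 consecutive K values with ≥ 2 replicates; ΔK exists only for
interior K, and sd = 0 yields an infinite sentinel with a warning. On the
default synthetic design (below), ΔK selects K = 2 in ≥ 80% of seeded
pipeline repetitions with the short default chains.

## Synthetic data

The generator emulates a six-site survey of a cliff-dwelling succulent:
20 individuals per population (120 total), ~60 biallelic dominant loci
from a dozen primer sets, two ancestral clusters (4 + 2 populations),
strong among-population differentiation, five private bands concentrated
in one-to-two populations (4 + 1), and sites ~6 km apart on average.

Population allele frequencies follow a hierarchical Balding–Nichols
model: one ancestral frequency per locus p0 ~ U(0.05, 0.95); cluster
frequencies Beta-distributed around p0 with parameter f_c; population
frequencies Beta-distributed around their cluster with f_p. The two
levels compose as F_tot = f_c + f_p(1−f_c), and `cluster_share` (default
0.5) sets the fraction of F_tot carried by the cluster level, so the
design's `fst_target` is the *total* among-population differentiation.
This matters: drawing cluster frequencies independently would add an
uncontrolled layer of divergence and the realized Φst would overshoot
the knob by ~0.15, breaking the generator's contract that estimators
recover its truth (the test suite checks median Φst over 20 replicates
within ±0.05 of the target). Frequencies are clipped to [0.01, 0.99] so
base loci stay informative; private loci are injected afterwards as
bands at frequency ~0.3 in exactly one population (at least one carrier
forced) and structurally zero elsewhere.

Genotypes are two Bernoulli(p) draws per individual/locus; the band
shows iff at least one dominant allele is present, so the expected band
frequency is 1 − (1−p)². An optional `clone_rate` duplicates genotypes
within populations to emulate clonal recruitment; the default is 0
because the emulated field protocol spaces samples to exclude clones.

What the generator does **not** emulate: linkage between loci, mutation,
scoring error and band homoplasy (co-migrating non-homologous
fragments), uneven sample sizes, and missing data. Tests passing on this
generator therefore demonstrate estimator correctness under the model's
own assumptions — independent loci, Hardy–Weinberg within populations —
not robustness to the artefacts of real gels.

The preset site layout is illustrative: fixed coordinates scaled so the
mean pairwise distance is 5.99 km; real site coordinates were not
available, and only relative distances enter the Mantel test.

## Scenarios

Decline removes floor(fraction·n) individuals per population, uniformly
without replacement, seeded ("half" is interpreted as floor(n/2) removed,
so odd populations keep the extra individual); extinction drops named
populations and must leave ≥ 2. The whole metric suite is recomputed on
the perturbed matrix with identical settings. Private-allele change is
summarised as a goodness-of-fit χ² of post-scenario per-population
counts against baseline counts, pooling zero-baseline populations into
one cell (dropped if its baseline remains 0), df = cells − 1. This is
the only χ² form consistent with a single statistic over private-allele
counts; note private counts can *rise* under extinction (a band shared
only between a removed and a kept population becomes private), and the
statistic tolerates either direction.

Structure-inference recomputation (MCMC) is excluded from the scenario
comparison by default for speed; run it explicitly on the perturbed
matrix when needed.

## Risk scoring

MER: each criterion (A breadth of distribution, B habitat status, C
intrinsic biological vulnerability, D human impact) maps a qualitative
level to an integer score, normalized by the criterion maximum; the
total over the four criteria is classified as EE (≥ 2.0), E ([1.70,
2.0)), Pr ([1.5, 1.70)). The published interval endpoints overlap at
exactly 1.70; the engine assigns the boundary to the higher-risk
category (precautionary) and flags totals sitting exactly on any
threshold. The level→score tables are this package's own calibration,
shipped as an editable YAML config; the governing standard describes
levels qualitatively and no authoritative numeric table exists. Genetic
evidence (mean He, Nm, private-allele trend with its χ² significance,
scenario-observed declines) is translated by documented rules into a
criterion-C sub-level, and C takes the maximum of its ecological and
genetic sub-scores — genetic knowledge can only raise vulnerability.

IUCN: a simplified engine over the standard category bounds (population
reduction A; restricted area of occupancy with few locations B2; small
population and decline C; very small/restricted population D), plus a
rule treating observed local extinction as quantitative evidence of
collapse (CR). The thresholds live entirely in an editable YAML config
and are external defaults, not fitted to any dataset; the overall
category is the highest triggered, and unlike MER the engine accepts any
subset of criteria. Named presets (2005, 2020e, 2020e_50, 2020e_ex and
their +g variants) bundle representative inputs for a
basic-knowledge/ecological/ecological+genetic assessment sequence; they
reproduce category outcomes, not any particular sub-score breakdown.

## Reproducibility and problem sizes

Every stochastic component (generator, permutation tests, Monte-Carlo
exact test, k-means, Gibbs sampler) takes an explicit seed; the pipeline
derives per-stage seeds from one global seed by hashing the stage name,
so stages rerun in isolation reproduce exactly. Default problem sizes
are chosen at desk scale: 10,000 permutations for AMOVA/Mantel in
one-shot analyses (reduced to hundreds inside scenario comparisons and
replicate studies), 2,000/5,000 MCMC iterations, 20 generator replicates
for calibration checks, 200 replicates for the permutation-null
uniformity check. The acceptance script reports, for each quantity, the
problem size it was computed at.

## Known limitations

- Allele-frequency estimation assumes Hardy–Weinberg within populations;
  inbreeding or clonal structure biases q̂ (the generator can emulate
  clonality, but the estimators do not correct for it).
- The admixture model's θ are band frequencies; do not interpret them as
  allele frequencies.
- The AMOVA is one-level (among/within populations); no region stratum.
- The IUCN engine is a teaching/screening tool, not an assessment-grade
  implementation of the Red List standard; likewise MER scoring depends
  on its editable calibration tables.
- Negative pairwise Φst estimates are floored at zero before
  linearization, a small upward bias for truly undifferentiated pairs.
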