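# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Site calling

Conversion failure during bisulfite treatment makes unmethylated cytosines
read as methylated, so the null hypothesis for a site is "methylation rate
equals the sample's false methylation rate (FMR)". The FMR is the pooled
ratio `Σ n_meth / Σ n_total` over the unmethylated spike-in chromosome;
per-coverage-bin FMRs can be reported but the pooled value is used for
testing, since coverage does not enter the failure mechanism. The test is
the one-sided upper binomial tail — failure can only inflate apparent
methylation, never suppress it. With FMR = 0 the tail degenerates to
p = 1 at `n_meth = 0` and p = 0 otherwise, handled explicitly so no log of
zero is ever taken.

Multiple testing uses Benjamini–Hochberg at α = 0.05 by default
(configurable). A significant site is only *called* methylated if its rate
reaches `min_rate = 0.20` in at least one of the four tissue–treatment
combinations; this guards against calling sites whose statistical
significance rests on high coverage at biologically negligible rates.

Replicates are merged by summing counts after dropping sites that are
replicate-discordant (Fisher's exact test with the same ≥ 20% prefilter,
BH at α = 0.05). Sites covered in a single replicate are retained: they
cannot be tested for replicate disagreement, and dropping them would
discard most low-coverage data; their count is reported in the merge log.

Calibration caveat: binomial tail p-values at realistic coverage are
strongly discrete (at FMR ≈ 0.005 and 20× coverage, ~90% of null sites
have p = 1). Valid discrete p-values are *super-uniform* —
`P(p ≤ t) ≤ t` — so the calibration check uses the one-sided Kolmogorov
statistic `D+ = sup_t (ECDF(t) − t)` against the sampling band
`1.36/√n`; a two-sided uniformity test would reject any discrete test.

## Methylated-region HMM

Two hidden states (U, M) over the sequence of *covered* cytosines, both
strands interleaved in genome order. Emissions are beta-binomial
`(α, β)` pairs, one per state per context (six pairs): the beta mixing
absorbs site-to-site variation in the true methylation level within a
state, and the per-context split is required because plant CG, CHG and
CHH methylation have very different level distributions. The chain runs
over cytosine index, not base pairs, matching the data structure; to keep
regions from spanning coverage deserts, the genome is split wherever
≥ 50 consecutive base pairs contain no covered cytosine (`max_gap = 50`).

Training is Baum–Welch over all segments jointly, genome-wide per sample.
The E-step is log-space forward–backward with emission log-likelihoods
floored at log(1e-300). The M-step updates start/transition from expected
counts; the beta-binomial pairs have no closed-form update, so each is
re-estimated from the posterior-weighted data: a method-of-moments start
(from the weighted mean and variance of per-site rates, falling back to
concentration 10 when the variance is degenerate) refined by Newton
iteration on the digamma-form score, capped at 50 iterations, with step
halving and parameters clamped to [1e-3, 1e6]. The log-likelihood trace is
asserted non-decreasing in the tests. Default initialization: U mean 0.05,
M mean 0.7, concentration 10, transition diagonal 0.9 — weakly informative
and well separated; the two states are exchangeable under EM, so consumers
align them by emission mean.

Decoding is Viterbi ("most probable path"); posterior decoding is
available behind a flag. Ties in the Viterbi recursion resolve toward U
for determinism. Maximal M runs become regions spanning the first to last
cytosine of the run (0-based half-open); both ends are then trimmed by
iteratively removing boundary cytosines with rate < 0.10. Sites with
coverage below the calling threshold participate in segmentation (the gap
rule speaks of covered positions) but not in rate-threshold decisions.
Training pools nothing across tissue–treatment combinations: there is one
segmentation, and one parameter set, per combination (replicates
combined); sharing parameters across combinations is left to the caller.

## Differential methylation

**DMPs.** Two-sided Fisher's exact test (point-probability rule) on
`[[n_meth_A, n_unmeth_A], [n_meth_B, n_unmeth_B]]`, only for the four
sanctioned comparisons and only at sites with `max(rate_A, rate_B) ≥ 0.20`
— the prefilter trades a little power at weakly methylated sites for a
much smaller multiple-testing burden. BH within each comparison.

**DMR candidates.** The union of the four samples' MRs is flattened into
atomic intervals; an interval is a candidate iff its MR-presence pattern
is non-trivial (some but not all samples) and it contains ≥ `min_c = 4`
cytosines covered in every sample. Adjacent atoms with identical presence
patterns are merged. The cytosine floor is an explicit, configurable
stand-in for a pre-test MR filter whose exact published criteria are not
available; four shared informative sites is the minimum at which the
region-level fit is meaningfully constrained.

**Region test.** Per context present in both samples, beta-binomial ML
fits to sample A, sample B, and the pool give
`LOD_c = ℓ_A + ℓ_B − ℓ_joint ≥ 0`; the statistic is `2·Σ_c LOD_c` against
χ² with `df = 2 × (#contexts)` — each separate distribution adds one
(α, β) pair, and the likelihood-ratio convention doubles the log-odds.
The same machinery generalizes to k groups with `df = 2(k−1)·(#contexts)`.
Boundary fits are clamped to [1e-3, 1e6]. The χ² reference is an
approximation at region-sized n; the null simulation in the tests bounds
the realized size at nominal 0.05 by 0.10.

**Grouping and confirmation.** Samples joined by any non-significant
sanctioned pairwise test (p ≥ 0.01) are merged greedily (union-find,
single linkage); the partition is deterministic, and non-transitive
significance patterns are resolved by the same rule and flagged. Counts
are summed within groups and the k-group test on the combined counts is
the candidate's confirmation p-value. Storey q < 0.01 confirms a DMR.

**Storey q-values.** `π̂0(λ) = #{p > λ}/(m(1−λ))` on λ = 0.05…0.95 step
0.05, smoothed by a cubic polynomial evaluated at λ = 0.95 and clamped to
(0, 1]; `q_i = min_{p_j ≥ p_i} π̂0·m·p_j/rank(p_j)`. Below 100 p-values
the π̂0 estimate is too unstable, so the procedure falls back to π̂0 = 1
(exactly BH) with a warning.

**Overlap resolution.** Among mutually overlapping confirmed DMRs the
retained set maximizes the number of significantly differential samples
(ties: total length, then leftmost starts). Overlap clusters are solved
exhaustively up to 20 intervals (clusters are small in practice — the
criterion is checked against a brute-force subset search in the tests);
larger clusters fall back to weight-then-length interval scheduling DP.

## Cross-species classification

Aligned sites are comparable only when the context *label* is identical in
all three species. This single rule implements both stated conditions:
substitutions at H positions leave the label unchanged unless the new base
is G, and any substitution to G changes the label (CHH→CHG/CG, CHG→CG),
so "exclude context transitions and H→G substitutions" is exactly label
inequality. Classification requires three-way testability; sites
untestable in any species are tallied separately rather than guessed.
"Methylated in a species" uses the union over the four tissue–treatment
combinations, consistent with the calling rule. Losses are a relabelling
of two-way-shared sites by the missing species, which the tests assert
(`Σ losses = shared2`), and the classes partition the kept, testable sites.

Feature annotation assigns each site one label by the precedence
TE > exon > intron > 5′UTR > 3′UTR > upstream-1kb > intergenic. TE-first
separates repeat-associated from genic methylation even where a TE sits
inside an intron; the order is configurable. Ortholog-sharing tests use
the upper-tail hypergeometric for pairwise overlap and, for 2/3-way
sharing, the maximum count over 10,000 independent permutations of
region-presence labels across orthologs within each species; an observed
count exceeding every permutation is flagged.

## Expression

The NB GLM uses a log link with `log(library size)` offsets and is fitted
by IRLS, batched across genes (all genes share the design matrix; the
per-gene weighted normal equations are solved in one einsum/solve per
iteration, with a 1e-10 ridge for numerical safety and η clipped to ±30).
Significance is an analysis of deviance: the model is refitted without
each term's columns and the deviance difference referred to χ² with the
term's df — one simultaneous test per factor or interaction, not one per
coefficient. Gene-length corrections are omitted by default.

Dispersion: for each gene the Cox–Reid adjusted profile likelihood
(NB log-likelihood at the profiled β minus `½ log det(XᵀWX)`) is evaluated
on a 25-point log-spaced grid (1e-4 to 10). Genes are binned by mean count
(~10+ genes per bin) and each gene maximizes
`APL_gene + w · mean(APL_bin)` with fixed prior weight w = 10, with a
quadratic interpolation of the grid maximum; estimates are floored at
1e-6. The strong shrinkage makes the estimator nearly unbiased when genes
in a bin share dispersion, which is what keeps the χ² deviance test close
to nominal size at n = 12 (the tests bound each term's type-I error within
[0.03, 0.07] at nominal 0.05); per-gene dispersion outliers are
correspondingly moderated toward the trend.

## Synthetic data

The generator emulates: (a) i.i.d. genomes (default GC 0.36, plant-like)
with both-strand CG/CHG/CHH context assignment; (b) methylomes from a
two-state Markov chain over cytosines (default stay probabilities 0.98/U
and 0.95/M, i.e. ~29% M occupancy in blocks of ~20 cytosines; state means
0.05 and 0.85, concentration 12), Poisson coverage (default 20×), and
additive conversion failure — observed rate = level + (1−level)·FMR,
default FMR 0.005; (c) an unmethylated spike-in chromosome sized at 1/1000
of the catalogue; (d) a 2 tissue × 2 treatment × replicate design in which
replicates share the latent truth and differ only in count noise, with
tissue-specific level shifts injected into designated intervals;
(e) three-way aligned-site maps with H-position divergence and known
conservation classes (defaults: 90% unmethylated, 2% conserved, 6% gains,
2% losses, 2% untestable per species — methylation among aligned sites is
rare and mostly shared, gains outnumber losses); and (f) NB expression
counts under the factorial GLM with configurable effects.

It does **not** emulate read-level artifacts (sequencing error, mapping
bias, PCR duplicates), non-stationary methylation along chromosomes
(centromere gradients), linked CG-dyad inheritance, TE evolution, or
correlated replicate noise. Passing tests therefore demonstrate the
statistical machinery — calibration, recovery, FDR control — under the
stated generative assumptions, not robustness to alignment artifacts or
model misspecification in real data.

Scaled problem sizes used by the test suite and the acceptance script —
30 kb genomes (~10⁴ cytosines) for HMM recovery, 10⁴ null regions/sites
for calibration, 2000 genes for GLM size, and a 100 kb four-combination ×
two-replicate study with 20 injected 400 bp tissue DMRs (level shift
+0.7) for the end-to-end run — were chosen as the smallest sizes at which
the sampling error of each check is comfortably below its tolerance.

## Determinism

All randomness flows through `numpy.random.default_rng(seed)`; EM and
Newton iterations are deterministic given their inputs; Viterbi ties break
toward U; permutation tests take an explicit seed. Identical seeds
reproduce byte-identical tables, trained parameters and regions.

## Known limitations

- The χ² reference for the region log-odds test is approximate; with few
  covered cytosines per region it is mildly anticonservative (bounded in
  the null simulations, not corrected analytically).
- The HMM assumes a single genome-wide parameter set per sample;
  chromosome-specific methylation regimes are averaged over.
- The candidate filter (`min_c = 4` shared covered cytosines) is a
  pragmatic stand-in for a richer MR pre-filter; it is configurable.
- Storey π̂0 needs ≥ 100 tests; below that the procedure is exactly BH.
- The dispersion estimator assumes genes of similar abundance share
  similar dispersion; strongly heteroskedastic per-gene dispersion at
  fixed abundance will be over-shrunk.
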