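# Methods

This note records the models, conventions and numerical choices behind
`coxnet`, in the order data flows through the package.

## Preprocessing

Input is a nonnegative gene × run count matrix plus a run → experiment
grouping. The pipeline order is fixed:

1. **Run filter** — keep runs whose total mapped counts are *strictly
   greater* than `min_total_mapped` (default 10 000 000). Deep runs are
   required for stable correlation estimates of low-expression genes.
2. **Gene filter** — drop genes whose mean count, *across the runs that
   survived step 1*, is strictly below `min_mean_count` (default 30).
   Means are computed after run filtering: shallow runs should not drag a
   gene under the threshold.
3. **log₂(x + p)** with pseudocount p = 1, so a zero count maps to 0.
4. **Quantile normalization within each experiment.** Every sample in an
   experiment is forced onto the experiment's mean-of-order-statistics
   reference. Ties within a sample receive the mean of the reference
   values over their tied rank positions — the standard convention; it
   keeps the map rank-preserving and idempotent (both tested to 1e-9).
5. **Per-experiment gene centering** — subtract each gene's mean within
   each experiment. This removes experiment-level baseline shifts so that
   correlations computed "using all experiments at once" reflect
   within-experiment covariation, not batch structure.

"Experiment" means the experiment ID of the grouping file; one study ≈
one experiment. Distribution-level steps never pool across experiments.

## Mutual Rank

Pearson correlation is computed for every gene pair over all samples
jointly (requires ≥ 3 samples; zero-variance genes are rejected rather
than silently given NaN). For a guide gene g, every other gene is ranked
by descending r, ties broken by ascending gene ID — determinism matters
because downstream lists feed file outputs that must reproduce
byte-for-byte. The Mutual Rank MR(a,b) = √(rank_a(b)·rank_b(a)) is
symmetric and lies in [1, N−1]; MR = 1 iff the genes are mutually best
partners. The guide is excluded before ranking, so ranks run 1..N−1.
Computation is dense (full N×N); the per-row ordering is cached since
edge extraction, list building and supportability all reuse it.

Coexpressed gene lists order all other genes by ascending MR (ties by
gene ID). Network edges are each gene's k = 3 lowest-MR partners,
de-duplicated as undirected pairs, so the edge count lies between
⌈3N/2⌉ and 3N.

## Cross-platform correspondence and common edges

Within a species, a gene corresponds to itself (if present on the other
platform); across species, to every gene sharing its ortholog group —
paralogs expand the match set, and an edge of platform A counts as
common with platform B if *any* combination of endpoint correspondents
is an edge of B. The common-edge summary is asymmetric: A's edge count
is the denominator of the ratio.

## COXSIM and supportability

For guide list list_g and reference list list_r compared at depth k,
n(i) is the number of genes among the top i of list_g with a
correspondent among the top i of list_r, and

COXSIM_k = Σᵢ n(i) / Σᵢ i,  i = 1..k.

The depth is k = round(0.01 · |list_g|) (half-up, floor 1): the top 1 %
of the guide's own list, so platforms with different gene counts are
compared at proportionate depth. k is derived from list_g only.

maxCOXSIM maximizes over the admissible reference guides: all orthologs
of g on cross-species platforms plus the identical gene on same-species
platforms. A guide without any admissible reference is reported as
"no reference" rather than zero stars — absence of evidence is kept
distinct from evidence of absence.

### The null distribution

The null model: both lists are uniformly random orderings, joined by a
uniform random one-to-one correspondence. Only the correspondent
positions of the guide's top-k genes matter; they form a uniform random
injection into the N reference positions, making n(i) hypergeometric
with E n(i) = i²/N and E COXSIM = (2k+1)/(3N).

The integer numerator S = Σᵢ n(i) has an *exactly computable*
distribution. A matched pair at guide depth d and reference position p
(both ≤ k) contributes k+1−max(d,p) to S, and the set of matched pairs
is a partial permutation of the k×k grid. Processing the grid in
L-shaped layers max(d,p) = i, a state (t pairs placed, score s) can
accept zero, one (corner cell, or one of the i−1−t free cells in row i
or column i) or two (one row-cell plus one column-cell) pairs in layer
i, each new pair weighted 1/(N−t); the k−t unmatched guide genes absorb
the probability of landing outside the reference top-k. The recursion
yields the full probability mass function of S; total mass 1 to float
rounding, and the survival function agrees with a 2×10⁶-replicate
Monte-Carlo simulation to three digits. P-values therefore need no tail
extrapolation and remain exact down to float underflow (~1e-300), well
past the three-star threshold of 1e-32. A seeded Monte-Carlo sampler of
the same null (reduced form: hypergeometric match count, uniform
subsets, uniform bijection) ships alongside for diagnostics and is used
by the calibration tests.

The P-value of an observation x is P(S ≥ x·Σᵢi). Because maxCOXSIM
maximizes over |R| references, the per-reference P is Šidák-corrected,
P_max = 1 − (1−p)^|R| (computed via expm1/log1p for tiny p); the
correction assumes independent references and can be switched off. Stars
use strict thresholds: 1 star if P < 1e-4, 2 if P < 1e-16, 3 if
P < 1e-32. Null models are cached per (k, reference list length);
when references differ in length, the null of the best-scoring
reference is used.

Two caveats are worth knowing. First, the null's random-injection
correspondence is one-to-one; paralogous (one-to-many) nulls are not
modeled, so P-values for heavily paralog-expanded maps are slightly
anti-conservative. Second, at shallow depths the statistic is coarse:
for k = 10 and N ≈ 1000, a single lucky match at the top of both lists
already gives S = 10 with probability ≈ 1/N, so the one-star bar
P < 1e-4 demands S ≥ 16 of a maximum 55 — near-perfect list agreement.
Significance resolution grows quickly with k; production-scale platforms
(k ≈ 130–200) do not sit in this coarse regime.

## Synthetic data

The generator emulates the structure the pipeline assumes: groups of
genes sharing an expression program across samples.

- Gene baselines b_g ~ N(5, 1.5) on the log₂ scale; runs fall into
  contiguous experiment blocks with experiment offsets N(0, 0.3) and
  per-gene-per-experiment effects N(0, 0.2), so per-experiment
  normalization and centering have observable work to do.
- Each of `n_modules` modules (default 10 × 20 genes, placed on a seeded
  random subset of the 1000 genes) has one latent factor per sample.
  A module gene's log₂ expression adds √c·σ times its factor and
  √(1−c)·σ independent noise, with σ = `noise_sd` (0.6) and
  c = `within_module_corr` (0.8), so the realized within-module
  correlation is ≈ c. Background genes get pure σ noise.
- Log-scale expression is exponentiated, scaled so each run's expected
  total is `library_size_mean` (2×10⁷, comfortably above the run-filter
  threshold, with 10 % lognormal depth variation) and Poisson-sampled —
  the minimal model giving the mean–variance coupling the log₂(x+1)
  pipeline expects.
- The platform pair shares module *memberships* (linked one-to-one by an
  ortholog map covering a configurable fraction of genes) but draws
  fresh factors, samples and noise. Unshared modules are placed on genes
  that are background in the other platform. The planted truth is
  returned as a separate table and never written into pipeline-facing
  files.

What the generator does **not** emulate: correlated background programs,
per-gene loading heterogeneity (all module genes are exchangeable, so
cross-platform list orderings of true partners are independent),
platform-specific probe effects, and count overdispersion beyond
Poisson. Consequences: recovery results here are conservative in one
specific way — real conserved modules have heterogeneous, conserved
loading profiles that make their list orderings agree across platforms
more than exchangeable modules do. Passing the planted-module tests
shows the pipeline recovers exchangeable-module structure; it does not
quantify performance on real data.

Under the default conditions (1000 genes, k = 10) the exchangeability
of module genes combines with the coarse-k regime described above:
even a contamination-free module gene clears the one-star bar with
probability only ≈ 0.78 (enumeration of random permutation pairs), and
the end-to-end rate is ≈ 0.6 once Mutual Rank's reciprocal-rank-1
background attachments are included. The background specificity
(≥ 99 % zero stars) and the shared-vs-unrelated common-edge contrast
are robust at these sizes.

## Numerical and interface choices

- Files are TSV, UTF-8, mandatory header, '#' comments; MR/COXSIM are
  written with 6 significant digits (beyond any threshold's resolution).
  Readers validate and reject; they never repair.
- Gene IDs are opaque strings; no accession validation.
- All randomness flows from explicit integer seeds (numpy Generator);
  same config + seed ⇒ byte-identical outputs, and CLI outputs carry a
  provenance line (version, config hash, seed) instead of timestamps.
- Problem sizes in the test suite and acceptance script (1000 × 200
  platforms, 2000-replicate calibration, 20 comparison trials) are the
  package's documented study conditions for desk-scale validation.
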