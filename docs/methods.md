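# Methods

This note documents the statistical procedures implemented in `amplicore`,
the parameter choices that matter, and what the synthetic-data generator does
and does not emulate.

## Data model

The pipeline's currency is the `OtuTable`: a samples × OTUs matrix of
non-negative read counts at one OTU clustering level (the `label`, e.g.
`0.03` ≈ species, `0.10` ≈ family). Counts are stored as reals because the
replicate-averaged tables produced by even-depth normalization are fractional
by construction; integer-ness is a queryable property and operations that
require raw integer counts (down-sampling, frequency-count estimators) assert
it. All-zero OTU columns are dropped at construction (and logged): an OTU with
no support in any sample is unobservable. Sample order is preserved from the
input file and used canonically in every matrix and report, so outputs are
deterministic.

## Even-depth normalization

Samples of unequal sequencing depth are made comparable by down-sampling each
to a common depth *d* **without replacement**: each sample's new counts are a
multivariate-hypergeometric draw from its observed reads. This is rarefaction
in the strict sense — subsampling actual reads — not a multinomial resampling
of an estimated composition. The *averaged shared table* is the entry-wise
mean of `replicates` (default 5) independent down-samplings; per-sample totals
remain exactly *d*, and fractional means are kept unrounded, since rounding
destroys information that downstream consumers (e.g. the core filters) can
interpret for themselves. Replicate *r* uses seed `master_seed + r`, so a
replicate set is reproducible and a single replicate coincides with a plain
down-sampling at the master seed.

## Alpha diversity

Per sample, from the abundance-frequency counts F₁, F₂, … (F_k = number of
OTUs seen exactly k times):

* **Chao1 (bias-corrected):** S_obs + F₁(F₁−1)/(2(F₂+1)). The +1 form is
  defined at F₂ = 0 and is the default in the standard amplicon toolchain.
  The 95 % CI is Chao's log-normal interval on the unseen-species count
  T = Ŝ − S_obs with the classic variance of the bias-corrected estimator.
* **ACE:** S_abund + S_rare/C_ace + (F₁/C_ace)·γ², with the rare class at
  counts ≤ 10 (the universal convention; configurable), C_ace = 1 − F₁/N_rare,
  and γ² the squared coefficient of variation of rare-class abundances,
  clamped at 0. When every rare read is a singleton, C_ace = 0 and ACE is
  undefined; the implementation falls back to Chao1 and flags the fallback in
  the output rather than failing or guessing. No closed-form CI is universal
  for ACE, so the variance is obtained by the delta method — a numerical
  gradient of the estimator with respect to (F_k) combined with the
  multinomial-type covariance Cov(F_i, F_j) = F_i(δ_ij − F_j/Ŝ) — and mapped
  through the same log-normal transform as Chao1.
* **Shannon H′** uses natural logarithms throughout (evenness is base-free,
  but H′ magnitudes are reported in nats), with the first-order analytic
  variance (Σp ln²p − H²)/N.
* **Faith's PD** is *rooted*: the sum of branch lengths of the minimal subtree
  connecting the present leaves **and the root**. The stem edges matter for
  singleton sets, where unrooted PD would be 0.
* **Rarefaction** is analytic: E[S_n] = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)],
  evaluated with log-binomials for stability, and verified in tests against a
  10,000-draw Monte-Carlo oracle.

The replicate-averaged summary reports each estimator as the mean over the
down-sampling replicates; CI columns are by default the **means of the
per-replicate analytic CI bounds** (matching the convention of reporting a
mean of five subsample estimates), with an empirical t-interval of the
replicate point estimates available behind `ci_of_means=True`.

## Beta diversity and overlap

Bray-Curtis (Σ|x−y|/Σ(x+y)) and Morisita-Horn are the primary dissimilarities;
Morisita-Horn is invariant to scaling one sample's counts and dominated by
abundant taxa, Bray-Curtis is not scale-invariant — both assertions are
property-tested. An incidence-based Sørensen option is also provided for
presence/absence comparisons; the abundance-based Bray-Curtis is the form
implemented under that name because that is what the cited formula defines.
The overlap (Venn) report partitions OTUs by the exact subset of samples in
which they reach a presence threshold (default ≥ 1 read; the core analysis
applies its own, stronger filters) and reports the fraction of all reads
carried by the OTUs present in every sample.

## Core-microbiome delineation

See the README for the three criteria. Numerical policy:

* the read floor is `count ≥ 3` (the strict reading of "more than two
  reads"); the frequency floor is a strict `> 0.1 %`; evenness is a strict
  `> 0.9`. OTUs passing both abundance filters whose evenness lies within
  0.005 of the threshold are logged as near-boundary, since at typical depths
  the evenness of a low-count OTU is a coarse-grained statistic;
* for averaged (fractional) tables the same thresholds are applied to the
  per-sample means; the report flags this interpretation;
* the report keeps every OTU with its per-criterion verdicts, and exposes
  *near-misses* (OTUs failing exactly one criterion) for diagnostics;
* whether to delineate on a single smallest-depth down-sampling or on the
  replicate-averaged table is left to the caller (`use_averaged` in the
  pipeline, default: averaged), as both are defensible normalizations.

Consensus taxonomy is majority-rule per rank (> 50 % of members), with every
rank at and below the first failure set to the explicit `unclassified`
sentinel, serialized in the semicolon constaxonomy style.

## Correlation with environment

Spearman's rho is the Pearson correlation of mid-ranks. For n ≤ 8 the
two-sided p-value is computed **exactly** by enumerating all n! permutations
of one rank vector; for larger n the t-approximation is used. At the n = 5 of
a typical survey the exact p for |rho| = 1 is 2/120 ≈ 0.0167 and for
|rho| = 0.9 it is 10/120 ≈ 0.083 — a printed "p = 0" from large-sample
software is a rounding artifact, and tests treat it as a bound, not a value.
No multiple-testing correction is applied by default (the number of tests is
recorded); Holm adjustment is available behind a flag.

## Synthetic surveys

`simulate` emulates the study design the pipeline targets: 5 samples at
depths (2,632, 3,446, 7,062, 5,852, 4,440) reads — realistic post-QC totals
for a small pyrosequencing survey — over 600 OTUs, with

* a log-normal species-abundance distribution (μ = 0, σ = 1.5);
* a per-OTU stress tolerance t ~ U(0, 1) and a per-sample contamination level
  z ∈ (0, 0.30, 0.55, 0.75, 0.90): a non-core OTU is present in a sample iff
  t > z, so *true* per-sample richness declines deterministically along the
  gradient (600 → ≈ 80 plus the core);
* per-sample log-normal abundance heterogeneity for non-core OTUs
  (σ = 1.5, i.e. a typical ±4–5-fold site-to-site swing in relative
  abundance), which is what keeps merely-ubiquitous background OTUs from
  looking evenly distributed;
* a planted core of 20 OTUs, each owning an expected *fraction* of every
  sample's composition (log-normal around 0.4 %, comfortably above the 0.1 %
  filter), jittered across samples by a Dirichlet with concentration 300 so
  cross-sample evenness is ≈ 0.99 in expectation;
* reads drawn per sample by a multinomial at the configured depth — with
  replacement, because generating reads from a composition is sampling a
  population, deliberately distinct from the without-replacement
  down-sampling applied downstream;
* a random coalescent-style ultrametric tree over the OTUs and a six-rank
  dummy taxonomy.

These defaults were fixed by a design calculation (Poisson detection margins
at the smallest depth; the evenness distribution of five log-normal weights)
plus a brute-force sweep over seeds, before the recovery thresholds were
frozen into the tests: at the defaults, core recovery by the default criteria
attains ≈ 0.97–0.98 pooled precision and recall over 20 seeds, and the
rank correlation between contamination and rarefied observed richness is
−1.0 in the median.

What the generator does **not** emulate: sequence-level noise (chimeras,
homopolymer errors), phylogenetic signal in who tolerates stress (tolerances
are independent of the tree), compositional interactions between taxa, and
multiple correlated environmental drivers. Passing the recovery tests
therefore shows the *statistics* behave as designed under a clean planted
model — not that any real community has a core of this shape.

## Problem sizes and determinism

Tests and the acceptance script run the full design at its native size
(5 × 600, depths above, 20 seeds for recovery), which completes in well under
a minute; Monte-Carlo oracles use 10,000 draws with 3-standard-error bands.
All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical seeds give bit-identical tables,
files and reports on any platform.
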