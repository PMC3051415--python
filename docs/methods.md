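# Methods

This note records the models behind `ancestrykit`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices a user auditing results should know
about.

## Admixture model and sampler

Individuals are unrelated diploids typed at L unlinked biallelic loci.
Individual i carries ancestry proportions Q_i on the K-simplex; each of the
2L allele copies has a latent continental origin z with
p(z = k) ∝ q_ik · p_kl(allele), where p_kl is population k's allele-1
frequency. The Gibbs sweep samples, in order: all latent origins; each
individual's Q_i ~ Dirichlet(α + origin counts); each p_kl ~ Beta(λ + allele-1
count, λ + allele-0 count); and (optionally) the symmetric concentration α by
a Metropolis random walk in log α under a log-uniform prior on [0.01, 10].
Frequencies use the independent Beta(λ=1, λ=1) prior ("uncorrelated
frequencies"); the correlated F-model is deliberately out of scope, so any
deviation from software using it is expected and explicit. Missing dosages
contribute no copies anywhere.

**Why α is sampled.** With a fixed flat Dirichlet prior (α = 1), the
posterior mean of a component is bounded by (1 + 2L·q)/(K + 2L) no matter
how informative the data: at L = 24, K = 4 a true ancestry of 0.93 can never
be reported above ≈ 0.88. Panels of a few dozen loci therefore need the
hierarchical treatment; sampling α (initialized at 1) removes the bound
while keeping the flat prior as the starting point. `update_alpha=False`
restores the fixed-α sampler, which is what the exact-integration
correctness check uses (its oracle integrates under a uniform prior).

- Supervised mode: parental individuals' origins are pinned by their labels,
  so their allele counts enter the frequency update as constants; study
  copies also update frequencies by default (`update_freqs_from_study=False`
  freezes p at the parental posterior mean).
- Unsupervised mode: all Q free, α always sampled; clusters are matched to
  reference labels by a one-to-one assignment maximizing mean membership
  (Hungarian algorithm), and the misclassification fraction counts
  individuals whose modal cluster is not their group's matched cluster.
- No-admixture mode: one latent cluster label per individual, uniform prior,
  whole-individual binomial likelihood.

Defaults: burn-in 10,000 / 10,000 retained sweeps (the cohort-scale runs);
the orchestrated study analog uses 1,500/1,500, which reproduces group-level
summaries to well within their Monte-Carlo error at n ≈ 600, L = 24.
Per-individual equal-tail 95 % credible intervals come from up to 500
stored post-burn-in draws. Reported group "95 % intervals" are the
empirical 2.5–97.5 percentiles of individual posterior-mean ancestries
across the group — an interval describing between-individual spread, not a
standard error of the mean (printed intervals of this kind in cohort
studies are far too wide to be standard errors).

**Sampler validation.** On K = 2, L = 2 instances with fixed frequencies the
Gibbs posterior mean is compared against deterministic numerical integration
of q·L(q) over a 20,001-point grid (uniform prior); agreement is required to
±0.01.

## Informativeness statistics

I_n is computed in nats (natural logarithm), making the upper bound ln K
exact; terms with p = 0 contribute 0. Allele frequencies are estimated by
simple counting with missing dosages excluded from numerator and
denominator — no shrinkage, so estimates are transparent and unbiased.
The single-population F_ST uses the unweighted cross-population mean
frequency and is defined as 0 when that mean is 0 or 1.

The regression screen fits OLS of one per-locus I_n set on another
(statsmodels), flags loci outside the two-sided prediction interval at the
configured level (default 99 %), and reports the two-tailed t-test of
slope = 1. The regression is unweighted and uses cluster-pooled frequency
estimates; a weighted alternative would need per-locus sampling variances
that small panels cannot estimate stably.

## Genetic-algorithm panel selection

Panel fitness is the sum of per-locus I_n over the subset — loci are
treated as unlinked, and no epistatic/multilocus criterion is used.
Chromosomes are size-m locus subsets; operators are tournament selection
(k = 3), uniform crossover on the union repaired back to size m, per-slot
swap mutation (rate 0.02) replacing a member with a non-member, and
elitism (2). Defaults (population 200, 300 generations) solve enumerable
instances exactly; "minimal panel" is delegated to the user via a
score-vs-m sweep because no principled stopping rule exists for additive
fitness. An exhaustive-search oracle covers small instances in the tests.

## Haplogroup calling and continental accounting

The NRY phylogeny ships as YAML (42 markers: 24 core + 18 haplogroup-E
subtyping markers) arranged per standard YCC-style nomenclature; it is data,
not code, because topology revisions should not require a release. One
marker's published placement (M106) is uncertain and is kept as a K-lineage,
noted in the file. The caller returns the deepest node whose terminal edge
is derived and whose root path contains no off-path derived marker;
missing path markers do not block descent (deeper derived evidence
confirms them), an explicitly ancestral path marker below a derived call
triggers a warning (treated as probable dropout), and derived markers on
incomparable branches raise a conflict error listing them. Two-tier typing
consults the subtype markers only when the core call lies inside
haplogroup E, mirroring a two-round genotyping design.

Haplogroup→continent maps are longest-prefix lookups shipped as editable
YAML (synthetic stand-in content assembled from published continental
assignments); every orchestrated run records the map's SHA-256 checksum in
its manifest. mtDNA haplogroup labels are consumed as-is; calling from
sequence is out of scope.

Sex-bias and regional questions about count compositions use an exact
conditional test on the r×c table: the p-value is the total probability of
tables (fixed margins) whose multivariate-hypergeometric point probability
does not exceed the observed one. Full enumeration is used when a cheap
bound puts the table space under 2·10⁵ tables; otherwise Monte Carlo with
100,000 tables by default, reported with its binomial standard error and
the (1 + hits)/(B + 1) estimator. A descriptive statistic, −2 ln of the
observed-to-modal point-probability ratio, is reported alongside but is
non-canonical and is never used for inference. Regional tests on continuous
ancestry fractions use the tie-corrected Kruskal–Wallis test restricted to
regions with strictly more than `min_region_n` (default 10) individuals;
complete ties return H = 0, p = 1.

## Distance statistics

IBS distance between two individuals is 1 − mean over co-typed loci of
1 − |d₁ − d₂|/2; pairs sharing no typed locus are an error rather than a
guess. Exact-zero off-diagonal distances are raised to 0.001 so ordination
never receives coincident points. Missing-data policy everywhere in this
module is pairwise-complete loci.

NMDS is Kruskal's: each SMACOF iteration fits disparities by
pool-adjacent-violators regression of configuration distances on
dissimilarity ranks (ties receive distinct rank positions via a stable
sort), rescales disparities to the current distance norm, and applies the
Guttman transform; stress-1 = √(Σ(d̂−d)²/Σd²), convergence at Δstress <
1e-6, best of 8 random starts, 500 iterations each. A start is cut short
if stress ever increases, so the reported trace is non-increasing by
construction. Random initialization depends only on the seed and the
matrix size, which makes the embedding exactly invariant under monotone
transforms of the input dissimilarities. The orchestrated pipeline
subsamples to 300 individuals before the O(n²)-per-iteration ordination;
the stress of a 300-point subsample of a ~1,200-point IBS matrix is a
stable summary at 24 loci.

AMOVA is one-level (groups / individuals within groups): squared molecular
distance between genotypes is the number of allele differences summed over
co-typed loci (|d_i − d_j| per locus); haplogroup data use 0/1 identity.
SS_total = Σ_{i<j} d²/N, SS_within = Σ_g Σ_{i<j∈g} d²/n_g, variance
components from the mean squares with the unequal-size coefficient
n′ = (N − Σn_g²/N)/(G−1), Φ_ST = σ²_a/(σ²_a+σ²_w), and the permutation
p-value is (1 + #{Φ_perm ≥ Φ_obs})/(n_perm + 1) permuting individuals among
groups (default 10,000 permutations; 999 in the orchestrated analog). The
within-individual level of classical three-level AMOVA is omitted because
dosage data carry no phase — a recorded limitation, which makes the
"percent among groups" here systematically comparable only to other
one-level analyses.

## Synthetic-data generator

The generator emulates the statistical structure of a four-continent
admixture study of U.S. Americans:

- **Parental panels.** Balding–Nichols frequencies: ancestral p uniform on
  (0.1, 0.9); population i draws Beta(p(1−F_i)/F_i, (1−p)(1−F_i)/F_i), so
  the mean is p and the variance p(1−p)F_i. Defaults F = 0.2 per panel
  (0.25 for the America panel, which has experienced the strongest drift).
  Panel sizes default to HGDP-like cluster sizes (100/160/230/64).
- **Marker ascertainment.** Real ASM panels are the extreme tail of a
  genome-wide scan, not random loci; the generator therefore draws a
  10,000-locus candidate pool and keeps, round-robin, each population's
  top single-population-F_ST loci until L = 24 are chosen. Random
  (unascertained) Balding–Nichols loci at continental F are far less
  informative than any deployed AIM panel and would misrepresent the
  study conditions; `ascertainment_pool=None` restores plain draws.
- **Study groups.** Four self-declared groups at the published sample sizes
  (246/245/127/46, scalable) with Dirichlet ancestry whose means follow the
  reported group averages (e.g. 0.862 African in the African-American-like
  group; 0.612/0.149/0.108/0.116 for the Hispanic-like group) and whose
  concentrations (6/10/3/8) produce individual spreads resembling the wide
  reported 2.5–97.5 percentile ranges. Groups with reported regional
  structure get the published per-region sizes and modest Dirichlet shifts
  per region so regional heterogeneity is detectable at full cohort size.
- **Uniparental systems.** Per-group continental-origin probability vectors
  for NRY (males only; sex is Bernoulli(0.5)) and mtDNA (everyone), set to
  the reported uniparental ancestry proportions — independent of the
  autosomal Q, because the three systems are analyzed as separate
  quantities and their joint single-genealogy coupling is not modelled.
  Origins are dressed as haplogroup labels drawn uniformly from
  per-continent pools (editable YAML) consistent with the packaged
  continent maps.

What the generator does **not** emulate: linkage disequilibrium between
loci (the panel is treated as unlinked, as a real ASM panel is designed to
be), genealogical correlation between uniparental origin and autosomal
ancestry within an individual, genotyping error and missingness patterns
of real assays, sub-continental structure inside parental panels, and any
coupling between self-identification and genotype (so the
pigmentation-marker outlier phenomenon is *not* built in; the regression
screen on synthetic data should and does find ≈ 0 outliers). Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not robustness to those real-data features.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.Generator` objects seeded from
  one configuration seed; every stochastic function takes an explicit
  generator or seed.
- Frequencies sampled in the Gibbs chain are clipped to [1e-9, 1−1e-9];
  mixture likelihood logs are clipped at 1e-12 — both guard exact-zero
  posteriors created by fixed panels.
- Missing genotype sentinel is −9 (STRUCTURE convention) internally and in
  the two-row dialect; empty cells in CSV. Dosage counts a declared
  reference allele per locus; when undeclared, the smallest observed allele
  code is the reference.
- Enumeration vs Monte-Carlo switch in the exact test uses a product upper
  bound on the number of tables; point-probability comparisons use an
  additive 1e-9 log-tolerance so ties are counted as "as extreme".
- Orchestrated-run problem sizes (1,500/1,500 sweeps, 999 permutations,
  20,000 MC tables, 300-point MDS subsample) were chosen so that one full
  study analog completes in about a minute on a laptop core while keeping
  every Monte-Carlo error an order of magnitude below the effects of
  interest.

## Known limitations

- The independent-frequency prior ignores the shared-ancestry correlation
  between parental panels; Native-American vs East-Asian discrimination at
  24 loci is accordingly optimistic relative to real panels.
- The GA optimizes an additive criterion, so it is equivalent to top-m
  selection; it exists for its extensibility to non-additive criteria and
  as a faithful re-implementation of the ascertainment strategy.
- Exact-test p-values are conservative on very sparse tables (discreteness).
- Haplogroup-level AMOVA (0/1 identity distance) is driven as much by the
  within-continent haplogroup diversity of each group as by between-group
  continental composition; the generator's uniform per-continent label
  pools emulate that diversity only crudely, so the *relative* sizes of the
  NRY and mtDNA among-group percentages on synthetic data should not be
  read as predictions for real cohorts.
- The NRY tree and continent maps are literature-informed defaults, not
  authoritative; both are data files intended to be replaced by users with
  study-specific versions (the manifest checksum exists for exactly that
  reason).
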