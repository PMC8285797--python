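# Methods

This note records the models, estimators, numerical conventions and
design choices behind `blockdiv`, and what the simulation-based tests do
and do not establish about real data.

## Synthetic panels (`simdata`)

Breeds drift independently from one ancestral gene pool under the
Balding–Nichols model: ancestral frequencies are uniform on
[0.05, 0.95] (mimicking array ascertainment against rare variants), and
each breed's frequency at a SNP is Beta(p(1−F)/F, (1−p)(1−F)/F), so
that E[p_breed] = p and Var = F·p(1−p). F is the breed's expected
divergence from the ancestral pool; between two breeds drifted at F
each, the Hudson-style ratio-of-averages F_ST estimator converges to F
itself (verified against a 2×10⁶-replicate simulation in the tests).

Default study conditions, used by the acceptance checks and chosen once:
10 breeds × 30 animals, F = 0.1 (typical of differentiated livestock
breeds), 10,000 biallelic SNPs on 29 autosomes at 60 kb mean spacing.
Inter-SNP distances are exponential (Poisson marker placement). A
near-regular grid with ±10% jitter is available
(`spacing_model="uniform_jitter"`), but at 60 kb mean spacing a regular
grid leaves essentially no sub-50 kb gaps and therefore no 4-SNP blocks;
the exponential layout reproduces the empirically observed regime where
roughly half the markers fall into blocks.

Haplotypes are drawn independently per SNP given the breed frequency, so
there is **no background linkage disequilibrium**; block alleles are
well-defined but their frequency spectrum is that of independent loci.
Two kinds of known-truth contamination can be injected:

* **admixed animals**: each gamete allele is drawn from the donor
  breed's frequency with probability α, else from the recipient's —
  an instant-admixture genome without tract structure. α = 1 models an
  animal of the donor breed mislabelled as the recipient.
* **relative pairs** with expected UAR 0.5: parent–offspring (one
  in-panel parent, a hidden mate, gametes formed with Haldane-style
  crossovers at ~1 per 100 Mb) or full sibs (two hidden parents, two
  in-panel offspring). Hidden out-of-panel parents keep every injected
  pair disjoint from the rest of the panel, so each pair should cost
  exactly one animal at the pruning stage.

All randomness flows from a single integer seed through independent
named streams (frequencies / genotypes / admixture / relatives), so
injections do not perturb the base panel and identical configurations
are byte-identical.

What the generator does **not** emulate: LD and haplotype-block
structure of real genomes, mutation, selection, non-equilibrium
demography, genotyping error and missingness patterns, and continuous
gradients of admixture. Passing tests therefore demonstrate the
procedures' behaviour under clean drift-plus-admixture structure, not
their operating characteristics on any particular real panel.

## Quality control (`genotype_io`)

Per-SNP filters: call rate ≥ 0.95, minor allele frequency ≥ 0.025
(computed on the pooled sample — standard array practice; the per-breed
alternative would remove breed-specific variation), autosomes only
(chromosome labels that are numeric after an optional `chr` prefix).
Breed inclusion requires at least 14 genotyped animals. Positions are
1-based (VCF convention). Haplotypes must be phased and complete before
block encoding; a `drop_missing` escape hatch codes a sample's block as
absent when any of its calls in the block is missing (both gametes are
dropped to keep copy counts even). Pedigree-based genotyping-error
checks and phasing/imputation are upstream concerns and out of scope.

## Haplotype blocks (`blocks`)

Blocks are built greedily left-to-right per chromosome: open at the
current SNP, extend while each adjacent gap is < 50,000 bp (strict) and
the running first-to-last span is < 150,000 bp (strict), emit at four
SNPs, restart at any violating SNP, discard trailing runs. The policy is
deterministic and independent of sample content. Distinct 4-symbol
phased haplotypes per block are dense-coded in first-observed row order;
codes are private to one dataset instantiation — cross-dataset
comparisons must use the haplotype strings.

## Relationship matrix and pruning (`relatedness`)

The UAR estimator standardises dosages with allele frequencies from the
**current full sample** (the cited convention; recomputed from survivors
at every iteration). Monomorphic SNPs are excluded from the average.
Off-diagonals of unrelated animals centre at −1/(n−1). Under pooled
multi-breed frequencies, same-breed unrelated pairs sit at a positive
baseline (≈ 0.17 at F = 0.1), so a parent–offspring pair realises
≈ 0.62 rather than 0.5; the 0.25 threshold separates both regimes.

Pruning removes one animal per iteration — the one with most
over-threshold within-breed partners, ties broken by higher mean
within-breed relationship, then by lexicographically last id — and
recomputes the matrix. On disjoint pairs and family cliques this equals
the minimum vertex cover (verified against exhaustive search on random
small instances). An animal is never removed if its breed would fall
below two animals; such a breed is retained as-is with a warning.

## Outlier detection (`outliers`)

Features per animal of a focal breed (robust z-scored by median and
normal-consistent MAD; zero-MAD columns dropped):

* `f1` mean UAR with own-breed animals (self excluded);
* `f2` mean of the top-5 UAR values with other-breed animals. A plain
  maximum has a Gumbel-like null (heavy right tail ⇒ false flags) and is
  dominated by single-pair noise; averaging the strongest few links
  keeps the admixture signal, which is spread over many donor-breed
  animals;
* `f3` foreign-allele proportion: fraction of the animal's 2×(blocks)
  block-allele copies absent from own-breed animals (self excluded) and
  present in ≥ 1 other breed;
* `f4` number of other-breed animals with UAR > 0.1 (half the pruning
  threshold; separates background cross-breed noise from genuine recent
  shared ancestry). In clean panels `f4` is constant zero and drops out
  via the zero-MAD rule.

Squared robust Mahalanobis distances come from a minimum covariance
determinant fit (support fraction 0.75) and are rescaled so their median
matches the chi-square median (consistency at the sample). **Distances
at breed-size n are far from their asymptotic chi-square law** (the
reweighted MCD lacks small-sample corrections: ~13% of clean animals at
n = 30 exceed the chi-square 97.5% quantile). All cutoffs are therefore
taken from a simulated Gaussian null at the same (n, d): 100 replicates
pushed through the identical estimator, deterministic per (n, d),
cached.

Three cutoff rules, for two different jobs:

* `simulated` (detector default): the null (1−α) quantile of the pooled
  per-animal distances — marginal false-flag rate α by construction
  (measured 2.6% at nominal 2.5%, n = 200, d = 4). Suited to one-shot
  screening.
* `maxnull` (removal-loop default): the null (1−α) quantile of the
  per-dataset **maximum** distance — a clean breed flags anything with
  probability ≈ α. Admixed animals sit orders of magnitude beyond
  either cutoff (distance/cutoff ratios ~50 at α_mix = 0.5), so
  sensitivity is unaffected, while the remove-and-repeat loop no longer
  erodes clean breeds: a marginally calibrated rule flags ≥1 of 30
  clean animals with probability ≈ ½ per round, which iterates into a
  5–9% false-removal rate; the family-wise rule measured 0.2–0.5%.
* `adaptive`: an adjusted-quantile rule (flag the tail only where the
  empirical distance distribution exceeds the null by more than a
  critical fluctuation (0.24 − 0.003d)/√n, outlier fraction capped at
  the MCD breakdown 25%), referred to the simulated null rather than
  the chi-square law.

The `chi2` rule (asymptotic quantile) is retained for reference. If the
robust scatter is singular, detection falls back to a univariate robust
z rule (|z| > 3.5 in any feature), logged.

The iteration recomputes UAR and block alleles from the survivors each
round and tests every breed against the full current panel (foreign
quantities shift when other breeds lose animals). A breed converges at
its first flag-free round. Removals per breed and round are capped at
(size − 14) so no breed falls below the inclusion minimum; a capped
breed removes its worst distances and freezes.

## Diversity statistics (`diversity`)

Within-breed He is plain gene diversity 1 − Σp² (no small-sample
correction; the corrected versions live in the differentiation
estimators where Jost's D requires them). Breed values are unweighted
means over blocks. Hdef = (He − Ho)/He is undefined (NaN) when He = 0.
Rarefaction operates on gene copies (2 per diploid animal); the default
standard is twice the smallest breed size. AR sums hypergeometric
retention probabilities per allele, computed with log-gamma for
stability, and equals the brute-force mean distinct-allele count over
all subsamples (verified exhaustively for N ≤ 12).

## Differentiation (`differentiation`)

Per block and breed pair, with ñ the harmonic mean of the two breed
sizes in animals, s = 2 populations and Ho the mean observed block
heterozygosity of the pair:

    Hs_hat = ñ/(ñ−1) · (1 − (Σp₁² + Σp₂²)/2 − Ho/(2ñ))
    Ht_hat = 1 − Σp̄² + Hs_hat/(ñs) − Ho/(2ñs)

The −Ho/(2ñ) term matters: without it Hs is biased upward by ≈He/(2ñ),
which exceeds the true block-level signal at breed-size samples and
drives the estimators negative. Components are averaged over blocks
before forming D_est = (Ht − Hs)/(1 − Hs)·s/(s−1) and
G_ST = (Ht − Hs)/Ht (per-block-D averaging available behind a flag;
it is noisier at near-monomorphic blocks). Nei's D_A uses raw
frequencies. Small negative estimates are clamped to zero in exported
matrices; raw values are available from the pairwise functions. Blocks
where either breed has fewer than two animals with data are skipped.

PCA standardises dosages by 2p and √(p(1−p)) and takes the thin SVD —
adequate for structure checks; no LD pruning or outlier iterations of
dedicated PCA tools.

## Allelic partition and pool (`metapop`)

A_S is the mean allele count per breed per block; D_A the mean over all
ordered breed pairs (i, j), including i = j, of alleles present in i and
absent from j; A_T the same mean of pooled-pair allele counts. Including
the diagonal pairs makes A_T = A_S + D_A an exact identity (machine
precision), with the single-breed degenerate case D_A = 0.
Contributions are leave-one-breed-out percent changes; positive means
diversity is lost when the breed is removed. Allele counts use raw K
per block (not K − 1).

The pool optimizer maximises the expected distinct-allele count under
binomial sampling of 2n_i gene copies per breed, by greedy unit
allocation (provably strong for this monotone submodular objective)
plus pairwise-swap hill climbing; it matches exhaustive search on all
small instances tested and never loses to 1,000 random compositions.
Log-space accumulation of Π(1−p)^(2n) avoids underflow; frequencies are
capped at 1 − 10⁻¹² before taking logs.

## Pipeline

One-step = pruning only; two-step = outlier iteration, then pruning on
survivors. All statistics are recomputed from scratch on each stage's
retained animals. A single seed propagates to every stochastic
component and is logged in report headers; reports are byte-identical
across reruns.

## Problem sizes

The test suite runs desk-scale configurations: 3 breeds × 20 animals ×
2,000–5,000 SNPs for unit and property tests, and 50 replicates of the
standard 10 × 30 × 10,000 conditions for the operating-characteristic
checks (about two minutes of compute). The acceptance script uses the
same sizes.

## Known limitations

* No LD in simulated data: block-allele spectra are those of
  independent SNPs; real panels have fewer, more structured block
  alleles.
* The Gaussian null for outlier cutoffs transfers only approximately to
  the real feature distributions (cross-animal correlation through
  shared UAR entries slightly heavies the tails; measured per-call
  clean flag rate 3.6% vs nominal 2.5% at n = 30). The family-wise
  `maxnull` rule absorbs this comfortably; the marginal `simulated`
  rule inherits it.
* Admixture signatures assume the donor (or a related breed) is present
  in the panel; admixture from an unsampled population is detectable
  only through `f1`/`f3`.
* Allele codes are dataset-local; persisted analyses must join on
  haplotype strings.
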