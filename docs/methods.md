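# Methods

This note documents the statistical model, its assumptions and defaults,
the synthetic-data generator, and the numerical and design choices made
where the design was genuinely open. Notation: at one genomic locus the
pooled base counts across all cells of the current node are
c₁ ≥ c₂ ≥ c₃ ≥ c₄ with total c; θ is the per-base error probability on
informative positions.

## Assumptions

* All cells are diploid; only single-base substitutions are modeled
  (no CNVs, no indels).
* Sequencing errors are unbiased: a base is misread to each of the
  other three bases with probability θ/3.
* Somatic SNVs are, with equal probability, of type AA→AB (a
  homozygous site becomes heterozygous in the subclone) or AB→AA (a
  germline heterozygous site loses its alternate allele).
* A fragment — both mates of a read pair — is a contiguous sample of
  exactly one haplotype.

## Bayesian locus filter

The posterior that all cells share one homozygous genotype is

    P(M=1 | c) = P(c | M=1) · P(M=1) / P(c).

`P(c | M=1)` is approximated by the dominant homozygous genotype: a
multinomial with event probabilities (1−θ, θ/3, θ/3, θ/3), maximized by
the majority base (asserted as a test property). The evidence `P(c)` is
approximated by a four-term sum over locus classes — homozygous,
heterozygous, homozygous+mutated, heterozygous+mutated — with a single
multinomial coefficient shared by all four terms and class priors
p_het = p_mut = 10⁻³, p_hom = 1 − p_het − p_mut, consistent with
P(M=1) = 0.998.

Normalization choice: a uniform genotype prior P(g) = 1/4 formally
multiplies the dominant-term likelihood, but the evidence's homozygous
term carries the same dominant-genotype mass without it. Keeping the
factor in the numerator only would cap the posterior at ≈ 1/4 and make
the threshold semantics opaque; the factor therefore cancels between
numerator and evidence, so the posterior approaches 1 for unambiguously
homozygous loci and is clipped to [0, 1]. The standalone
`hom_likelihood` function retains the printed 1/4. The resulting
posterior is an approximation and need not normalize exactly; the
threshold K calibrates it.

A locus is informative iff **all** hold:

| rule | default | rationale |
| --- | --- | --- |
| posterior ≤ K | K = 0.05 | Bayesian filter above |
| c₁ > het_ratio·c₂ | ratio 1.5 | a het site shared by all cells gives c₁ ≈ c₂; subclonal SNVs give skewed counts |
| c₁+c₂+c₃ ≥ min_top3 | 5 | minimum support |
| c − c₁ ≥ min_nonref | 5 | at least 5 non-majority bases |
| coverage within coverage_sd_limit SD of mean | 2 (two-sided) | high-coverage pileup artifacts; mean/SD over the loci present in the current pileup |

Rejections are attributed to the first failing rule in the order:
coverage outlier, min_top3, het ratio, min_nonref, posterior. Filters
are re-run from scratch at every recursion node on that node's cells
only — loci rejected on the full population can become informative on a
subset. All likelihood arithmetic is in log space with `lgamma`
factorials; log-sum-exp accumulation throughout. Tests verify the
log-space pipeline against an exact rational-arithmetic oracle to
10⁻¹⁰ relative error at c up to 500.

## Overlap likelihoods and similarity

Base-pair kernels for two sequenced bases:

    P_ss = (1−θ)² + θ²/3          same underlying base read as same
    P_sd = 1 − P_ss
    P_ds = 2(1−θ)θ/3 + 2θ²/9      different bases read as same
    P_dd = 1 − P_ds

An overlap of two fragments (one per cell) over the shared informative
loci is summarized as (x_s, x_d) matches/mismatches. Under "same
genotype", each position is heterozygous with weight 1 − h − ε/2 or
homozygous-identical with weight h + ε/2; under "different genotypes"
the weights are 1 − h − ε (het), h (hom-identical) and ε (subclonally
mutated, with mixed kernels (P_ss+P_ds)/2 for a match). The two phase
configurations are summed **jointly across all heterozygous positions
of the overlap** with weight ½ each — the coupling that encodes
phasing. Mutated positions are treated per-position (no phase
coupling), a deliberate small-ε approximation. For fixed overlap length
both likelihoods are probability distributions over (x_s, x_d); tests
check normalization up to length 12 and equivalence with a brute-force
enumeration oracle (every assignment of positions to classes × phase ×
outcomes) to 10⁻¹⁰ relative at length ≤ 6.

Parameters (defaults): h = 0.5 (fraction of homozygous loci among
informative positions), ε = 0.01 (fraction of mutated loci), θ = 0.05.
θ is deliberately higher than the platform error rate because the
informative set is enriched for error-carrying positions. ε is the
operative proxy for between-subclone difference prevalence; no separate
prevalence parameter is exposed.

s(i,j) sums the per-overlap log-odds over all fragment pairs of cells
i ≠ j; cell pairs sharing no overlap have s = 0 by definition. Log-odds
values are cached per (x_s, x_d) (table up to 64, computed on demand
beyond). Fragments are the phased unit: mates share a fragment id
(configurable off at ingestion). Multiple fragments of one cell at a
locus form pairs independently — non-independence across a cell's own
overlapping reads is negligible at these coverages. Accumulation order
is fixed (loci in genomic order, fragment ids sorted), making the
matrix bit-reproducible.

## Spectral clustering and recursion

S* = S − min(S) (entrywise shift; the minimum becomes 0 and ordering is
preserved). The symmetric normalized Laplacian L = I − D^{−1/2} S*
D^{−1/2} is formed with degree regularization d + 10⁻¹² (cells with an
all-zero row otherwise have no degree), and the k = 6 eigenvectors of
the smallest eigenvalues embed the cells; eigenvector signs are fixed
by making each vector's largest-magnitude entry positive. All six
eigenvectors (including the near-trivial first) feed both k-means and
the mixture model.

Number of clusters: k-means (10 seeded restarts, greedy k-means++) for
k = 1..4 gives inertias i₁..i₄ and gaps g_k = i_{k−1} − i_k, g₁ := 0.
k grows from 2 while each g_k > 0.75·g_{k−1}; the largest k whose whole
chain of conditions holds is chosen. The sequential (elbow) form
matters: once gains flatten after a clean 2-way structure, g₃ fails its
test but g₄ ≈ g₃ would pass *its own* test, so selecting the largest k
satisfying only its own condition would systematically report 4
clusters on 2-cluster data (observed on the benchmark: gaps
0.87/0.37/0.34).

Whether to split at all: Gaussian mixtures with 1–4 diagonal-covariance
components (5 seeded restarts) are compared by BIC; the node becomes a
leaf if one component wins. Guards: nodes with fewer than 10 cells, no
informative loci, or an identically-zero similarity matrix never split
(termination `no_signal` for the latter two). A split is rolled back if
any child has fewer than `min_cluster_cells` (default 500) cells or
mean pooled coverage below 9 — the lowest coverage sufficient for a
reliable variant call. Pooled coverage of a cell group is estimated as
its total quality-passing bases (recorded before monomorphic-locus
pruning) divided by genome length. Nodes smaller than
2·`min_cluster_cells` are marked `too_small` without running the
pipeline, since no acceptable split exists; the leaf partition is
unchanged, only the recorded reason differs from a rolled-back split.
Recursion depth caps at 10.

## Pseudo-bulk variant calling

Per-cluster pooled counts feed a MAQ-style multinomial genotype model
over the 10 unordered diploid genotypes: homozygote gg emits g with
probability 1 − θ_call, others θ_call/3; heterozygote g₁g₂ emits each
of g₁, g₂ with ½ − θ_call/3, others θ_call/3; uniform genotype prior.
θ_call defaults to 0.01 — distinct from the similarity θ = 0.05,
because calling operates on all loci after base-quality filtering, not
on the error-enriched informative subset. Calls require pooled depth
≥ 9; confidence is GQ = −10·log₁₀(1 − posterior), capped at 255.
Variants are called at all pileup loci of the cluster, not only
filter-passing ones (the filter is tuned for clustering). The caller is
a reconstruction from its stated ingredients; its quality model may
differ from other MAQ-derived implementations. Germline handling is an
optional position mask (no matched normal required).

## Synthetic data generator

The generator emulates amplification-free droplet scDNA-seq: a uniform
random reference; germline het sites as per-bp Bernoulli(10⁻³) with
random phase, shared by all cells; a clone tree whose branches add
private SNVs (50/50 gain/loss, losses placed on still-heterozygous
germline sites when available, otherwise converted to gains; positions
never collide across branches); Poisson fragment counts per cell with
expectation coverage·genome/fragment_bases; uniform fragment placement
within chromosome blocks; uniform substitution errors (default 1%);
constant base quality Phred 37 with a configurable 1% of bases at
Phred 10 to exercise quality filtering. One master seed; per-cell
generators are seeded `[seed, 7919, cell_index]`, so any cell is
reproducible in isolation. Two generation paths (full retention for
SAM export; streaming for ~10⁸-observation runs) are tested to produce
identical pileups.

What it does **not** emulate: platform error profiles and quality-score
distributions, GC/mappability bias, chimeric reads, doublets, CNVs,
indels. Passing tests therefore demonstrate the statistical machinery
under the model's own assumptions — correctness of the filter,
similarity, clustering and caller — not robustness to real-data
artifacts such as mapping bias or allele-specific dropout.

## Benchmark scale and scoring

The standard study is two equal clones of 500 cells on a 2 Mb genome,
600 clone-private SNVs, 0.05× per-cell coverage (pooled ≈ 50×), 1%
error — a deliberately scaled-down cohort with pooled coverage and SNV
observability comparable to the regimes where the approach is expected
to succeed; it runs in a few minutes on one CPU within ~5 GB.
Partition scores: predicted clusters are matched one-to-one to true
clones (Hungarian assignment on the contingency table); precision is
the purity of matched clusters, recall the fraction of all cells
recovered by them (both reduce to matched accuracy for equal cluster
counts). Pseudo-bulk SNV recall is measured on heterozygosity-gaining
clone-private SNVs only: a loss reverts a germline het site to the
reference in the tumor, so with germline sites masked it cannot appear
in any cluster's VCF — an intrinsic blind spot of germline-masked
pseudo-bulk calling, not an implementation artifact.

## Known limitations

* In very sparse regimes (tens of informative loci, pooled coverage
  ≲ 20) the Laplacian embedding of a pure-noise similarity matrix is
  heavy-tailed and the BIC stop can prefer a spurious split; artifact
  clusters in low-signal data are a known behavior of this family of
  stopping heuristics. The termination criteria are reliable at the
  benchmark's pooled coverages (≥ ~25).
* The posterior filter is an approximation (dominant-term likelihood,
  four-term evidence); K has no exact probabilistic calibration.
  `calibrate_posterior_threshold` chooses K empirically on a null
  pileup for a requested pass rate (default 10⁻⁴) if a specific
  false-positive rate is needed.
* The similarity model ignores phase coupling at mutated positions and
  treats a cell's own overlapping fragments as independent.
* Chromosomes are coordinate blocks of one axis; inter-chromosomal
  structure (e.g. per-chromosome coverage variation) is not modeled.
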