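# Methods

This note documents the statistical model, the algorithmic choices made
where the construction was genuinely open, the synthetic-data generator and
its limits, and the numerical conventions that make every run bitwise
reproducible.

## Model and statistics

**Observations.** Both methods treat chromosomes as observations: with N
diploid individuals there are n = 2N observations, and each individual's
trait value appears twice (once per haplotype).  This repeated-measures
duplication is deliberate — it is part of the construction being studied —
and is *not* corrected in either statistic.

**Allelic t-test.** At each SNP the n observations are split by allele
(group 1 = minor allele) and compared with the pooled two-sample t
statistic, df = n − 2.  SNPs where either group has fewer than 2
observations are skipped with a warning; detection uses |t|.  No analytic
p-value is attached during detection: the permutation reference is the
primary one, and the analytic t reference is exposed only for the
calibration study below.

**Local phylogeny.** The tree at a focal SNP is estimated from a window of
neighboring SNPs.  The window grows outward from the focal SNP, alternating
nearest-left / nearest-right (left first); a candidate SNP is admitted only
if it passes the four-gamete test against *every* SNP already in the window,
a side closes permanently at its first incompatible candidate, and growth
stops at `max_window` SNPs (default 21, odd so the window can be symmetric).
Under infinite sites, a four-gamete-incompatible pair cannot sit on one
tree, so the window approximates the locally tree-compatible neighborhood.
The tree itself is average-linkage (UPGMA) agglomeration on Hamming
distances between chromosome rows over the window columns, with merge
heights equal to half the average distance.  UPGMA was chosen because it
directly yields the two ingredients the score needs — height-ordered splits
and shared-branch lengths — and because it is exactly testable against a
brute-force replay.  No claim is made that this reproduces any particular
published tree-reconstruction program.

**Clustered tree and covariance.** For a cluster count k, the tree is
reduced to the k clusters below its k − 1 highest (earliest) splits.
Average linkage is monotone, so these are exactly the last k − 1 merges;
among equal heights the later merge counts as the earlier split.  The trait
covariance is proportional to shared ancestry: for chromosomes a ≠ b,
V_ab = (H − h(MRCA(a, b))) / H with h measured from the tips, same-cluster
pairs using their cluster root, and V_aa = 1.  Dividing by the total height
H fixes the proportionality constant left open by the "proportional to
shared lineage length" definition, making σ² the single scale parameter.
A ridge V ← (1 − λ)V + λI with λ = 10⁻⁶ guards against exact singularity
from duplicated haplotypes; it preserves the unit diagonal.

**LSS.** For each k in 2..min(k_max, n − 1) the cluster means and common
variance are estimated by GLS (these are the exact MLEs), and

    LSS = max_k { 2 ln L − k ln n },   ln L = −(n/2) ln 2π − (n/2) ln σ̂² − ½ ln|V| − n/2.

Defaults: k_max = 15, penalty exactly k ln n.  Counting k parameters rather
than k + 1 (for σ²) shifts every candidate by the same constant, so the
argmax over k is unaffected; the convention is kept because it is the
printed form of the statistic.  The grid stops at n − 1 because k = n
saturates the mean structure (σ̂² = 0).  The covariance is rebuilt from the
k-cluster tree at each k, reading the likelihood as L(· | y, V(Θ), Θ) with
Θ the clustered tree.  A consequence worth knowing: the *unpenalized*
2 ln L sequence is then not guaranteed monotone in k (observed dips of
order one log unit on random data), because V changes along with the mean
structure.  With V held fixed the nested sequence is provably monotone, and
the test suite asserts exactly that version; the per-k-V dips are treated
as a monitored diagnostic, not an error.

**Detection.** The gene statistic is the maximum per-SNP statistic (LSS, or
|t|); the choice of maximum is ours — any region-wise aggregate would do,
and the max is the standard one.  B = 100 permutations shuffle trait values
across *individuals*, re-applying the within-individual duplication
afterwards, so the permuted null preserves the repeated-measures structure;
the same permutation indices are reused across SNPs and across both
methods, pairing the comparison.  p = #(permuted ≥ observed)/B, ties count
as extreme, no +1 correction — so p = 0.00 is possible and p has
granularity 1/B.

**Localization.** Profiles average the per-SNP statistic over trait
replicates (|t| in absolute value, LSS as-is).  Two scalar surrogates make
the visual comparison testable: `localization_error`, the bp distance from
the profile argmax (ties → smallest position) to the nearest causal SNP,
invariant under monotone transforms of the statistic; and `smoothness`, the
mean |adjacent difference| after dividing the profile by its population
standard deviation, which puts the two methods' scales on a common footing.
SNPs skipped by a method drop out of its adjacency chain.

## Synthetic data

The generator produces exactly the features the two methods exploit and
nothing more:

- **Genealogies**: Kingman coalescent per block (j lineages merge at rate
  j(j−1)/2), checked in expectation against E[TMRCA] = 2(1 − 1/n) and
  Watterson's E[total length] = 2Σ_{i<n} 1/i.
- **Mutations**: infinite sites; count ~ Poisson(θ/2 × total length), each
  on a branch chosen by length; every column is polymorphic and E[S] = θ a_{n−1}.
- **Recombination proxy**: `n_blocks` fully independent genealogies with
  evenly spaced bp positions inside `block_span_bp` each.  This preserves
  local tree structure and decaying cross-block LD at a fraction of the
  complexity of an ancestral recombination graph — but it makes LD
  *piecewise constant*: there is no within-block decay and no partial
  sharing across block boundaries.
- **Diploids**: consecutive chromosomes pair into individuals; no
  inbreeding, no relatedness between individuals.  Genotypes are therefore
  in Hardy–Weinberg proportions up to hypergeometric sampling noise —
  see the calibration discussion below, because this matters.
- **Traits**: y_i = Σ_s β_s g_is + ε_i with g the minor-allele count and
  ε ~ N(0, noise_sd²); an empty effect map is the null trait.

Defaults define the calibration study conditions: 150 individuals, 3 blocks
of 50 kb, θ = 1.5 per block (≈ 30 polymorphic SNPs in total), noise_sd = 5.
The effect-magnitude menu for power studies is
{0.76, 3.38, 3.89, 10.89, 11.99}; with noise_sd = 5 the weakest effect on a
common SNP explains < 1 % of trait variance (0.76² × 2pq ≈ 0.23 vs. total
≈ 25.2), placing it firmly in the weak-signal regime, while the largest
effects are overwhelming — the menu spans both regimes.

What passing tests on this generator do **not** show: behavior under real
LD decay, under population structure or cryptic relatedness, under
Hardy–Weinberg departure, with covariates, or with genotyping error —
none of which the generator emulates.

## Calibration findings

Study sizes (chosen once, as the package's own desk-scale conditions):
type-I-error calibration uses the default gene with R = 200 null replicates
and B = 100 permutations; the power grid uses a 100-individual, 2-block
gene with R = 100 replicates per effect size; smoothness uses 20 replicate
sets of 10 traits each.

- The permutation-based LSS detection test calibrates at or below the
  nominal 0.05 (it tends to run conservative), and the permutation-based
  t-test calibrates as well — permutation fixes the reference distribution
  regardless of the statistic.
- Referencing the allelic |t| against the **analytic** t distribution on
  duplicated observations is a different story, and a more subtle one than
  "duplication inflates the test".  Duplication has two opposing
  finite-sample effects.  Minor alleles concentrated in *homozygotes* give
  the minor group twice the weight the denominator accounts for: var(t)
  inflates strongly (a constructed SNP with all minor alleles in
  homozygotes shows var(t) ≈ 2).  Minor alleles carried by *heterozygotes*
  put the same trait value in both groups, shrinking the difference:
  var(t) deflates.  Under Hardy–Weinberg proportions the two effects cancel
  asymptotically, and on this generator — which is in HWE by construction,
  with a coalescent site-frequency spectrum dominated by het-carried rare
  variants — the aggregate per-SNP rejection rate at the 0.05 level comes
  out slightly *below* 0.05 (≈ 0.042–0.046 across seeds), even though the
  aggregate var(t) sits slightly above the nominal df/(df − 2).  Allelic-
  test inflation of the kind reported on real sequence data therefore
  requires Hardy–Weinberg departure (structure, inbreeding, imputation
  artifacts), which this generator deliberately does not produce.  The test
  suite pins both mechanisms with constructed genotype configurations and
  asserts the aggregate claim as stated, which on this generator fails —
  kept failing on purpose, as an honest record of the finding.

## Numerical conventions

- One RNG stream per purpose (haplotypes, traits, permutations), all
  spawned from the single master seed; changing B never changes simulated
  data, and every output is bitwise reproducible under a fixed seed.
- UPGMA tracks cross-cluster distance *sums* (exact integers for Hamming
  input) and divides once, so tied averages compare exactly; ties merge the
  lexicographically lowest cluster-id pair.  Equal heights at the cluster
  cut resolve by merge order (later merge = earlier split).
- GLS solves V⁻¹-products through one Cholesky factorization per (tree, k)
  (ln|V| from the same factor, no explicit inverse).  Within a gene, trees
  are cached across SNPs sharing a window, and all trait columns
  (replicates × permutations) are scored in one batched solve per
  (tree, k).
- Degenerate cases: constant traits raise a degenerate-trait error;
  zero-height trees raise a degenerate-tree error; t-test groups smaller
  than 2 observations skip the SNP with a warning; multiallelic VCF records
  are skipped with a warning; unphased or missing genotypes are hard errors
  (phasing/imputation is upstream of this package).
- MAF ties at exactly 0.5 keep the original ALT coding — an arbitrary but
  documented and deterministic rule.

## Known limitations

- The local-tree estimator (window + UPGMA) is a design choice, not a
  likelihood-based phylogeny; its parameters (`max_window = 21`, Hamming
  distance, height normalization) deserve sensitivity analysis before any
  fidelity claim about a specific published tree method.
- The LSS's broad-scale clustering makes it weak on rare causal variants:
  a small carrier clade may not surface among the k − 1 deepest splits at
  useful k, while the allelic t-test sees such variants directly.  The
  worked power numbers use a common causal SNP for exactly this reason.
- No covariates, no Welch variant, no genotype-level (0/1/2) regression,
  no multiple-testing correction across genes: scope is the per-gene
  comparison of the two constructions as defined.
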