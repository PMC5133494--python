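# treescan

Quantitative-trait association mapping with and without local phylogenies:
a reusable pipeline comparing a **tree-based likelihood score statistic
(LSS)** against the classical **allelic pooled t-test**, with a
coalescent-style simulator for calibrated synthetic experiments.

## The problem

Quantitative trait mapping (QTM) asks two questions about a gene region
typed at many biallelic SNPs in a population sample: *detection* (is the
region associated with the trait at all?) and *localization* (which SNP is
closest to the causal one?).  Classical single-SNP tests treat individuals
(or chromosomes) as exchangeable and can miss weak signals, because randomly
sampled chromosomes are not exchangeable: at every SNP they are related by a
genealogy, and a causal SNP imprints that genealogy's structure on the trait
— two chromosomes that share most of their evolutionary history should show
strongly correlated trait values.

`treescan` implements both ends of this trade-off for phased haplotype data:

- **Allelic t-test** — at each SNP, the per-chromosome trait observations
  (each individual's value appears twice, so n = 2 × individuals) are split
  by minor/major allele and compared with a pooled two-sample t statistic.
- **LSS** — at each SNP a local phylogeny Θ of all chromosomes is estimated
  from the neighboring SNPs (four-gamete-compatible window, UPGMA on Hamming
  distances), reduced to its k broad-scale clusters (the k − 1 deepest
  splits), and the trait is modeled as

  y ~ N(Xμ, σ²V(Θ)),  V_ab = (H − h(MRCA(a, b))) / H,

  where X assigns one mean per cluster and V has unit diagonal.  With
  μ̂, σ̂² the (GLS / maximum-likelihood) estimates, the per-SNP score is the
  BIC-penalized profile likelihood maximized over the cluster count:

  LSS_i = max_{k = 2..k_max} { 2 ln L(μ̂, σ̂² | y, V(Θ), Θ) − k ln n },  k_max = 15.

Gene-level detection for either method takes the maximum per-SNP statistic
and references it against 100 trait permutations (shuffled across
individuals, keeping each individual's duplication across its two
chromosomes); the p-value is the fraction of permutations at least as
extreme.  Localization is read off per-SNP profiles averaged over trait
replicates.

Who is this for: statistical geneticists comparing region-based association
strategies, and method developers who need a small, fully reproducible
test bed — every experiment here runs on simulated phased haplotypes
(independent Kingman-coalescent blocks with infinite-sites mutations,
additive traits with Gaussian noise) with one master seed.

## Worked example

Simulate one gene region (150 diploid individuals, three 50-kb blocks,
~38 SNPs) with a single common causal SNP of effect size |β| = 10.89 on a
noise SD of 5, then run detection and localization:

```bash
cat > gene.yaml <<EOF
seed: 42
n_individuals: 150
n_blocks: 3
theta: 1.5
block_span_bp: 50000
noise_sd: 5.0
effect_map:
  - [18, 10.89]
EOF

treescan simulate --config gene.yaml --out-dir sim
# wrote 38 SNPs x 300 chromosomes to sim

treescan detect --vcf sim/haplotypes.vcf --trait sim/trait.tsv \
    --regions sim/regions.tsv --flank-bp 0 --permutations 100 --seed 7 \
    --out detection.tsv
# gene    lss     p=0.000
# gene    ttest   p=0.000

treescan localize --config gene.yaml --replicates 20 --out profile.tsv
# smoothness: lss=0.1232 abs_t=0.7875
```

Both methods detect the planted signal: the observed gene statistics
(max over SNPs) are LSS = −2165.90 and |t| = 12.62, and none of the 100
permuted datasets reaches them, so both permutation p-values are 0.00.
The localization profile (`profile.tsv`) shows the mean |t| peaking exactly
at the causal SNP (mean |t| = 13.41 at position 81818, true |β| = 10.89),
while the mean LSS forms a plateau over the 10 SNPs whose local trees share
the causal block — SNPs sharing a compatibility window share a tree, hence
a score.  That plateau structure is what the smoothness numbers quantify:
the standardized adjacent-SNP variability of the LSS profile (0.12) is far
below that of the |t| profile (0.79), the expected behavior of a statistic
that borrows strength from neighboring SNPs.

Power / type-I-error tables over trait replicates
(`treescan power --config ... --replicates 200`) and full per-SNP scans with
Newick tree export (`treescan scan ... --emit-newick`) follow the same
pattern; see `--help` on each subcommand.

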