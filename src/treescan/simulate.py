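"""Coalescent-style synthetic data: haplotypes with local tree structure and traits.

The generator emulates the study design the analysis methods assume: phased
0/1 haplotypes whose columns share a genealogy locally (independent Kingman
coalescent blocks with infinite-sites mutations, a crude stand-in for
recombination), diploid individuals formed by pairing consecutive
chromosomes, and quantitative traits that are additive in minor-allele
counts plus Gaussian noise.  An empty effect map yields a null trait with no
genotype-phenotype association.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import HaplotypeMatrix, TraitVector
from .errors import InvalidArgumentError

__all__ = [
    "Genealogy",
    "SimulationConfig",
    "simulate_genealogy",
    "drop_mutations",
    "simulate_haplotypes",
    "simulate_trait",
    "expand_observations",
    "choose_causal_snp",
    "rng_streams",
]

#: Effect magnitudes spanning the strong/weak-signal regimes exercised by the
#: power harness (largest to smallest).
EFFECT_SIZE_MENU: tuple[float, ...] = (0.76, 3.38, 3.89, 10.89, 11.99)


@dataclass(frozen=True)
class Genealogy:
    """A binary genealogy over ``n_tips`` chromosomes.

    Tips are node ids ``0 .. n_tips - 1``; the ``j``-th merge event creates
    internal node ``n_tips + j`` at coalescent time ``times[j]`` by joining
    the two lineages whose current root node ids are ``children[j]``.
    """

    n_tips: int
    children: np.ndarray  # (n_tips - 1, 2) node ids
    times: np.ndarray  # (n_tips - 1,) strictly increasing merge times

    def __post_init__(self) -> None:
        children = np.asarray(self.children, dtype=np.int64)
        times = np.asarray(self.times, dtype=np.float64)
        object.__setattr__(self, "children", children)
        object.__setattr__(self, "times", times)
        m = self.n_tips - 1
        if children.shape != (m, 2) or times.shape != (m,):
            raise InvalidArgumentError("genealogy needs exactly n_tips - 1 merge events")
        if m > 1 and not np.all(np.diff(times) > 0):
            raise InvalidArgumentError("merge times must be strictly increasing")

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    def node_times(self) -> np.ndarray:
        """Time of every node (tips at 0), length ``2 n_tips - 1``."""
        return np.concatenate([np.zeros(self.n_tips), self.times])

    def parents(self) -> np.ndarray:
        """Parent node id per node; the root maps to -1."""
        parent = np.full(self.n_nodes, -1, dtype=np.int64)
        for j, (a, b) in enumerate(self.children):
            parent[a] = self.n_tips + j
            parent[b] = self.n_tips + j
        return parent

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (0 for the root)."""
        t = self.node_times()
        parent = self.parents()
        lengths = np.zeros(self.n_nodes)
        non_root = parent >= 0
        lengths[non_root] = t[parent[non_root]] - t[non_root]
        return lengths

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    @property
    def tmrca(self) -> float:
        return float(self.times[-1])

    def tip_sets(self) -> np.ndarray:
        """Boolean matrix ``(n_nodes, n_tips)``: tips below each node."""
        below = np.zeros((self.n_nodes, self.n_tips), dtype=bool)
        below[np.arange(self.n_tips), np.arange(self.n_tips)] = True
        for j, (a, b) in enumerate(self.children):
            below[self.n_tips + j] = below[a] | below[b]
        return below


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic gene region.

    Defaults describe the calibration gene used throughout: 150 diploid
    individuals, three independent-genealogy blocks of 50 kb with
    per-block mutation parameter ``theta = 1.5`` (roughly 30 polymorphic
    SNPs in total), and trait noise ``noise_sd = 5.0`` chosen so that the
    weakest menu effect (|beta| = 0.76) explains under 1 % of the trait
    variance.
    """

    seed: int
    n_individuals: int = 150
    n_blocks: int = 3
    theta: float = 1.5
    block_span_bp: int = 50_000
    effect_map: tuple[tuple[int, float], ...] = ()
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_map", tuple((int(i), float(b)) for i, b in self.effect_map))
        if self.n_individuals < 2:
            raise InvalidArgumentError("n_individuals must be >= 2")
        if self.n_blocks < 1:
            raise InvalidArgumentError("n_blocks must be >= 1")
        if self.theta <= 0:
            raise InvalidArgumentError("theta must be > 0")
        if self.block_span_bp < 1:
            raise InvalidArgumentError("block_span_bp must be >= 1")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")


def rng_streams(seed: int) -> tuple[np.random.SeedSequence, np.random.SeedSequence, np.random.SeedSequence]:
    """Independent seed streams (haplotypes, traits, permutations) from one master seed.

    Keeping one stream per purpose guarantees that, e.g., changing the number
    of permutations never changes the simulated haplotypes.
    """
    root = np.random.SeedSequence(seed)
    hap_ss, trait_ss, perm_ss = root.spawn(3)
    return hap_ss, trait_ss, perm_ss


def simulate_genealogy(n_tips: int, rng: np.random.Generator) -> Genealogy:
    """Draw a Kingman-coalescent genealogy over ``n_tips`` chromosomes.

    While ``j`` lineages remain, the waiting time to the next merge is
    Exponential with rate ``j (j - 1) / 2`` (time in coalescent units) and a
    uniformly chosen pair of lineages merges.
    """
    if n_tips < 2:
        raise InvalidArgumentError("a genealogy needs at least 2 tips")
    active = list(range(n_tips))
    children = np.empty((n_tips - 1, 2), dtype=np.int64)
    times = np.empty(n_tips - 1)
    t = 0.0
    for step, j in enumerate(range(n_tips, 1, -1)):
        t += rng.exponential(2.0 / (j * (j - 1)))
        ia, ib = rng.choice(j, size=2, replace=False)
        a, b = active[ia], active[ib]
        children[step] = sorted((a, b))
        times[step] = t
        new = n_tips + step
        # remove the higher index first so the lower one stays valid
        for idx in sorted((ia, ib), reverse=True):
            del active[idx]
        active.append(new)
    return Genealogy(n_tips=n_tips, children=children, times=times)


def drop_mutations(genealogy: Genealogy, theta: float, rng: np.random.Generator) -> list[np.ndarray]:
    """Place infinite-sites mutations on a genealogy.

    The mutation count is Poisson(``theta / 2`` x total branch length); each
    mutation falls on a branch chosen proportionally to its length and flips
    the allele of every tip below it.  Every emitted column is polymorphic
    because the root branch carries no mutations.
    """
    if theta <= 0:
        raise InvalidArgumentError("theta must be > 0")
    lengths = genealogy.branch_lengths()
    total = lengths.sum()
    n_mut = int(rng.poisson(theta / 2.0 * total))
    if n_mut == 0:
        return []
    probs = lengths / total
    branch_nodes = rng.choice(genealogy.n_nodes, size=n_mut, p=probs)
    below = genealogy.tip_sets()
    return [below[node].astype(np.uint8) for node in branch_nodes]


def _block_positions(n_snps: int, block_index: int, span: int) -> np.ndarray:
    """Evenly spaced 1-based positions inside block ``block_index``."""
    offsets = np.floor(np.arange(1, n_snps + 1) * span / (n_snps + 1)).astype(np.int64)
    offsets = np.maximum(offsets, 1)
    positions = block_index * span + offsets
    if np.unique(positions).size != n_snps:
        raise InvalidArgumentError(
            f"block span {span} bp too small for {n_snps} SNPs; increase block_span_bp"
        )
    return positions


def simulate_haplotypes(config: SimulationConfig) -> HaplotypeMatrix:
    """Generate phased haplotypes: independent genealogy + mutation blocks.

    Rows ``2i`` and ``2i + 1`` form individual ``i``.  Block independence is
    a deliberately crude recombination proxy: it preserves the one property
    the downstream methods exploit (tree-structured correlation locally,
    decaying linkage across blocks).
    """
    hap_ss, _, _ = rng_streams(config.seed)
    rng = np.random.default_rng(hap_ss)
    n_chrom = 2 * config.n_individuals
    columns: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    for b in range(config.n_blocks):
        genealogy = simulate_genealogy(n_chrom, rng)
        cols = drop_mutations(genealogy, config.theta, rng)
        if not cols:
            continue
        columns.extend(cols)
        positions.append(_block_positions(len(cols), b, config.block_span_bp))
    if columns:
        entries = np.column_stack(columns)
        pos = np.concatenate(positions)
    else:
        entries = np.zeros((n_chrom, 0), dtype=np.uint8)
        pos = np.zeros(0, dtype=np.int64)
    individual_ids = tuple(f"ind{i:04d}" for i in range(config.n_individuals))
    snp_ids = tuple(f"snp_{p}" for p in pos)
    return HaplotypeMatrix(
        entries=entries,
        positions=pos,
        snp_ids=snp_ids,
        individual_ids=individual_ids,
        chrom="1",
    )


def _minor_genotypes(haps: HaplotypeMatrix) -> np.ndarray:
    """Per-individual minor-allele counts (ties at frequency 0.5 keep allele 1)."""
    freq = haps.entries.mean(axis=0)
    flip = freq > 0.5
    entries = np.where(flip[None, :], 1 - haps.entries, haps.entries)
    return entries[0::2].astype(np.int64) + entries[1::2]


def simulate_trait(
    haps: HaplotypeMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TraitVector:
    """Draw a trait: additive minor-allele effects plus Gaussian noise.

    ``value_i = sum_s beta_s g_is + eps_i`` with ``g`` the minor-allele count
    (0/1/2) and ``eps ~ Normal(0, noise_sd^2)``.  An empty effect map gives a
    pure-noise null trait.
    """
    if rng is None:
        _, trait_ss, _ = rng_streams(config.seed)
        rng = np.random.default_rng(trait_ss)
    n = haps.n_individuals
    values = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else np.zeros(n)
    if config.effect_map:
        g = _minor_genotypes(haps)
        for snp_index, beta in config.effect_map:
            if not 0 <= snp_index < haps.n_snps:
                raise InvalidArgumentError(
                    f"effect_map snp_index {snp_index} out of range for {haps.n_snps} SNPs"
                )
            values = values + beta * g[:, snp_index]
    return TraitVector(values=values, individual_ids=haps.individual_ids)


def expand_observations(trait: TraitVector) -> np.ndarray:
    """Duplicate each individual's trait across its two chromosomes.

    Both methods treat chromosomes as observations, so ``n`` equals twice the
    number of individuals; entries ``2i`` and ``2i + 1`` both carry trait
    value ``i``, matching the haplotype row order.
    """
    return np.repeat(trait.values, 2)


def choose_causal_snp(haps: HaplotypeMatrix, min_maf: float = 0.1) -> int:
    """Pick the most central SNP with minor-allele frequency >= ``min_maf``.

    Used by the power harness so that the planted effect sits on a SNP common
    enough for its signal to be expressible; deterministic given the matrix.
    """
    if haps.n_snps == 0:
        raise InvalidArgumentError("empty haplotype matrix")
    freq = haps.entries.mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    eligible = np.flatnonzero(maf >= min_maf)
    if eligible.size == 0:
        eligible = np.array([int(np.argmax(maf))])
    center = (haps.positions[0] + haps.positions[-1]) / 2.0
    return int(eligible[np.argmin(np.abs(haps.positions[eligible] - center))])
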