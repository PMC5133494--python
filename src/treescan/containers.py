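"""Core in-memory containers shared across the pipeline.

The genotypic substrate is a phased binary haplotype matrix: one row per
chromosome (two consecutive rows per diploid individual), one column per
biallelic SNP, entries coded 0/1 with 1 conventionally the minor allele
after :func:`treescan.io.recode_minor`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["HaplotypeMatrix", "GeneRegion", "TraitVector"]


@dataclass(frozen=True)
class HaplotypeMatrix:
    """Phased binary haplotypes over a genomic region.

    Parameters
    ----------
    entries
        ``(2N, S)`` array in {0, 1}; rows ``2i`` and ``2i + 1`` are the two
        chromosomes of individual ``i``.
    positions
        1-based bp positions, strictly increasing, one per SNP column.
    snp_ids, individual_ids
        Identifiers; ``len(individual_ids) == entries.shape[0] // 2``.
    chrom
        Chromosome label shared by all SNPs in the matrix.
    """

    entries: np.ndarray
    positions: np.ndarray
    snp_ids: tuple[str, ...]
    individual_ids: tuple[str, ...]
    chrom: str = "1"

    def __post_init__(self) -> None:
        entries = np.ascontiguousarray(np.asarray(self.entries, dtype=np.uint8))
        positions = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        object.__setattr__(self, "individual_ids", tuple(self.individual_ids))
        if entries.ndim != 2:
            raise InvalidArgumentError("entries must be a 2-D matrix")
        n_rows, n_snps = entries.shape
        if n_rows % 2 != 0:
            raise InvalidArgumentError("row count must be even (two chromosomes per individual)")
        if entries.size and entries.max() > 1:
            raise InvalidArgumentError("entries must be binary 0/1")
        if positions.shape != (n_snps,):
            raise InvalidArgumentError("positions must have one entry per SNP column")
        if n_snps > 1 and not np.all(np.diff(positions) > 0):
            raise InvalidArgumentError("positions must be strictly increasing")
        if len(self.snp_ids) != n_snps:
            raise InvalidArgumentError("snp_ids must have one entry per SNP column")
        if len(self.individual_ids) != n_rows // 2:
            raise InvalidArgumentError("individual_ids must have one entry per two rows")

    @property
    def n_chromosomes(self) -> int:
        return self.entries.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.entries.shape[0] // 2

    @property
    def n_snps(self) -> int:
        return self.entries.shape[1]

    def genotypes(self) -> np.ndarray:
        """Per-individual allele-1 counts, shape ``(N, S)`` with values 0/1/2."""
        return (self.entries[0::2].astype(np.int64) + self.entries[1::2]).astype(np.int64)

    def chromosome_ids(self) -> tuple[str, ...]:
        """Row labels ``<individual>_<1|2>`` matching the entry rows."""
        out = []
        for ind in self.individual_ids:
            out.append(f"{ind}_1")
            out.append(f"{ind}_2")
        return tuple(out)


@dataclass(frozen=True)
class GeneRegion:
    """A named gene interval with symmetric flanks.

    Coordinates are 1-based and fully inclusive; the analyzed window is
    ``[start_bp - flank_bp, end_bp + flank_bp]``.
    """

    name: str
    chrom: str
    start_bp: int
    end_bp: int
    flank_bp: int = 100_000

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise InvalidArgumentError(f"region {self.name}: start_bp > end_bp")
        if self.flank_bp < 0:
            raise InvalidArgumentError(f"region {self.name}: flank_bp must be >= 0")

    @property
    def lo(self) -> int:
        return self.start_bp - self.flank_bp

    @property
    def hi(self) -> int:
        return self.end_bp + self.flank_bp


@dataclass(frozen=True)
class TraitVector:
    """One quantitative trait value per individual."""

    values: np.ndarray
    individual_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "individual_ids", tuple(self.individual_ids))
        if values.ndim != 1:
            raise InvalidArgumentError("trait values must be 1-D")
        if len(self.individual_ids) != values.shape[0]:
            raise InvalidArgumentError("one individual id per trait value required")
        if values.size and not np.all(np.isfinite(values)):
            raise InvalidArgumentError("trait values must be finite")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]
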