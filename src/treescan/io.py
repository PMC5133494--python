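"""Reading and writing genotypes, traits and gene regions.

Supported formats: VCF 4.x with phased GT fields (read via cyvcf2), a plain
TSV haplotype-matrix format (rows = chromosomes, header = SNP ids), a
two-column trait TSV and a BED-like region table.  Phasing and imputation
are upstream concerns: unphased or missing genotypes are hard errors, and
multiallelic sites are skipped with a logged warning because both analysis
methods are defined for biallelic SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GeneRegion, HaplotypeMatrix, TraitVector
from .errors import EmptyRegionError, InvalidArgumentError, UnsupportedInputError

logger = logging.getLogger(__name__)

__all__ = [
    "read_vcf_region",
    "write_vcf",
    "read_haplotype_tsv",
    "write_haplotype_tsv",
    "read_trait_table",
    "write_trait_table",
    "read_region_table",
    "filter_monomorphic",
    "recode_minor",
]


def read_vcf_region(path: str | Path, region: GeneRegion) -> HaplotypeMatrix:
    """Extract phased biallelic SNPs inside a flanked gene region.

    SNPs with 1-based position in ``[start_bp - flank_bp, end_bp + flank_bp]``
    (both ends inclusive) are returned, two rows per sample in sample order
    (first then second haplotype).

    Raises
    ------
    UnsupportedInputError
        On unphased ("/") or missing genotypes.
    EmptyRegionError
        If no SNP falls inside the region.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n_chrom = 2 * len(samples)
    columns: list[np.ndarray] = []
    positions: list[int] = []
    snp_ids: list[str] = []
    for variant in vcf:
        if variant.CHROM != region.chrom:
            continue
        pos = variant.POS
        if pos < region.lo or pos > region.hi:
            continue
        if len(variant.ALT) != 1:
            logger.warning(
                "skipping multiallelic site %s:%d (%s -> %s)",
                variant.CHROM, pos, variant.REF, ",".join(variant.ALT),
            )
            continue
        col = np.empty(n_chrom, dtype=np.uint8)
        for s, gt in enumerate(variant.genotypes):
            a, b, phased = gt[0], gt[1], gt[-1]
            if a < 0 or b < 0:
                raise UnsupportedInputError(
                    f"missing genotype at {variant.CHROM}:{pos} for sample {samples[s]}"
                )
            if not phased:
                raise UnsupportedInputError(
                    f"unphased genotype at {variant.CHROM}:{pos} for sample {samples[s]}"
                )
            col[2 * s] = a
            col[2 * s + 1] = b
        columns.append(col)
        positions.append(pos)
        snp_ids.append(variant.ID if variant.ID not in (None, ".") else f"snp_{pos}")
    if not columns:
        raise EmptyRegionError(f"no SNPs in region {region.name} [{region.lo}, {region.hi}]")
    order = np.argsort(np.asarray(positions), kind="stable")
    return HaplotypeMatrix(
        entries=np.column_stack([columns[i] for i in order]),
        positions=np.asarray(positions)[order],
        snp_ids=tuple(snp_ids[i] for i in order),
        individual_ids=tuple(samples),
        chrom=region.chrom,
    )


def write_vcf(haps: HaplotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with phased GT fields (REF=A, ALT=T)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=treescan\n")
        max_pos = int(haps.positions[-1]) + 1 if haps.n_snps else 1
        fh.write(f"##contig=<ID={haps.chrom},length={max_pos}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(haps.individual_ids)
            + "\n"
        )
        for j in range(haps.n_snps):
            col = haps.entries[:, j]
            gts = "\t".join(f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(haps.n_individuals))
            fh.write(
                f"{haps.chrom}\t{haps.positions[j]}\t{haps.snp_ids[j]}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_haplotype_tsv(haps: HaplotypeMatrix, path: str | Path) -> None:
    """Write the TSV haplotype format: two '#' metadata lines, then a matrix
    with chromosome row labels and SNP-id columns."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#chrom\t{haps.chrom}\n")
        fh.write("#positions\t" + "\t".join(str(p) for p in haps.positions) + "\n")
        fh.write("chromosome\t" + "\t".join(haps.snp_ids) + "\n")
        for r, label in enumerate(haps.chromosome_ids()):
            fh.write(label + "\t" + "\t".join(str(v) for v in haps.entries[r]) + "\n")


def read_haplotype_tsv(path: str | Path) -> HaplotypeMatrix:
    """Read the TSV haplotype format written by :func:`write_haplotype_tsv`."""
    path = Path(path)
    with path.open() as fh:
        lines = [line.rstrip("\n") for line in fh if line.strip()]
    if len(lines) < 4 or not lines[0].startswith("#chrom") or not lines[1].startswith("#positions"):
        raise UnsupportedInputError(f"{path} is not a treescan haplotype TSV")
    chrom = lines[0].split("\t")[1]
    positions = np.asarray([int(x) for x in lines[1].split("\t")[1:]], dtype=np.int64)
    snp_ids = tuple(lines[2].split("\t")[1:])
    labels: list[str] = []
    rows: list[list[int]] = []
    for line in lines[3:]:
        fields = line.split("\t")
        labels.append(fields[0])
        rows.append([int(x) for x in fields[1:]])
    individual_ids = []
    for i in range(0, len(labels), 2):
        base = labels[i].rsplit("_", 1)[0]
        individual_ids.append(base)
    return HaplotypeMatrix(
        entries=np.asarray(rows, dtype=np.uint8),
        positions=positions,
        snp_ids=snp_ids,
        individual_ids=tuple(individual_ids),
        chrom=chrom,
    )


def filter_monomorphic(haps: HaplotypeMatrix) -> HaplotypeMatrix:
    """Drop SNPs lacking 2 or more variants across samples (monomorphic columns).

    Column order is preserved.  Raises :class:`EmptyRegionError` if nothing
    survives.
    """
    counts = haps.entries.sum(axis=0)
    keep = (counts > 0) & (counts < haps.n_chromosomes)
    if not keep.any():
        raise EmptyRegionError("all SNPs monomorphic after filtering")
    if keep.all():
        return haps
    idx = np.flatnonzero(keep)
    return replace(
        haps,
        entries=haps.entries[:, idx],
        positions=haps.positions[idx],
        snp_ids=tuple(haps.snp_ids[i] for i in idx),
    )


def recode_minor(haps: HaplotypeMatrix) -> HaplotypeMatrix:
    """Orient every column so allele 1 is the minor allele.

    Columns with allele-1 frequency above 0.5 are complemented; a frequency
    of exactly 0.5 keeps the original (ALT) coding, a deterministic tie rule.
    """
    freq = haps.entries.mean(axis=0)
    flip = freq > 0.5
    if not flip.any():
        return haps
    entries = np.where(flip[None, :], 1 - haps.entries, haps.entries).astype(np.uint8)
    return replace(haps, entries=entries)


def write_trait_table(trait: TraitVector, path: str | Path) -> None:
    """Write a two-column TSV: individual_id, value."""
    pd.DataFrame(
        {"individual_id": list(trait.individual_ids), "value": trait.values}
    ).to_csv(path, sep="\t", index=False)


def read_trait_table(path: str | Path, individual_ids: tuple[str, ...] | None = None) -> TraitVector:
    """Read a trait TSV, reordering rows to match ``individual_ids`` if given.

    Raises :class:`InvalidArgumentError` on unknown or missing individuals or
    non-finite values.
    """
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    if "individual_id" not in df.columns or "value" not in df.columns:
        raise InvalidArgumentError(f"{path}: expected columns individual_id, value")
    if df["individual_id"].duplicated().any():
        dup = df["individual_id"][df["individual_id"].duplicated()].iloc[0]
        raise InvalidArgumentError(f"duplicate individual id {dup!r} in trait table")
    if df["value"].isna().any():
        missing = df.loc[df["value"].isna(), "individual_id"].iloc[0]
        raise InvalidArgumentError(f"missing trait value for individual {missing!r}")
    if individual_ids is None:
        ordered = df
    else:
        table = df.set_index("individual_id")
        extra = set(table.index) - set(individual_ids)
        if extra:
            raise InvalidArgumentError(f"trait table has unknown individual(s): {sorted(extra)}")
        unknown = set(individual_ids) - set(table.index)
        if unknown:
            raise InvalidArgumentError(f"trait table lacks individual(s): {sorted(unknown)}")
        ordered = table.loc[list(individual_ids)].reset_index()
    return TraitVector(
        values=ordered["value"].to_numpy(dtype=np.float64),
        individual_ids=tuple(ordered["individual_id"]),
    )


def read_region_table(path: str | Path, flank_bp: int = 100_000) -> list[GeneRegion]:
    """Read a BED-like region table with columns name, chrom, start, end."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "name": str})
    required = {"name", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise InvalidArgumentError(f"{path}: expected columns {sorted(required)}")
    return [
        GeneRegion(
            name=row["name"],
            chrom=row["chrom"],
            start_bp=int(row["start"]),
            end_bp=int(row["end"]),
            flank_bp=flank_bp,
        )
        for _, row in df.iterrows()
    ]
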