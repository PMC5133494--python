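"""Per-gene orchestration: filter -> recode -> trees -> statistics -> detection.

:func:`scan_gene` ties the stages together for one flanked gene region and
writes a reproducible output layout (one directory per gene, stable file
names, a JSON run manifest).  Per-SNP failures (degenerate trait, unstable
t-test) skip the SNP with a logged warning instead of aborting the gene.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import GeneRegion, HaplotypeMatrix, TraitVector
from .detection import detection_pvalues, PermutationResult
from .errors import EmptyRegionError
from .io import filter_monomorphic, read_trait_table, read_vcf_region, recode_minor
from .lss import DEFAULT_K_MAX, LssGeneEngine
from .simulate import expand_observations
from .tree import DEFAULT_MAX_WINDOW, to_newick
from .ttest import allelic_t_matrix

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "GeneScan", "scan_gene"]


@dataclass(frozen=True)
class RunConfig:
    """Settings shared by every gene in a scan."""

    seed: int
    k_max: int = DEFAULT_K_MAX
    max_window: int = DEFAULT_MAX_WINDOW
    B: int = 100
    alpha: float = 0.05
    flank_bp: int = 100_000
    methods: tuple[str, ...] = ("lss", "ttest")
    emit_newick: bool = False
    out_dir: Path | None = None


@dataclass(frozen=True)
class GeneScan:
    """Per-SNP statistics and gene-level detection results for one region."""

    region: GeneRegion
    per_snp: pd.DataFrame
    detection: dict[str, PermutationResult]
    n_snps_before_filter: int
    n_snps_after_filter: int


def scan_gene(
    config: RunConfig,
    region: GeneRegion,
    *,
    vcf_path: str | Path | None = None,
    trait_path: str | Path | None = None,
    haps: HaplotypeMatrix | None = None,
    trait: TraitVector | None = None,
) -> GeneScan:
    """Run the full per-gene pipeline; deterministic under the config seed.

    Inputs may be given as file paths (VCF + trait TSV) or as in-memory
    objects.  Outputs (per-SNP TSV, detection TSV, optional Newick trees,
    manifest) are written under ``out_dir/<region.name>/`` when ``out_dir``
    is set.
    """
    if haps is None:
        if vcf_path is None:
            raise EmptyRegionError("either haps or vcf_path is required")
        haps = read_vcf_region(vcf_path, region)
    n_before = haps.n_snps
    haps = recode_minor(filter_monomorphic(haps))
    logger.info("region %s: %d SNPs before filtering, %d after", region.name, n_before, haps.n_snps)
    if trait is None:
        if trait_path is None:
            raise EmptyRegionError("either trait or trait_path is required")
        trait = read_trait_table(trait_path, haps.individual_ids)

    engine = LssGeneEngine(haps, k_max=config.k_max, max_window=config.max_window)
    y = expand_observations(trait)
    lss_scores, k_star = engine.scores(y, with_k=True)
    t_stats = allelic_t_matrix(y, haps.entries)[:, 0]
    n1 = haps.entries.sum(axis=0).astype(int)
    skipped = np.isnan(t_stats)
    for idx in np.flatnonzero(skipped):
        logger.warning("region %s: SNP %s skipped by the allelic t-test", region.name, haps.snp_ids[idx])
    per_snp = pd.DataFrame(
        {
            "snp_id": haps.snp_ids,
            "position": haps.positions,
            "lss": lss_scores,
            "k_star": k_star,
            "t": t_stats,
            "abs_t": np.abs(t_stats),
            "n1": n1,
            "n0": haps.n_chromosomes - n1,
        }
    )

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    detection = detection_pvalues(
        haps,
        trait,
        config.methods,
        B=config.B,
        rng=rng,
        gene=region.name,
        k_max=config.k_max,
        max_window=config.max_window,
        engine=engine,
    )

    result = GeneScan(
        region=region,
        per_snp=per_snp,
        detection=detection,
        n_snps_before_filter=n_before,
        n_snps_after_filter=haps.n_snps,
    )
    if config.out_dir is not None:
        _write_outputs(config, result, engine, haps)
    return result


def _write_outputs(config: RunConfig, result: GeneScan, engine: LssGeneEngine, haps) -> None:
    gene_dir = Path(config.out_dir) / result.region.name
    gene_dir.mkdir(parents=True, exist_ok=True)
    result.per_snp.to_csv(gene_dir / "per_snp.tsv", sep="\t", index=False)
    rows = [
        {
            "gene": res.gene,
            "method": res.method,
            "observed_stat": res.observed_stat,
            "p_value": res.p_value,
            "B": len(res.permuted_stats),
        }
        for res in result.detection.values()
    ]
    pd.DataFrame(rows).to_csv(gene_dir / "detection.tsv", sep="\t", index=False)
    window_rows = pd.DataFrame(
        {
            "snp_id": haps.snp_ids,
            "position": haps.positions,
            "window_size": [len(w) for w in engine.windows],
            "window_start": [int(haps.positions[w[0]]) for w in engine.windows],
            "window_end": [int(haps.positions[w[-1]]) for w in engine.windows],
        }
    )
    window_rows.to_csv(gene_dir / "windows.tsv", sep="\t", index=False)
    if config.emit_newick:
        tree_dir = gene_dir / "trees"
        tree_dir.mkdir(exist_ok=True)
        for s, t_idx in enumerate(engine.tree_of_snp):
            (tree_dir / f"{haps.snp_ids[s]}.nwk").write_text(to_newick(engine.trees[t_idx]) + "\n")
    manifest = {
        "treescan_version": __version__,
        "region": asdict(result.region),
        "seed": config.seed,
        "k_max": config.k_max,
        "max_window": config.max_window,
        "B": config.B,
        "alpha": config.alpha,
        "flank_bp": config.flank_bp,
        "methods": list(config.methods),
        "n_snps_before_filter": result.n_snps_before_filter,
        "n_snps_after_filter": result.n_snps_after_filter,
    }
    (gene_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
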