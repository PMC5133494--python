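"""Localization: per-SNP statistic profiles against true effect sizes.

The profile averages each method's per-SNP statistic over trait replicates
(|t| is averaged in absolute value, the LSS as-is) and records the true
|beta| at each SNP.  Two scalar surrogates make the visual comparison
testable: ``localization_error`` (bp distance from the profile peak to the
nearest causal SNP) and ``smoothness`` (mean absolute difference between
adjacent SNPs after standardizing the profile to unit variance, so methods
on different scales are comparable).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .lss import DEFAULT_K_MAX, LssGeneEngine
from .simulate import SimulationConfig, expand_observations, rng_streams, simulate_trait
from .tree import DEFAULT_MAX_WINDOW
from .ttest import allelic_t_matrix

__all__ = ["profile", "localization_error", "smoothness", "replicate_profiles"]


def profile(
    stats_per_replicate: np.ndarray,
    positions: np.ndarray,
    truth: tuple[tuple[int, float], ...] = (),
    *,
    take_abs: bool = False,
) -> pd.DataFrame:
    """Average a replicate x SNP statistic matrix into a per-SNP profile.

    ``truth`` maps SNP indices to effect sizes; non-causal SNPs get
    ``true_abs_beta = 0``.  Set ``take_abs`` for t statistics so the average
    is over |t|.
    """
    stats = np.asarray(stats_per_replicate, dtype=np.float64)
    if stats.ndim == 1:
        stats = stats[None, :]
    positions = np.asarray(positions, dtype=np.int64)
    if stats.shape[1] != positions.shape[0]:
        raise InvalidArgumentError("statistic matrix and positions disagree on SNP count")
    if take_abs:
        stats = np.abs(stats)
    truth_vec = np.zeros(positions.shape[0])
    for idx, beta in truth:
        if not 0 <= idx < positions.shape[0]:
            raise InvalidArgumentError(f"truth snp_index {idx} out of range")
        truth_vec[idx] = abs(beta)
    with warnings.catch_warnings():
        # SNPs skipped in every replicate yield an all-NaN column -> NaN mean
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = np.nanmean(stats, axis=0)
    return pd.DataFrame(
        {
            "position": positions,
            "mean_stat": means,
            "true_abs_beta": truth_vec,
        }
    )


def localization_error(prof: pd.DataFrame) -> float:
    """bp distance from the profile's argmax SNP to the nearest causal SNP.

    Argmax ties resolve to the smallest position.  Invariant to monotone
    transformations of the statistic.
    """
    causal = prof.loc[prof["true_abs_beta"] > 0, "position"].to_numpy()
    if causal.size == 0:
        raise InvalidArgumentError("profile has no causal SNP")
    stats = prof["mean_stat"].to_numpy()
    positions = prof["position"].to_numpy()
    peak_pos = positions[np.nanargmax(stats)]  # first (smallest position) argmax wins
    return float(np.min(np.abs(causal - peak_pos)))


def smoothness(values) -> float:
    """Mean |difference| between adjacent SNPs' statistics at unit variance.

    The profile is divided by its (population) standard deviation before
    differencing; a constant profile returns 0.  Accepts a profile frame or
    a plain statistic vector.
    """
    if isinstance(values, pd.DataFrame):
        values = values["mean_stat"].to_numpy()
    x = np.asarray(values, dtype=np.float64)
    x = x[np.isfinite(x)]  # SNPs skipped by a method drop out of the adjacency
    if x.shape[0] < 2:
        raise InvalidArgumentError("smoothness needs at least 2 SNPs")
    sd = x.std()
    if sd == 0:
        return 0.0
    z = x / sd
    return float(np.mean(np.abs(np.diff(z))))


def replicate_profiles(
    config: SimulationConfig,
    R: int,
    *,
    k_max: int = DEFAULT_K_MAX,
    max_window: int = DEFAULT_MAX_WINDOW,
    haps=None,
    engine: LssGeneEngine | None = None,
):
    """Per-replicate LSS and |t| matrices for one simulated gene.

    Returns ``(lss R x S, abs_t R x S, positions, effect_map, haps)``; the
    haplotypes are fixed by the config seed and traits drawn per replicate.
    """
    from .detection import _prepare_gene

    if haps is None:
        haps = _prepare_gene(config)
    if engine is None:
        engine = LssGeneEngine(haps, k_max=k_max, max_window=max_window)
    _, trait_ss, _ = rng_streams(config.seed)
    children = trait_ss.spawn(R)
    traits = [
        simulate_trait(haps, config, rng=np.random.default_rng(children[r])) for r in range(R)
    ]
    Y = np.column_stack([expand_observations(t) for t in traits])
    lss_mat = engine.scores(Y).T
    t_mat = allelic_t_matrix(Y, haps.entries).T
    return lss_mat, np.abs(t_mat), haps.positions, config.effect_map, haps
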