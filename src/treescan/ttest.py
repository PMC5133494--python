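"""The allelic pooled two-sample t-test baseline.

Each chromosome is an observation (an individual's trait value appears
twice), grouped by allele at the focal SNP, group 1 being the minor allele.
This reproduces the classical allelic construction on purpose, including its
known weakness: the analytic t reference ignores that the two observations
from one individual share a trait value, so referencing |t| against the t
distribution can be anti-conservative.  Detection therefore uses permutation
p-values; the analytic reference is exposed only for calibration studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateTraitError, InvalidArgumentError, UnstableTestError

__all__ = ["TTestResult", "allelic_t", "allelic_t_matrix"]


@dataclass(frozen=True)
class TTestResult:
    snp_index: int | None
    t: float
    df: int
    n0: int
    n1: int

    @property
    def abs_t(self) -> float:
        return abs(self.t)


def allelic_t(y: np.ndarray, col: np.ndarray, *, snp_index: int | None = None) -> TTestResult:
    """Pooled t-test of per-chromosome trait observations split by allele.

    ``t = (ybar_1 - ybar_0) / (s_p sqrt(1/n0 + 1/n1))`` with the pooled
    variance ``s_p^2 = ((n0 - 1) s0^2 + (n1 - 1) s1^2) / (n0 + n1 - 2)``.

    Raises :class:`UnstableTestError` when either allele group has fewer
    than 2 observations and :class:`DegenerateTraitError` when ``s_p = 0``.
    """
    y = np.asarray(y, dtype=np.float64)
    col = np.asarray(col)
    if y.shape != col.shape or y.ndim != 1:
        raise InvalidArgumentError("y and col must be equal-length vectors")
    n1 = int(col.sum())
    n0 = y.shape[0] - n1
    if n1 < 2 or n0 < 2:
        raise UnstableTestError(f"allele group too small (n0={n0}, n1={n1})")
    y1 = y[col == 1]
    y0 = y[col == 0]
    ss = (n1 - 1) * y1.var(ddof=1) + (n0 - 1) * y0.var(ddof=1)
    sp2 = ss / (n0 + n1 - 2)
    if sp2 <= 0:
        raise DegenerateTraitError("pooled variance is zero")
    t = (y1.mean() - y0.mean()) / np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))
    return TTestResult(snp_index=snp_index, t=float(t), df=n0 + n1 - 2, n0=n0, n1=n1)


def allelic_t_matrix(Y: np.ndarray, entries: np.ndarray) -> np.ndarray:
    """Vectorized allelic t over all SNPs and many trait columns at once.

    ``Y`` is ``(n, m)`` per-chromosome observations, ``entries`` the
    ``(n, S)`` binary haplotype matrix (allele 1 = minor).  Returns an
    ``(S, m)`` matrix of t statistics; SNPs with an allele group smaller
    than 2 observations, and degenerate (zero pooled variance) cells, are
    NaN so downstream maxima can skip them.
    """
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    G = np.asarray(entries, dtype=np.float64)
    if G.shape[0] != n:
        raise InvalidArgumentError("entries must have one row per observation")
    n1 = G.sum(axis=0)
    n0 = n - n1
    valid = (n1 >= 2) & (n0 >= 2)
    tot = Y.sum(axis=0, keepdims=True)
    tot2 = (Y * Y).sum(axis=0, keepdims=True)
    S1 = G.T @ Y
    Q1 = G.T @ (Y * Y)
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = S1 / n1[:, None]
        m0 = (tot - S1) / n0[:, None]
        ss1 = Q1 - n1[:, None] * m1 * m1
        ss0 = (tot2 - Q1) - n0[:, None] * m0 * m0
        sp2 = (ss1 + ss0) / (n - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0)[:, None])
        t = (m1 - m0) / se
    t[~valid, :] = np.nan
    t[~np.isfinite(t)] = np.nan
    return t
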