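"""The likelihood score statistic (LSS).

Trait observations (one per chromosome) are modeled as multivariate normal
with one mean per tree cluster and covariance ``sigma^2 V``, where V comes
from the clustered local phylogeny at the focal SNP.  For each cluster count
k the cluster means and the common variance are estimated by generalized
least squares (the exact MLEs), and the per-SNP score is the BIC-style
penalized profile likelihood maximized over k:

    LSS_i = max_k { 2 ln L(mu_hat, sigma2_hat | y, V, tree) - k ln n }

with n the number of chromosomes (twice the number of individuals).  The
penalty is exactly ``k ln n``: the variance parameter is deliberately not
counted, which shifts every k by the same constant and leaves the argmax
unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .containers import HaplotypeMatrix
from .errors import (
    DegenerateDesignError,
    DegenerateTraitError,
    DegenerateTreeError,
    EmptyRegionError,
    InvalidArgumentError,
)
from .tree import (
    DEFAULT_MAX_WINDOW,
    DEFAULT_RIDGE,
    ClusteredTree,
    CovarianceModel,
    LocalTree,
    build_tree,
    covariance_from_clusters,
    cut_to_clusters,
    select_window,
)

__all__ = ["GlsFit", "LssResult", "gls_fit", "lss_score", "LssGeneEngine"]

_LOG_2PI = math.log(2.0 * math.pi)

#: Default maximum cluster count for the penalized maximum over k.
DEFAULT_K_MAX = 15


@dataclass(frozen=True)
class GlsFit:
    """MLEs of the clustered-tree Gaussian model for one (y, V, membership)."""

    mu_hat: np.ndarray
    sigma2_hat: float
    loglik: float
    k: int
    n: int


@dataclass(frozen=True)
class LssResult:
    """Per-SNP LSS with the per-k diagnostics behind the maximum."""

    snp_index: int | None
    score: float
    k_star: int
    per_k: tuple[tuple[int, float, float], ...]  # (k, loglik, penalized)
    k_max: int


def _membership_matrix(labels: np.ndarray, k: int) -> np.ndarray:
    n = labels.shape[0]
    X = np.zeros((n, k))
    X[np.arange(n), labels] = 1.0
    return X


def _gls_batch(
    Y: np.ndarray,
    labels: np.ndarray,
    V: np.ndarray,
    k: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """GLS for many trait columns at once under one (labels, V).

    Returns ``(mu_hat (k, m), quad (m,), logdet V)`` where ``quad`` is the
    generalized residual sum of squares ``(y - X mu)' V^-1 (y - X mu)``.
    Products with ``V^-1`` go through one Cholesky factorization; no explicit
    inverse is formed.
    """
    n = Y.shape[0]
    if V.shape != (n, n):
        raise InvalidArgumentError("V dimension must match observation count")
    if np.bincount(labels, minlength=k).min() == 0:
        raise InvalidArgumentError("every cluster must be non-empty")
    factor = cho_factor(V, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(factor[0]))))
    X = _membership_matrix(labels, k)
    VinvY = cho_solve(factor, Y)
    VinvX = cho_solve(factor, X)
    G = X.T @ VinvX
    B = X.T @ VinvY
    try:
        g_factor = cho_factor(G, lower=True)
    except LinAlgError as exc:
        raise DegenerateDesignError("singular X' V^-1 X design") from exc
    mu = cho_solve(g_factor, B)
    quad = np.einsum("ij,ij->j", Y, VinvY) - np.einsum("kj,kj->j", B, mu)
    return mu, quad, logdet


def gls_fit(
    y: np.ndarray,
    membership: np.ndarray,
    V: CovarianceModel | np.ndarray,
) -> GlsFit:
    """Fit cluster means and the common variance by GLS.

    With X the n x k membership indicator:
    ``mu_hat = (X'V^-1 X)^-1 X'V^-1 y``, ``sigma2_hat = rss_V / n`` and
    ``ln L = -(n/2) ln 2 pi - (n/2) ln sigma2_hat - (1/2) ln|V| - n/2``.

    Raises :class:`DegenerateTraitError` when the generalized residual
    variance vanishes (y constant given the design) and
    :class:`DegenerateDesignError` on a singular design.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.ndim != 1:
        raise InvalidArgumentError("y must be 1-D")
    labels = np.asarray(membership, dtype=np.int64)
    if labels.shape != y.shape:
        raise InvalidArgumentError("membership must align with y")
    Vmat = V.V if isinstance(V, CovarianceModel) else np.asarray(V, dtype=np.float64)
    k = int(labels.max()) + 1
    n = y.shape[0]
    mu, quad, logdet = _gls_batch(y[:, None], labels, Vmat, k)
    sigma2 = float(quad[0]) / n
    scale = max(float(np.mean((y - y.mean()) ** 2)), float(np.mean(y * y)), np.finfo(float).tiny)
    if sigma2 <= 1e-12 * scale:
        raise DegenerateTraitError("sigma2_hat = 0: trait constant under the fitted design")
    loglik = -0.5 * n * _LOG_2PI - 0.5 * n * math.log(sigma2) - 0.5 * logdet - 0.5 * n
    return GlsFit(mu_hat=mu[:, 0], sigma2_hat=sigma2, loglik=loglik, k=k, n=n)


def _k_grid(n_tips: int, k_max: int) -> range:
    # k = n_tips would saturate the mean structure (sigma2_hat = 0), so the
    # grid tops out at n_tips - 1.
    return range(2, min(k_max, n_tips - 1) + 1)


def lss_score(
    y: np.ndarray,
    tree: LocalTree,
    k_max: int = DEFAULT_K_MAX,
    *,
    ridge: float = DEFAULT_RIDGE,
    snp_index: int | None = None,
) -> LssResult:
    """BIC-penalized maximum over cluster counts for one SNP's tree.

    For each k in 2..min(k_max, n_tips - 1): cut the tree, build V, fit GLS
    and evaluate ``2 ln L - k ln n``; the score is the maximum (ties go to
    the smallest k).
    """
    y = np.asarray(y, dtype=np.float64)
    if k_max < 2:
        raise InvalidArgumentError("k_max must be >= 2")
    n = y.shape[0]
    if n != tree.n_tips:
        raise InvalidArgumentError("y must hold one observation per chromosome (tree tip)")
    if np.all(y == y[0]):
        raise DegenerateTraitError("y is constant across observations")
    ks = _k_grid(tree.n_tips, k_max)
    if len(ks) == 0:
        raise DegenerateTreeError("no valid cluster count for this tree")
    log_n = math.log(n)
    per_k: list[tuple[int, float, float]] = []
    best: tuple[float, int] | None = None
    for k in ks:
        ct = cut_to_clusters(tree, k)
        cov = covariance_from_clusters(ct, ridge=ridge, snp_index=snp_index)
        fit = gls_fit(y, ct.labels, cov)
        penalized = 2.0 * fit.loglik - k * log_n
        per_k.append((k, fit.loglik, penalized))
        if best is None or penalized > best[0]:
            best = (penalized, k)
    return LssResult(
        snp_index=snp_index,
        score=best[0],
        k_star=best[1],
        per_k=tuple(per_k),
        k_max=k_max,
    )


class LssGeneEngine:
    """Precomputed per-SNP clustered trees for fast scoring of many traits.

    Trees depend only on the haplotypes, so within a gene they are built once
    (deduplicated across SNPs that share a compatibility window) and reused
    across trait replicates and permutations.  :meth:`scores` evaluates the
    LSS for every SNP and every trait column in a batch, pushing the linear
    algebra into one Cholesky solve per (tree, k).
    """

    def __init__(
        self,
        haps: HaplotypeMatrix,
        *,
        k_max: int = DEFAULT_K_MAX,
        max_window: int = DEFAULT_MAX_WINDOW,
        ridge: float = DEFAULT_RIDGE,
    ) -> None:
        if haps.n_snps == 0:
            raise EmptyRegionError("no SNPs to scan")
        self.haps = haps
        self.k_max = k_max
        self.max_window = max_window
        self.ridge = ridge
        self.n = haps.n_chromosomes
        self.windows: list[np.ndarray] = []
        self.tree_of_snp = np.empty(haps.n_snps, dtype=np.int64)
        self.trees: list[LocalTree] = []
        self._cuts: list[list[tuple[int, ClusteredTree]]] = []
        seen: dict[tuple[int, ...], int] = {}
        for s in range(haps.n_snps):
            window = select_window(haps, s, max_window)
            self.windows.append(window)
            key = tuple(window.tolist())
            if key not in seen:
                tree = build_tree(haps, window)
                cuts = [(k, cut_to_clusters(tree, k)) for k in _k_grid(tree.n_tips, k_max)]
                seen[key] = len(self.trees)
                self.trees.append(tree)
                self._cuts.append(cuts)
            self.tree_of_snp[s] = seen[key]

    @property
    def n_unique_trees(self) -> int:
        return len(self.trees)

    def scores(self, Y: np.ndarray, with_k: bool = False):
        """LSS for each SNP (rows) and each trait column of ``Y`` (columns).

        ``Y`` has one row per chromosome; a 1-D vector is treated as a single
        column.  Returns ``(S, m)`` scores, plus the per-column selected
        ``k_star`` when ``with_k`` is set.
        """
        Y = np.asarray(Y, dtype=np.float64)
        squeeze = Y.ndim == 1
        if squeeze:
            Y = Y[:, None]
        if Y.shape[0] != self.n:
            raise InvalidArgumentError("Y must hold one row per chromosome")
        m = Y.shape[1]
        log_n = math.log(self.n)
        u = len(self.trees)
        best = np.full((u, m), -np.inf)
        best_k = np.zeros((u, m), dtype=np.int64)
        for t, cuts in enumerate(self._cuts):
            for k, ct in cuts:
                cov = covariance_from_clusters(ct, ridge=self.ridge)
                _, quad, logdet = _gls_batch(Y, ct.labels, cov.V, k)
                sigma2 = np.maximum(quad, 1e-300) / self.n
                two_ln_l = -self.n * _LOG_2PI - self.n * np.log(sigma2) - logdet - self.n
                penalized = two_ln_l - k * log_n
                better = penalized > best[t]
                best[t][better] = penalized[better]
                best_k[t][better] = k
        scores = best[self.tree_of_snp]
        ks = best_k[self.tree_of_snp]
        if squeeze:
            scores, ks = scores[:, 0], ks[:, 0]
        return (scores, ks) if with_k else scores
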