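"""Community-level kernel association pre-test for survival outcomes.

The microbial profile is summarized by Bray-Curtis (abundance) and Jaccard
(presence/absence) distances, turned into centered kernels, and related to
the outcome through martingale residuals of a covariate-only null survival
model.  Per-kernel p-values come from residual permutations and are combined
into an omnibus p-value with the Cauchy combination.  An insignificant
omnibus p does not block balance selection; it only raises a caution flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError
from .preprocess import Composition, CountTable, SurvivalOutcome, close_raw
from .survival import martingale_residuals

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "KernelTestResult",
    "bray_curtis",
    "jaccard",
    "kernel_from_distance",
    "mirkat_s",
    "gate_warning",
    "community_test",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal, values in [0, 1]."""

    D: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.allclose(D, D.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(D) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(D < 0):
            raise ValidationError("distances must be nonnegative")
        object.__setattr__(self, "D", D)

    @property
    def n_samples(self) -> int:
        return self.D.shape[0]


@dataclass(frozen=True)
class KernelTestResult:
    per_kernel_p: dict[str, float]
    omnibus_p: float
    n_permutations: int
    statistic: dict[str, float]

    def summary(self) -> dict:
        return {
            "per_kernel_p": dict(self.per_kernel_p),
            "omnibus_p": self.omnibus_p,
            "n_permutations": self.n_permutations,
            "statistic": dict(self.statistic),
        }


def bray_curtis(X: Composition | CountTable | np.ndarray) -> DistanceMatrix:
    """Bray-Curtis distances between samples.

    Accepts a :class:`Composition`, a :class:`CountTable` (closed to relative
    abundances without pseudocount, so true zeros are preserved) or a raw
    nonnegative matrix.
    """
    if isinstance(X, CountTable):
        M = close_raw(X)
    elif isinstance(X, Composition):
        M = X.X
    else:
        M = np.asarray(X, dtype=float)
    D = squareform(pdist(M, metric="braycurtis"))
    return DistanceMatrix(np.nan_to_num(D, nan=0.0), "bray_curtis")


def jaccard(tab: CountTable | np.ndarray) -> DistanceMatrix:
    """Jaccard distances on presence/absence (raw count > 0)."""
    counts = tab.counts if isinstance(tab, CountTable) else np.asarray(tab)
    present = counts > 0
    if np.any(~present.any(axis=1)):
        logger.warning("samples with empty presence sets; their pairwise Jaccard is 0")
    D = squareform(pdist(present, metric="jaccard"))
    return DistanceMatrix(np.nan_to_num(D, nan=0.0), "jaccard")


def kernel_from_distance(D: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Gower-centered kernel: K = -1/2 J D^2 J, clipped to PSD.

    Negative eigenvalues (both Bray-Curtis and Jaccard are non-Euclidean in
    general) are clipped to zero.
    """
    M = D.D if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    n = M.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    K = -0.5 * J @ (M * M) @ J
    K = (K + K.T) / 2.0
    vals, vecs = np.linalg.eigh(K)
    if vals[0] < -1e-12:
        vals = np.clip(vals, 0.0, None)
        K = (vecs * vals) @ vecs.T
        K = (K + K.T) / 2.0
    return K


def cauchy_combination(pvalues: np.ndarray) -> float:
    """ACAT: combine p-values via the tangent transform of a Cauchy mean."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("at least one p-value is required")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    # guard the open interval; permutation p-values are already in (0, 1)
    p = np.clip(p, 1e-15, 1 - 1e-15)
    stat = float(np.mean(np.tan((0.5 - p) * np.pi)))
    return float(0.5 - np.arctan(stat) / np.pi)


def mirkat_s(
    kernels: list[np.ndarray] | dict[str, np.ndarray],
    outcome: SurvivalOutcome,
    n_permutations: int = 999,
    seed: int | None = None,
) -> KernelTestResult:
    """Kernel association test between microbiome similarity and survival.

    The score-type statistic Q = r' K r uses martingale residuals r of the
    covariate-only null model.  P-values are estimated by permuting the
    residuals (the (b+1)/(B+1) estimator) and combined across kernels with
    the Cauchy combination.
    """
    if isinstance(kernels, dict):
        names = list(kernels.keys())
        mats = [np.asarray(kernels[k], dtype=float) for k in names]
    else:
        mats = [np.asarray(K, dtype=float) for K in kernels]
        names = [f"kernel_{i}" for i in range(len(mats))]
    if not mats:
        raise ValidationError("at least one kernel is required")
    n = outcome.n_samples
    for K in mats:
        if K.shape != (n, n):
            raise ValidationError("kernel dimensions must match the number of samples")
    if n_permutations < 99:
        logger.warning("n_permutations=%d is small; p-values will be coarse", n_permutations)

    r = martingale_residuals(outcome)
    rng = np.random.default_rng(seed)
    perms = np.empty((n_permutations, n), dtype=float)
    for b in range(n_permutations):
        perms[b] = r[rng.permutation(n)]

    stats_, pvals = {}, {}
    informative: list[float] = []
    for name, K in zip(names, mats):
        q_obs = float(r @ K @ r)
        q_perm = np.einsum("bi,bi->b", perms @ K, perms)
        p = (1.0 + np.sum(q_perm >= q_obs)) / (n_permutations + 1.0)
        stats_[name] = q_obs
        pvals[name] = float(p)
        # a kernel whose statistic is constant under permutation carries no
        # evidence (e.g. Jaccard when every taxon is present everywhere);
        # its p is always 1 and must not enter the omnibus combination
        scale = max(abs(q_obs), float(np.max(np.abs(q_perm))), 1.0)
        if np.ptp(q_perm) <= 1e-12 * scale and abs(q_obs - q_perm[0]) <= 1e-12 * scale:
            logger.warning("kernel %s is degenerate under permutation; "
                           "excluded from the omnibus p-value", name)
            continue
        informative.append(p)

    if informative:
        # clip at the permutation resolution before the Cauchy combination
        lo = 1.0 / (n_permutations + 1.0)
        omnibus = cauchy_combination(np.clip(informative, lo, 1.0 - lo))
    else:
        logger.warning("all kernels degenerate; omnibus p-value set to 1")
        omnibus = 1.0
    return KernelTestResult(pvals, omnibus, n_permutations, stats_)


def gate_warning(result: KernelTestResult, alpha: float = 0.05) -> bool:
    """Caution flag: True iff the omnibus p-value is >= alpha.

    A True flag advises caution in interpreting the selected balance; it
    never blocks the selection itself.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    return bool(result.omnibus_p >= alpha)


def community_test(
    counts: CountTable,
    outcome: SurvivalOutcome,
    n_permutations: int = 999,
    seed: int | None = None,
) -> tuple[KernelTestResult, dict[str, DistanceMatrix]]:
    """Convenience wrapper: Bray-Curtis + Jaccard kernels from a count table."""
    dists = {"bray_curtis": bray_curtis(counts), "jaccard": jaccard(counts)}
    kernels = {name: kernel_from_distance(d) for name, d in dists.items()}
    result = mirkat_s(kernels, outcome, n_permutations=n_permutations, seed=seed)
    return result, dists
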