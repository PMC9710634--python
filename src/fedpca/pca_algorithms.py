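"""Centralized reference PCA and the single-round federated algorithms.

Four federated variants are implemented here:

* ``p_cov`` — exact: clients upload their d x d Gram matrices, which the
  aggregator sums element-wise and eigendecomposes.
* ``ap_cov`` — approximate: clients upload a truncated local SVD
  (k' right singular vectors + singular values); the aggregator rebuilds a
  proxy covariance from each and sums.
* ``ap_stack`` — approximate: same uploads, but the aggregator stacks the
  scaled local subspaces vertically and takes one SVD of the stack.
* ``qr_pca`` — exact: clients upload the R factor of a local QR
  decomposition; the aggregator stacks, re-factors and takes an SVD.

All algorithms assume centered data and report eigenvalues of the
covariance matrix M = (1/n) A'A, i.e. squared singular values divided by
the pooled sample count.  The proxy covariance is rebuilt with *squared*
singular values, which makes ``ap_cov`` and ``ap_stack`` provably
equivalent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .evaluation import canonical_sign
from .federation_core import AGGREGATOR, CommLog, DataMatrix, SitePartition


@dataclass
class Subspace:
    """Top-k eigenvectors (columns of V) and eigenvalues of M = (1/n) A'A."""

    V: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=np.float64)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64)
        if self.V.ndim != 2:
            raise ValueError("V must be 2-D")
        k = self.V.shape[1]
        if k > self.V.shape[0]:
            raise ValueError(f"k={k} exceeds the ambient dimension {self.V.shape[0]}")
        if self.eigenvalues.shape != (k,):
            raise ValueError("one eigenvalue per eigenvector is required")
        gram_dev = np.max(np.abs(self.V.T @ self.V - np.eye(k)))
        if gram_dev > 1e-8:
            raise ValueError(f"V columns not orthonormal (max dev {gram_dev:.2e})")
        if np.any(np.diff(self.eigenvalues) > 1e-10 * max(1.0, self.eigenvalues[0])):
            raise ValueError("eigenvalues must be nonincreasing")

    @property
    def k(self) -> int:
        return self.V.shape[1]


@dataclass
class LocalSummary:
    """Truncated local SVD a site ships to the aggregator."""

    site: int
    V_loc: np.ndarray
    singular_values: np.ndarray

    @property
    def k_prime(self) -> int:
        return self.V_loc.shape[1]

    @property
    def d(self) -> int:
        return self.V_loc.shape[0]


@dataclass
class CovarianceAccumulator:
    """Summed (proxy) Gram matrix held at the aggregator."""

    M: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.float64)
        sym_dev = np.max(np.abs(self.M - self.M.T))
        if sym_dev > 1e-10 * max(1.0, np.max(np.abs(self.M))):
            raise ValueError(f"accumulated matrix not symmetric (dev {sym_dev:.2e})")
        self.M = 0.5 * (self.M + self.M.T)


@dataclass
class QRFactors:
    """Per-site R factors plus the aggregator's stacked and merged factors."""

    R_sites: list[np.ndarray]
    R_stacked: np.ndarray
    R_merged: np.ndarray


def _values(A) -> np.ndarray:
    return np.asarray(getattr(A, "values", A), dtype=np.float64)


def _check_k(k: int, n: int, d: int) -> None:
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(n, d):
        raise ValueError(
            f"k={k} exceeds min(n, d)={min(n, d)}: an n x d matrix has at "
            f"most min(n, d) (and generically n-1 nonzero) covariance "
            f"eigenvalues"
        )


def _top_k_eig(M: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k eigenpairs of a symmetric PSD matrix, nonincreasing order."""
    d = M.shape[0]
    vals, vecs = scipy.linalg.eigh(M, subset_by_index=[d - k, d - 1])
    order = np.argsort(vals)[::-1]
    return np.maximum(vals[order], 0.0), vecs[:, order]


def centralized_pca(A, k: int) -> Subspace:
    """Reference PCA: top-k right singular vectors of the centered pooled
    matrix, with eigenvalues (singular values)^2 / n.

    This is the oracle every federated result is compared against.
    """
    Av = _values(A)
    n, d = Av.shape
    _check_k(k, n, d)
    _, s, Vt = scipy.linalg.svd(Av, full_matrices=False)
    V = canonical_sign(Vt[:k].T)
    return Subspace(V, (s[:k] ** 2) / n)


def local_subspace(A_s, k_prime: int, site: int = 0) -> LocalSummary:
    """Client-side truncated SVD: top-k' right singular vectors and singular
    values of one site block.  k' is capped at min(n_s, d) with a warning."""
    v = _values(A_s)
    if v.size == 0:
        raise ValueError("empty site block")
    n_s, d = v.shape
    if k_prime < 1:
        raise ValueError("k_prime must be >= 1")
    cap = min(n_s, d)
    if k_prime > cap:
        warnings.warn(
            f"site {site}: k'={k_prime} truncated to min(n_s, d)={cap}",
            UserWarning,
            stacklevel=2,
        )
        k_prime = cap
    _, s, Vt = scipy.linalg.svd(v, full_matrices=False)
    return LocalSummary(site, Vt[:k_prime].T, s[:k_prime])


def merge_proxy_covariance(summaries: list[LocalSummary]) -> CovarianceAccumulator:
    """Aggregator-side proxy covariance: sum of V_s diag(sigma_s^2) V_s'."""
    if not summaries:
        raise ValueError("no summaries to merge")
    d = summaries[0].d
    M = np.zeros((d, d))
    for summ in summaries:
        if summ.d != d:
            raise ValueError(
                f"summary for site {summ.site} has d={summ.d}, expected {d}"
            )
        M += (summ.V_loc * summ.singular_values**2) @ summ.V_loc.T
    return CovarianceAccumulator(M)


# --- client-side payload builders (the only raw-data access points) -------

def _client_gram(A_s) -> np.ndarray:
    v = _values(A_s)
    return v.T @ v


def _client_qr(A_s) -> np.ndarray:
    v = _values(A_s)
    return np.linalg.qr(v, mode="r")


# --- federated algorithms -------------------------------------------------

def _broadcast_result(log: CommLog | None, n_sites: int, d: int, k: int) -> None:
    if log is not None:
        for s in range(n_sites):
            log.record(2, AGGREGATOR, s, (d, k))


def p_cov(partition: SitePartition, k: int, log: CommLog | None = None) -> Subspace:
    """Exact federated PCA by element-wise summation of local Gram matrices."""
    n, d = partition.n_total, partition.d
    _check_k(k, n, d)
    M = np.zeros((d, d))
    for s, site in enumerate(partition.sites):
        M += _client_gram(site)
        if log is not None:
            log.record(1, s, AGGREGATOR, (d, d))
    vals, vecs = _top_k_eig(0.5 * (M + M.T), k)
    _broadcast_result(log, partition.n_sites, d, k)
    return Subspace(canonical_sign(vecs), vals / n)


def _collect_summaries(
    partition: SitePartition, k: int, k_prime: int, log: CommLog | None
) -> list[LocalSummary]:
    if k > k_prime:
        raise ValueError(f"k={k} must not exceed the intermediate dimension k'={k_prime}")
    d = partition.d
    summaries = []
    for s, site in enumerate(partition.sites):
        summ = local_subspace(site, k_prime, site=s)
        summaries.append(summ)
        if log is not None:
            log.record(1, s, AGGREGATOR, (d, summ.k_prime))
            log.record(1, s, AGGREGATOR, (summ.k_prime, 1))
    if k > max(s.k_prime for s in summaries):
        raise ValueError(
            f"k={k} exceeds the effective intermediate dimension at every site"
        )
    return summaries


def ap_cov(
    partition: SitePartition,
    k: int,
    k_prime: int,
    log: CommLog | None = None,
) -> Subspace:
    """Approximate federated PCA via summed per-site proxy covariances."""
    n, d = partition.n_total, partition.d
    _check_k(k, n, d)
    summaries = _collect_summaries(partition, k, k_prime, log)
    acc = merge_proxy_covariance(summaries)
    vals, vecs = _top_k_eig(acc.M, k)
    _broadcast_result(log, partition.n_sites, d, k)
    return Subspace(canonical_sign(vecs), vals / n)


def ap_stack(
    partition: SitePartition,
    k: int,
    k_prime: int,
    log: CommLog | None = None,
) -> Subspace:
    """Approximate federated PCA via SVD of the vertically stacked, scaled
    local subspaces — numerically equivalent to :func:`ap_cov`."""
    n, d = partition.n_total, partition.d
    _check_k(k, n, d)
    summaries = _collect_summaries(partition, k, k_prime, log)
    stack = np.vstack(
        [(summ.singular_values[:, None] * summ.V_loc.T) for summ in summaries]
    )
    _, s, Vt = scipy.linalg.svd(stack, full_matrices=False)
    _broadcast_result(log, partition.n_sites, d, k)
    return Subspace(canonical_sign(Vt[:k].T), (s[:k] ** 2) / n)


def qr_merge(partition: SitePartition, log: CommLog | None = None) -> QRFactors:
    """Client QR factors, their vertical stack and the merged second-pass factor."""
    d = partition.d
    R_sites = []
    for s, site in enumerate(partition.sites):
        R = _client_qr(site)
        R_sites.append(R)
        if log is not None:
            log.record(1, s, AGGREGATOR, R.shape)
    R_stacked = np.vstack(R_sites)
    R_merged = np.linalg.qr(R_stacked, mode="r")
    return QRFactors(R_sites, R_stacked, R_merged)


def qr_pca(partition: SitePartition, k: int, log: CommLog | None = None) -> Subspace:
    """Exact federated PCA via stacked per-site QR factors."""
    n, d = partition.n_total, partition.d
    _check_k(k, n, d)
    factors = qr_merge(partition, log)
    _, s, Vt = scipy.linalg.svd(factors.R_merged, full_matrices=False)
    _broadcast_result(log, partition.n_sites, d, k)
    return Subspace(canonical_sign(Vt[:k].T), (s[:k] ** 2) / n)


def default_k_prime(k: int) -> int:
    """Default intermediate dimensionality for the approximate methods."""
    return max(2 * k, k + 5)
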