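"""Accuracy metrics against the centralized reference and the closed-form
communication-cost model.

Eigenvector sign is mathematically arbitrary, so every angle here is
sign-folded (computed from the absolute cosine) and :func:`canonical_sign`
gives deterministic orientations for serialized output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


def canonical_sign(V: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive.

    Ties are broken by the lowest row index (``argmax`` semantics).
    Idempotent, and a no-op for every sign-folded metric below.
    """
    V = np.array(V, dtype=np.float64, copy=True)
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def angle_degrees(x: np.ndarray, y: np.ndarray) -> float:
    """Sign-folded angle between two vectors, in degrees (range [0, 90])."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("angle is undefined for a zero vector")
    xn, yn = x / nx, y / ny
    c = float(xn @ yn)
    if c < 0.0:
        yn, c = -yn, -c
    # atan2 of the perpendicular component: same value as arccos of the
    # folded cosine, but resolves angles far below sqrt(machine eps)
    s = float(np.linalg.norm(yn - c * xn))
    return float(np.degrees(np.arctan2(s, c)))


def _matrix_values(A) -> np.ndarray:
    return np.asarray(getattr(A, "values", A), dtype=np.float64)


def reconstruction_error(A, V: np.ndarray) -> float:
    """Frobenius norm of ``A V V^T - A``."""
    Av = _matrix_values(A)
    V = np.asarray(V, dtype=np.float64)
    gram_dev = np.max(np.abs(V.T @ V - np.eye(V.shape[1])))
    if gram_dev > 1e-6:
        warnings.warn(
            f"V is not orthonormal (max |V'V - I| = {gram_dev:.2e}); "
            "the reconstruction error is still computed",
            UserWarning,
            stacklevel=2,
        )
    return float(np.linalg.norm(Av @ V @ V.T - Av, "fro"))


def reconstruction_ratio(A, V_fed: np.ndarray, V_ref: np.ndarray) -> float:
    """Federated over reference reconstruction error; inf when only the
    reference error vanishes, 1 when both do."""
    if V_fed.shape[1] != V_ref.shape[1]:
        raise ValueError(
            f"subspace ranks differ: {V_fed.shape[1]} vs {V_ref.shape[1]}"
        )
    err_fed = reconstruction_error(A, V_fed)
    err_ref = reconstruction_error(A, V_ref)
    if err_ref == 0.0:
        return 1.0 if err_fed == 0.0 else float("inf")
    return err_fed / err_ref


@dataclass
class AccuracyReport:
    per_eigenvector_angles_deg: list[float]
    reconstruction_error_fed: float
    reconstruction_error_ref: float
    ratio: float
    k: int
    algorithm: str | None = None
    k_prime: int | None = None
    seed: int | None = None

    @property
    def max_angle_deg(self) -> float:
        return max(self.per_eigenvector_angles_deg)

    @property
    def mean_angle_deg(self) -> float:
        return float(np.mean(self.per_eigenvector_angles_deg))

    def to_dict(self) -> dict:
        return {
            "per_eigenvector_angles_deg": self.per_eigenvector_angles_deg,
            "max_angle_deg": self.max_angle_deg,
            "mean_angle_deg": self.mean_angle_deg,
            "reconstruction_error_fed": self.reconstruction_error_fed,
            "reconstruction_error_ref": self.reconstruction_error_ref,
            "ratio": self.ratio,
            "k": self.k,
            "algorithm": self.algorithm,
            "k_prime": self.k_prime,
            "seed": self.seed,
        }


def compare_subspaces(
    S_fed,
    S_ref,
    A,
    algorithm: str | None = None,
    k_prime: int | None = None,
    seed: int | None = None,
) -> AccuracyReport:
    """Per-eigenvector angles (paired by rank order, no re-matching) plus
    reconstruction errors of the federated and reference subspaces on *A*."""
    V_fed, V_ref = S_fed.V, S_ref.V
    if V_fed.shape[1] != V_ref.shape[1]:
        raise ValueError(
            f"k mismatch: federated {V_fed.shape[1]} vs reference {V_ref.shape[1]}"
        )
    k = V_fed.shape[1]
    angles = [angle_degrees(V_fed[:, j], V_ref[:, j]) for j in range(k)]
    err_fed = reconstruction_error(A, V_fed)
    err_ref = reconstruction_error(A, V_ref)
    if err_ref == 0.0:
        ratio = 1.0 if err_fed == 0.0 else float("inf")
    else:
        ratio = err_fed / err_ref
    return AccuracyReport(
        per_eigenvector_angles_deg=angles,
        reconstruction_error_fed=err_fed,
        reconstruction_error_ref=err_ref,
        ratio=ratio,
        k=k,
        algorithm=algorithm,
        k_prime=k_prime,
        seed=seed,
    )


_ALGORITHMS = ("p-cov", "ap-cov", "ap-stack", "qr-pca", "sub-it")


def _canon_algo(name: str) -> str:
    name = name.lower().replace("_", "-")
    if name not in _ALGORITHMS:
        raise ValueError(f"unknown algorithm {name!r}; choose from {_ALGORITHMS}")
    return name


@dataclass
class CostPrediction:
    """Closed-form traffic prediction for one federated run.

    ``per_client_upload``/``per_client_download`` are the nominal per-client
    scalar counts (a site with fewer samples than features uploads less for
    qr-pca and the approximate methods; the exact per-site adjustment is
    folded into ``total`` when ``site_sizes`` are supplied).
    """

    algorithm: str
    n_sites: int
    per_client_upload: int
    per_client_download: int
    rounds: int
    total: int

    @property
    def total_bytes_float64(self) -> int:
        return 8 * self.total

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "n_sites": self.n_sites,
            "per_client_upload": self.per_client_upload,
            "per_client_download": self.per_client_download,
            "rounds": self.rounds,
            "total": self.total,
            "total_bytes_float64": self.total_bytes_float64,
        }


def predicted_comm_cost(
    algorithm: str,
    d: int,
    k: int,
    k_prime: int | None = None,
    iterations: int | None = None,
    n_sites: int = 1,
    site_sizes: Sequence[int] | None = None,
) -> CostPrediction:
    """Scalar traffic of each protocol, matching the recorded CommLog exactly.

    Single-round methods use round 1 for uploads and round 2 for the
    broadcast of the result (rounds = 2); the iterative method uses one
    bidirectional round per iteration (rounds = iterations).  The federated
    statistics protocol is accounted separately
    (:func:`predicted_stats_cost`).
    """
    algorithm = _canon_algo(algorithm)
    if site_sizes is not None:
        if len(site_sizes) != n_sites:
            raise ValueError("site_sizes length must equal n_sites")
        site_sizes = [int(s) for s in site_sizes]
    S = n_sites
    down = d * k

    if algorithm == "p-cov":
        up = d * d
        total = S * (d * d + down)
        rounds = 2
    elif algorithm == "qr-pca":
        up = d * d
        if site_sizes is None:
            up_total = S * d * d
        else:
            up_total = sum(min(ns, d) * d for ns in site_sizes)
        total = up_total + S * down
        rounds = 2
    elif algorithm in ("ap-cov", "ap-stack"):
        if k_prime is None:
            raise ValueError(f"{algorithm} requires k_prime")
        up = d * k_prime + k_prime  # eigenvectors plus singular values
        if site_sizes is None:
            up_total = S * up
        else:
            up_total = sum(
                d * min(k_prime, ns, d) + min(k_prime, ns, d)
                for ns in site_sizes
            )
        total = up_total + S * down
        rounds = 2
    else:  # sub-it
        if iterations is None:
            raise ValueError("sub-it requires iterations")
        up = d * k * iterations
        down = d * k * iterations
        total = 2 * d * k * iterations * S
        rounds = iterations
    return CostPrediction(algorithm, S, up, down, rounds, total)


def predicted_stats_cost(d: int, n_sites: int) -> CostPrediction:
    """Traffic of the two-round federated column-statistics protocol."""
    up = 3 * d + 1
    down = 2 * d
    return CostPrediction(
        "column-stats", n_sites, up, down, 2, n_sites * (up + down)
    )
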