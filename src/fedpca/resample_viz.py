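"""Privacy-aware projection sharing: each site projects its rows onto the
federated eigenvectors, fits a multivariate Gaussian to the projections and
shares only fresh draws from that fit — never the exact points."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

#: Diagonal jitter added to the empirical covariance so degenerate clouds
#: (single points, collinear sites) still yield a valid Gaussian.
COV_JITTER = 1e-9


@dataclass
class ProjectionCloud:
    site: int | str
    points: np.ndarray
    kind: Literal["exact", "resampled"]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2:
            raise ValueError("points must be an m x k matrix")
        if self.kind not in ("exact", "resampled"):
            raise ValueError(f"kind must be 'exact' or 'resampled', got {self.kind!r}")

    @property
    def k(self) -> int:
        return self.points.shape[1]


def project(A_s, subspace) -> ProjectionCloud:
    """Exact local projection of one site block onto the shared eigenvectors."""
    values = np.asarray(getattr(A_s, "values", A_s), dtype=np.float64)
    V = subspace.V if hasattr(subspace, "V") else np.asarray(subspace)
    if values.shape[1] != V.shape[0]:
        raise ValueError(
            f"site has {values.shape[1]} features but the subspace lives in "
            f"{V.shape[0]} dimensions"
        )
    site = getattr(A_s, "site", 0)
    return ProjectionCloud(site, values @ V, "exact")


def resample_local(
    cloud: ProjectionCloud, m: int | None = None, seed: int = 0
) -> ProjectionCloud:
    """Draw m points from a Gaussian fitted to the cloud (sample covariance,
    n-1 divisor, jittered diagonal; mean = cloud mean).  Default m is the
    cloud size, so the shared view keeps per-site proportions."""
    if cloud.points.shape[0] < 1:
        raise ValueError("cannot resample an empty cloud")
    if m is None:
        m = cloud.points.shape[0]
    if m < 1:
        raise ValueError("m must be >= 1")
    mean = cloud.points.mean(axis=0)
    if cloud.points.shape[0] > 1:
        cov = np.cov(cloud.points, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
    else:
        cov = np.zeros((cloud.k, cloud.k))
    cov = cov + COV_JITTER * np.eye(cloud.k)
    rng = np.random.default_rng(seed)
    points = rng.multivariate_normal(mean, cov, size=m)
    return ProjectionCloud(cloud.site, points, "resampled")


def assemble_global_view(
    exact_local: ProjectionCloud,
    resampled_others: list[ProjectionCloud],
) -> pd.DataFrame:
    """One client's view: its own exact projections plus only resampled
    points from every other site, as a labeled point table."""
    k = exact_local.k
    for cloud in resampled_others:
        if cloud.k != k:
            raise ValueError(
                f"cloud for site {cloud.site} has k={cloud.k}, expected {k}"
            )
        if cloud.kind != "resampled":
            raise ValueError(
                f"foreign cloud for site {cloud.site} is {cloud.kind!r}; only "
                "resampled points may cross site boundaries"
            )
    frames = []
    for cloud in [exact_local, *resampled_others]:
        df = pd.DataFrame(
            cloud.points, columns=[f"PC{j + 1}" for j in range(k)]
        )
        df.insert(0, "kind", cloud.kind)
        df.insert(0, "site_id", cloud.site)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
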