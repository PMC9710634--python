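"""Synthetic expression-like data: low-rank-plus-noise matrices with a
controlled spectrum, skewed site-size draws, per-site batch-effect shifts and
the greedy meta-site grouping heuristic.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .federation_core import DataMatrix, SitePartition

#: Real cohort layouts (total samples, number of collection sites) usable as
#: presets for skewed-partition simulations.
SITE_LAYOUT_PRESETS: dict[str, tuple[int, int]] = {
    "tcga-kidney": (887, 24),
    "tcga-thyroid": (504, 11),
    "tcga-liver": (404, 8),
    "tcga-bladder": (408, 14),
    "tcga-ovary": (377, 9),
    "tcga-brain": (679, 20),
    "tcga-prostate": (495, 14),
    "tcga-corpus-uteri": (547, 12),
    "tcga-breast": (1093, 19),
    "tcga-cervix-uteri": (304, 8),
    "tcga-colon": (458, 12),
    "tcga-lung": (1017, 34),
    "tcga-stomach": (386, 9),
    "tcga-skin": (468, 11),
}


@dataclass
class SpectrumSpec:
    """Recipe for a low-rank-plus-noise matrix with chosen leading scales."""

    n: int
    d: int
    leading_values: Sequence[float]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.leading_values = [float(v) for v in self.leading_values]
        if self.rank > min(self.n, self.d):
            raise ValueError(
                f"rank {self.rank} exceeds min(n, d)={min(self.n, self.d)}"
            )
        if any(v <= 0 for v in self.leading_values):
            raise ValueError("leading values must be positive")
        if sorted(self.leading_values, reverse=True) != list(self.leading_values):
            raise ValueError("leading values must be sorted nonincreasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def rank(self) -> int:
        return len(self.leading_values)


def generate_lowrank(spec: SpectrumSpec) -> DataMatrix:
    """A = Z diag(values) W' + E, column-centered.

    W is a random d x r orthonormal basis, Z has i.i.d. standard-normal
    entries and E is i.i.d. Normal(0, noise_sd).  The planted directions
    (columns of W) dominate the top of the spectrum when noise_sd is small.
    """
    rng = np.random.default_rng(spec.seed)
    r = spec.rank
    W, _ = np.linalg.qr(rng.standard_normal((spec.d, r)))
    Z = rng.standard_normal((spec.n, r))
    A = (Z * np.asarray(spec.leading_values)) @ W.T
    if spec.noise_sd > 0:
        A = A + rng.normal(0.0, spec.noise_sd, size=(spec.n, spec.d))
    A = A - A.mean(axis=0)
    sample_ids = [f"S{i:05d}" for i in range(spec.n)]
    feature_ids = [f"G{j:05d}" for j in range(spec.d)]
    return DataMatrix(A, sample_ids, feature_ids)


@dataclass
class SiteSizeSpec:
    """Dirichlet-multinomial site-size draw; alpha is the single skew knob
    (small alpha -> one dominant site, large alpha -> near-uniform sizes)."""

    n_total: int
    n_sites: int
    alpha: float = 1.0
    min_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.n_total < self.n_sites * self.min_size:
            raise ValueError(
                f"cannot place {self.n_total} samples over {self.n_sites} "
                f"sites with min_size={self.min_size}"
            )


def skewed_site_sizes(spec: SiteSizeSpec) -> list[int]:
    """Draw per-site sample counts summing to n_total, each >= min_size."""
    rng = np.random.default_rng(spec.seed)
    weights = rng.dirichlet(np.full(spec.n_sites, spec.alpha))
    spare = spec.n_total - spec.n_sites * spec.min_size
    extra = rng.multinomial(spare, weights)
    return [int(spec.min_size + e) for e in extra]


def inject_batch_effects(
    partition: SitePartition, shift_scale: float, seed: int = 0
) -> SitePartition:
    """Add a per-site constant offset vector (entries i.i.d. Normal(0,
    shift_scale)) to every row of each site.  shift_scale 0 is the identity."""
    if shift_scale < 0:
        raise ValueError("shift_scale must be nonnegative")
    rng = np.random.default_rng(seed)
    sites = []
    for site in partition.sites:
        offset = rng.normal(0.0, shift_scale, size=site.d) if shift_scale else 0.0
        sites.append(
            DataMatrix(
                site.values + offset,
                list(site.sample_ids),
                list(site.feature_ids),
            )
        )
    return SitePartition(sites)


def greedy_meta_sites(sizes: Sequence[int], g: int) -> list[int]:
    """Group sites into g size-balanced meta-sites by the
    longest-processing-time greedy rule.

    Sites are visited in decreasing size order (ties by original index) and
    each is assigned to the currently smallest group (ties to the lowest
    group index).  Returns the group index of every site, deterministic.
    """
    S = len(sizes)
    if not 1 <= g <= S:
        raise ValueError(f"need 1 <= g <= {S} groups, got g={g}")
    assignment = [0] * S
    totals = [0] * g
    for i in sorted(range(S), key=lambda i: (-sizes[i], i)):
        group = min(range(g), key=lambda j: (totals[j], j))
        assignment[i] = group
        totals[group] += sizes[i]
    return assignment
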