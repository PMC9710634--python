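"""Star-topology federation model: row partitioning, message accounting and
federated column statistics.

The aggregator is simulated in-process.  "Sending" a payload means appending a
:class:`MessageRecord` to a :class:`CommLog`; the convention throughout the
package is that functions prefixed ``_client_`` are the only places where raw
site rows may be touched, while aggregator-side logic consumes only the
payloads those functions emit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Sentinel used as sender/receiver for the central coordinator.
AGGREGATOR = "aggregator"

#: Columns whose pooled sample variance falls below this (relative to the
#: column scale) are treated as constant.
_ZERO_VAR_RTOL = 1e-12


@dataclass
class DataMatrix:
    """A samples x features real matrix with row and column labels."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got ndim={self.values.ndim}")
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise ValueError(f"matrix must be at least 1x1, got {n}x{d}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite entries")
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample labels for {n} rows"
            )
        if len(self.feature_ids) != d:
            raise ValueError(
                f"{len(self.feature_ids)} feature labels for {d} columns"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class SitePartition:
    """Ordered per-site row blocks sharing one feature axis."""

    sites: list[DataMatrix]

    def __post_init__(self) -> None:
        if len(self.sites) < 1:
            raise ValueError("a partition needs at least one site")
        ref = self.sites[0].feature_ids
        for i, site in enumerate(self.sites):
            if site.feature_ids != ref:
                raise ValueError(f"site {i} feature_ids differ from site 0")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_sizes(self) -> list[int]:
        return [s.n for s in self.sites]

    @property
    def n_total(self) -> int:
        return sum(self.site_sizes)

    @property
    def d(self) -> int:
        return self.sites[0].d

    @property
    def feature_ids(self) -> list[str]:
        return self.sites[0].feature_ids

    def concatenated(self) -> DataMatrix:
        """Pool all site blocks back into one matrix (site order)."""
        values = np.vstack([s.values for s in self.sites])
        sample_ids = [sid for s in self.sites for sid in s.sample_ids]
        return DataMatrix(values, sample_ids, list(self.feature_ids))


@dataclass(frozen=True)
class MessageRecord:
    round: int
    sender: int | str
    receiver: int | str
    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.round < 0:
            raise ValueError("round must be nonnegative")
        if self.rows < 1 or self.cols < 1:
            raise ValueError(
                f"payload shape must be positive, got {self.rows}x{self.cols}"
            )
        if self.sender == self.receiver:
            raise ValueError("sender and receiver must differ")

    @property
    def scalar_count(self) -> int:
        return self.rows * self.cols


@dataclass
class CommLog:
    """Append-only sequence of message records with derived traffic totals."""

    records: list[MessageRecord] = field(default_factory=list)

    def record(
        self,
        round: int,
        sender: int | str,
        receiver: int | str,
        shape: tuple[int, int],
    ) -> MessageRecord:
        rec = MessageRecord(round, sender, receiver, int(shape[0]), int(shape[1]))
        self.records.append(rec)
        return rec

    @property
    def num_rounds(self) -> int:
        """N: number of distinct communication rounds (not messages)."""
        return len({r.round for r in self.records})

    @property
    def total_scalars(self) -> int:
        """T: total number of real numbers transmitted."""
        return sum(r.scalar_count for r in self.records)

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "round": r.round,
                    "sender": r.sender,
                    "receiver": r.receiver,
                    "rows": r.rows,
                    "cols": r.cols,
                    "scalar_count": r.scalar_count,
                }
                for r in self.records
            ],
            indent=2,
        )


def record_message(
    log: CommLog,
    round: int,
    sender: int | str,
    receiver: int | str,
    shape: tuple[int, int],
) -> CommLog:
    """Append one message to *log* and return it (fluent style)."""
    log.record(round, sender, receiver, shape)
    return log


@dataclass
class ColumnStats:
    """Pooled per-column first and second moments."""

    n_total: int
    means: np.ndarray
    variances: np.ndarray
    zero_variance_mask: np.ndarray
    ddof: int = 1


def split_by_sizes(
    A: DataMatrix,
    sizes: Sequence[int],
    seed: int = 0,
    shuffle: bool = False,
) -> SitePartition:
    """Partition the rows of *A* into consecutive blocks of the given sizes.

    With ``shuffle`` the rows are permuted (deterministically per *seed*)
    before slicing; sample labels travel with their rows, so the original
    order is always recoverable.
    """
    sizes = [int(s) for s in sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("every site size must be >= 1")
    total = sum(sizes)
    if total != A.n:
        raise ValueError(
            f"site sizes sum to {total} but the matrix has {A.n} rows"
        )
    if shuffle:
        order = np.random.default_rng(seed).permutation(A.n)
    else:
        order = np.arange(A.n)
    sites = []
    offset = 0
    for s in sizes:
        idx = order[offset : offset + s]
        sites.append(
            DataMatrix(
                A.values[idx],
                [A.sample_ids[i] for i in idx],
                list(A.feature_ids),
            )
        )
        offset += s
    return SitePartition(sites)


def split_by_assignment(
    A: DataMatrix, assignment: dict[str, str]
) -> SitePartition:
    """Partition rows by a ``sample_id -> site_id`` mapping.

    Sites are ordered by first appearance of their id along the sample axis.
    Every sample of *A* must be assigned exactly once.
    """
    missing = [sid for sid in A.sample_ids if sid not in assignment]
    if missing:
        raise ValueError(
            f"{len(missing)} samples lack a site assignment (first: {missing[0]!r})"
        )
    extra = set(assignment) - set(A.sample_ids)
    if extra:
        raise ValueError(
            f"assignment names {len(extra)} unknown samples (e.g. {sorted(extra)[0]!r})"
        )
    site_order: list[str] = []
    rows: dict[str, list[int]] = {}
    for i, sid in enumerate(A.sample_ids):
        site = assignment[sid]
        if site not in rows:
            rows[site] = []
            site_order.append(site)
        rows[site].append(i)
    sites = [
        DataMatrix(
            A.values[rows[site]],
            [A.sample_ids[i] for i in rows[site]],
            list(A.feature_ids),
        )
        for site in site_order
    ]
    return SitePartition(sites)


def _client_column_summaries(
    block: DataMatrix,
) -> tuple[int, np.ndarray, np.ndarray, np.ndarray]:
    """Client-side payload for the statistics protocol.

    Returns (n_s, per-column counts, sums, sums of squares).  The counts
    vector is redundant for complete data but keeps the payload shape stable
    if missingness support is added later; it is what makes the upload
    3d + 1 scalars.
    """
    v = block.values
    counts = np.full(block.d, block.n, dtype=np.float64)
    return block.n, counts, v.sum(axis=0), (v * v).sum(axis=0)


def federated_column_stats(
    partition: SitePartition,
    log: CommLog | None = None,
    ddof: int = 1,
) -> ColumnStats:
    """Pooled column means/variances via a two-round summary-statistic exchange.

    Round 1: every client uploads ``(n_s, counts, sums, sums of squares)``
    (3d + 1 scalars).  Round 2: the aggregator broadcasts means and variances
    (2d scalars) back to every client.  The result is identical to computing
    the statistics on the pooled matrix, whatever the row layout.
    """
    d = partition.d
    n_total = 0
    sums = np.zeros(d)
    sumsq = np.zeros(d)
    for s, site in enumerate(partition.sites):
        n_s, _counts, site_sums, site_sumsq = _client_column_summaries(site)
        if log is not None:
            log.record(1, s, AGGREGATOR, (3, d))
            log.record(1, s, AGGREGATOR, (1, 1))
        n_total += n_s
        sums += site_sums
        sumsq += site_sumsq
    means = sums / n_total
    if n_total > ddof:
        variances = (sumsq - n_total * means**2) / (n_total - ddof)
    else:
        variances = np.zeros(d)
    variances = np.maximum(variances, 0.0)
    scale = np.maximum(1.0, means**2)
    zero_mask = variances <= _ZERO_VAR_RTOL * scale
    variances = np.where(zero_mask, 0.0, variances)
    if log is not None:
        for s in range(partition.n_sites):
            log.record(2, AGGREGATOR, s, (2, d))
    return ColumnStats(n_total, means, variances, zero_mask, ddof=ddof)


def center_scale(
    partition: SitePartition,
    stats: ColumnStats,
    scale: bool = True,
) -> SitePartition:
    """Center (and optionally variance-scale) every site block in place of a copy.

    Scaling drops constant columns from all sites with a warning; centering
    alone keeps them (a constant column centers to zero harmlessly).
    """
    keep = ~stats.zero_variance_mask if scale else np.ones(partition.d, bool)
    if scale and not keep.any():
        raise ValueError("all columns have zero variance; nothing to analyze")
    n_dropped = int((~keep).sum())
    if scale and n_dropped:
        dropped = [f for f, k in zip(partition.feature_ids, keep) if not k]
        warnings.warn(
            f"dropping {n_dropped} zero-variance column(s): {dropped[:5]}...",
            UserWarning,
            stacklevel=2,
        )
    means = stats.means[keep]
    if scale:
        denom = np.sqrt(stats.variances[keep])
    else:
        denom = np.ones(keep.sum())
    feature_ids = [f for f, k in zip(partition.feature_ids, keep) if k]
    sites = [
        DataMatrix(
            (site.values[:, keep] - means) / denom,
            list(site.sample_ids),
            list(feature_ids),
        )
        for site in partition.sites
    ]
    return SitePartition(sites)
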