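"""Candidate module formation by correlation-constrained agglomeration.

At one time point, genes are clustered on the absolute Pearson correlation:
starting from singletons, the pair of modules whose union has the highest
average internal |PCC| is merged, but only while that average stays above the
null-derived high-correlation threshold for this sample size.  Clustering
ends when no qualifying merge remains, so every returned module's internal
average exceeds the threshold and no two returned modules could still be
combined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import TimepointSlice

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "GeneModule",
    "abs_pcc_matrix",
    "cluster_modules",
    "cluster_all_modules",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric |PCC| matrix over genes at one time point."""

    gene_ids: tuple[str, ...]
    abs_pcc: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        a = self.abs_pcc
        if a.shape != (len(self.gene_ids), len(self.gene_ids)):
            raise ValueError("matrix shape does not match gene_ids")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(a), 1.0):
            raise ValueError("diagonal must be 1")
        if a.min() < 0 or a.max() > 1 + 1e-12:
            raise ValueError("entries must lie in [0, 1]")


@dataclass(frozen=True)
class GeneModule:
    """A gene module whose average internal |PCC| exceeded the merge threshold."""

    members: frozenset[str]
    timepoint_label: str
    avg_internal_pcc: float

    def sorted_members(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))

    def __len__(self) -> int:
        return len(self.members)


def abs_pcc_matrix(slice_: TimepointSlice) -> CorrelationMatrix:
    """Absolute Pearson correlation between every gene pair of a slice.

    Genes with zero variance across the slice have undefined correlations and
    are excluded with a logged warning.
    """
    vals = slice_.values
    sd = vals.std(axis=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        dropped = [g for g, k in zip(slice_.gene_ids, keep) if not k]
        logger.warning(
            "excluding %d zero-variance gene(s) at %s: %s%s",
            n_dropped,
            slice_.timepoint_label,
            dropped[:5],
            "..." if n_dropped > 5 else "",
        )
    if keep.sum() < 2:
        raise ValueError(
            f"fewer than 2 genes with positive variance at {slice_.timepoint_label}"
        )
    sub = vals[keep]
    r = np.corrcoef(sub)
    a = np.abs(r)
    np.clip(a, 0.0, 1.0, out=a)
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    genes = tuple(g for g, k in zip(slice_.gene_ids, keep) if k)
    return CorrelationMatrix(gene_ids=genes, abs_pcc=a, n_samples=slice_.n_samples)


def _agglomerate(
    cm: CorrelationMatrix, threshold: float
) -> tuple[list[tuple[tuple[str, ...], float]], list[tuple[tuple[str, ...], float]]]:
    """Run the greedy agglomeration; return (merge nodes, final modules).

    At each step the pair of current modules whose union has the highest
    average pairwise |PCC| over all internal pairs is merged, provided that
    average exceeds ``threshold``; ties are broken by the lexicographically
    smallest combined gene-id tuple, which makes the result independent of
    input gene order.  Every merge produces a node (members, internal
    average); the final modules are the state when no qualifying merge
    remains.

    Bookkeeping holds per-module internal pair-sums and a cross-sum matrix so
    each merge evaluation is O(1) after the O(g^2) setup; the result equals a
    naive recomputation of every union average.
    """
    g = len(cm.gene_ids)
    members: list[tuple[str, ...] | None] = [(gid,) for gid in cm.gene_ids]
    internal = np.zeros(g)  # sum of |PCC| over internal pairs
    sizes = np.ones(g, dtype=np.int64)
    # cross[i, j] = sum of |PCC| across modules i, j; exact symmetry keeps
    # every later update symmetric bit-for-bit
    cross = (cm.abs_pcc + cm.abs_pcc.T) / 2.0
    np.fill_diagonal(cross, 0.0)
    active = np.ones(g, dtype=bool)
    nodes: list[tuple[tuple[str, ...], float]] = []

    while active.sum() > 1:
        idx = np.flatnonzero(active)
        sz = sizes[idx]
        pair_sz = sz[:, None] + sz[None, :]
        n_pairs = pair_sz * (pair_sz - 1) // 2
        merged_sum = internal[idx][:, None] + internal[idx][None, :] + cross[np.ix_(idx, idx)]
        avg = merged_sum / n_pairs
        np.fill_diagonal(avg, -np.inf)
        best = np.max(avg)
        if not best > threshold:
            break
        ii, jj = np.nonzero(avg == best)
        # tie-break: lexicographically smallest combined sorted gene-id tuple
        # (canonicalize orientation: float round-off can break symmetry by 1 ulp)
        candidates = sorted({(min(i, j), max(i, j)) for i, j in zip(ii, jj)})
        key = min(
            candidates,
            key=lambda p: tuple(sorted(members[idx[p[0]]] + members[idx[p[1]]])),  # type: ignore[operator]
        )
        a, b = idx[key[0]], idx[key[1]]
        internal[a] = internal[a] + internal[b] + cross[a, b]
        sizes[a] = sizes[a] + sizes[b]
        members[a] = tuple(sorted(members[a] + members[b]))  # type: ignore[operator]
        cross[a, :] += cross[b, :]
        cross[:, a] += cross[:, b]
        cross[a, a] = 0.0
        active[b] = False
        members[b] = None
        n_pairs_a = sizes[a] * (sizes[a] - 1) // 2
        nodes.append((members[a], float(internal[a] / n_pairs_a)))  # type: ignore[arg-type]

    finals = []
    for i in np.flatnonzero(active):
        n_pairs_i = sizes[i] * (sizes[i] - 1) // 2
        avg_i = float(internal[i] / n_pairs_i) if n_pairs_i else 1.0
        finals.append((members[i], avg_i))  # type: ignore[arg-type]
    return nodes, finals


def _check_cluster_args(cm: CorrelationMatrix, threshold: float, min_size: int) -> None:
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if min_size < 2:
        raise ValueError(f"min_size must be >= 2, got {min_size}")
    if len(cm.gene_ids) == 0:
        raise ValueError("empty correlation matrix")


def cluster_modules(
    cm: CorrelationMatrix,
    threshold: float,
    min_size: int = 5,
    timepoint_label: str = "",
) -> list[GeneModule]:
    """Final modules of the greedy agglomeration (see ``_agglomerate``).

    Returns the partition left when no qualifying merge remains, restricted
    to modules with at least ``min_size`` members, largest internal average
    first.  Every returned module's internal average exceeds ``threshold``
    and no two returned modules could still be merged.
    """
    _check_cluster_args(cm, threshold, min_size)
    _, finals = _agglomerate(cm, threshold)
    out = [
        GeneModule(
            members=frozenset(mem), timepoint_label=timepoint_label, avg_internal_pcc=avg
        )
        for mem, avg in finals
        if len(mem) >= min_size
    ]
    out.sort(key=lambda m: (-m.avg_internal_pcc, m.sorted_members()))
    return out


def cluster_all_modules(
    cm: CorrelationMatrix,
    threshold: float,
    min_size: int = 5,
    timepoint_label: str = "",
) -> list[GeneModule]:
    """Every module formed during the agglomeration, not just the final cut.

    Hierarchical clustering produces a module at every qualifying merge; with
    few samples the last merges tend to absorb spuriously aligned background
    genes, so the best-scoring module is often an intermediate node rather
    than a final one.  This is the candidate pool that composite-index
    scoring selects from.  Deduplicated by membership, ordered by descending
    internal average.
    """
    _check_cluster_args(cm, threshold, min_size)
    nodes, finals = _agglomerate(cm, threshold)
    seen: dict[frozenset[str], float] = {}
    for mem, avg in nodes + finals:
        if len(mem) >= min_size:
            seen[frozenset(mem)] = avg
    out = [
        GeneModule(members=m, timepoint_label=timepoint_label, avg_internal_pcc=a)
        for m, a in seen.items()
    ]
    out.sort(key=lambda m: (-m.avg_internal_pcc, m.sorted_members()))
    return out
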