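"""Post-detection analyses: regulated genes, pathway pair counts, bridge
genes, and hypergeometric enrichment.

Once a critical time point and its network-biomarker module are fixed, the
disease onset is expected at the *next* sampled time point.  The module's
downstream footprint is characterized by:

* **regulated genes** — non-member genes that, at the onset time point,
  correlate (PCC p < alpha) with at least ``min_links`` module members and
  are differentially expressed between the critical and onset time points
  (two-sample t-test p < alpha);
* **pathway pair counts** — for a gene set (pathway), the number of
  high-correlation gene pairs between module and pathway at a time point,
  using the null-derived high-|PCC| threshold;
* **bridge genes** — regulated genes of a first module that also link to a
  second module and pass its differential-expression filter, connecting two
  successive transitions;
* **enrichment** — an upper-tail hypergeometric test of how many of the
  regulated genes carry a disease annotation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .io import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatedGeneResult",
    "PathwayCorrelationSummary",
    "EnrichmentResult",
    "BridgeGeneResult",
    "pcc_pvalue",
    "regulated_genes",
    "hypergeom_upper",
    "pathway_pair_counts",
    "bridge_genes",
]


@dataclass(frozen=True)
class RegulatedGeneResult:
    dnb_members: tuple[str, ...]
    critical_timepoint: str
    onset_timepoint: str
    genes: dict[str, tuple[int, float]]  # gene -> (n_dnb_links, de_pvalue)

    def gene_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class PathwayCorrelationSummary:
    pathway_name: str
    timepoint_label: str
    n_dnb_genes_involved: int
    n_pathway_genes_involved: int
    n_pairs: int


@dataclass(frozen=True)
class EnrichmentResult:
    population_size: int
    annotated_in_population: int
    sample_size: int
    annotated_in_sample: int
    p_value: float


@dataclass(frozen=True)
class BridgeGeneResult:
    genes: dict[str, tuple[int, float]]  # gene -> (n_dnb2_links, de_pvalue)
    overlap_with_dnb2: tuple[str, ...]

    def gene_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


def pcc_pvalue(r: float, n_samples: int) -> float:
    """Two-sided p-value of a Pearson correlation under the null r = 0.

    Uses the exact t transform t = r * sqrt((n-2)/(1-r^2)) with n-2 degrees
    of freedom; |r| = 1 is the degenerate limit with p = 0.
    """
    if n_samples < 3:
        raise ValueError(f"need at least 3 samples, got {n_samples}")
    if abs(r) > 1.0 + 1e-12:
        raise ValueError(f"|r| must be <= 1, got {r}")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    df = n_samples - 2
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Exact summation of the pmf in log space over k..min(K, n); stable for
    genome-scale counts.  N is the population, K the annotated genes in it,
    n the drawn sample, k the annotated genes observed in the sample.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K <= N and 0 <= n <= N, got N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    logpmf = (
        _log_comb(K, i)
        + _log_comb(N - K, n - i)
        - _log_comb(N, n)
    )
    return float(min(1.0, np.exp(logsumexp(logpmf))))


def _log_comb(a, b):
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def _link_counts(
    ds: ExpressionDataset,
    timepoint: str,
    members: tuple[str, ...],
    candidates: Iterable[str],
    alpha: float,
) -> dict[str, int]:
    """Per-candidate count of module members correlated with PCC p < alpha."""
    sl = ds.slice_timepoint(timepoint)
    n = sl.n_samples
    if n < 3:
        raise ValueError(
            f"time point {timepoint!r} has {n} samples; PCC p-values need >= 3"
        )
    index = {g: i for i, g in enumerate(sl.gene_ids)}
    cand = [g for g in candidates]
    vals = sl.values
    centred = vals - vals.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1, keepdims=True)
    z = centred / np.where(norms > 0, norms, 1.0)
    zm = z[[index[g] for g in members]]
    zc = z[[index[g] for g in cand]]
    r = np.clip(zc @ zm.T, -1.0, 1.0)
    # critical |r| for the two-sided test at this sample size
    df = n - 2
    t_crit = stats.t.isf(alpha / 2.0, df)
    r_crit = t_crit / np.sqrt(df + t_crit**2)
    links = (np.abs(r) > r_crit) | (np.abs(r) == 1.0)
    return {g: int(c) for g, c in zip(cand, links.sum(axis=1))}


def _de_pvalues(
    ds: ExpressionDataset,
    tp_a: str,
    tp_b: str,
    genes: Iterable[str],
    equal_var: bool = True,
) -> dict[str, float]:
    """Two-sided two-sample t-test per gene between two time points."""
    sa = ds.slice_timepoint(tp_a)
    sb = ds.slice_timepoint(tp_b)
    idx_a = {g: i for i, g in enumerate(sa.gene_ids)}
    idx_b = {g: i for i, g in enumerate(sb.gene_ids)}
    genes = list(genes)
    a = sa.values[[idx_a[g] for g in genes]]
    b = sb.values[[idx_b[g] for g in genes]]
    res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    return {g: float(p) for g, p in zip(genes, np.atleast_1d(res.pvalue))}


def regulated_genes(
    ds: ExpressionDataset,
    dnb_members: Iterable[str],
    critical_tp: str,
    onset_tp: str,
    min_links: int = 10,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> RegulatedGeneResult:
    """Non-member genes regulated by the module at the onset time point.

    A gene qualifies iff (a) at ``onset_tp`` its correlation with at least
    ``min_links`` module members is individually significant (PCC p < alpha),
    and (b) its expression differs between ``critical_tp`` and ``onset_tp``
    by a two-sided two-sample t-test with p < alpha (pooled variance by
    default, Welch via ``equal_var=False``).
    """
    members = tuple(sorted(set(dnb_members)))
    missing = [g for g in members if g not in ds.values.index]
    if missing:
        raise KeyError(f"module member(s) not in dataset: {missing[:5]}")
    non_members = [g for g in ds.gene_ids if g not in set(members)]

    links = _link_counts(ds, onset_tp, members, non_members, alpha)
    linked = [g for g in non_members if links[g] >= min_links]
    result: dict[str, tuple[int, float]] = {}
    if linked:
        de = _de_pvalues(ds, critical_tp, onset_tp, linked, equal_var=equal_var)
        for g in linked:
            if de[g] < alpha or alpha >= 1.0:
                result[g] = (links[g], de[g])
    return RegulatedGeneResult(
        dnb_members=members,
        critical_timepoint=critical_tp,
        onset_timepoint=onset_tp,
        genes=result,
    )


def pathway_pair_counts(
    ds: ExpressionDataset,
    timepoint: str,
    dnb_members: Iterable[str],
    pathway_members: Iterable[str],
    high_threshold: float,
    pathway_name: str = "",
) -> PathwayCorrelationSummary:
    """Count high-correlation gene pairs between a module and a pathway.

    A pair (d, p) with d a module gene, p a pathway gene, d != p, counts when
    |PCC(d, p)| at the time point exceeds ``high_threshold`` (the top-5% null
    position for this sample size).  Genes belonging to both sets may appear
    on both sides but are never paired with themselves.  The involved-gene
    counts are the distinct genes appearing in at least one counted pair.
    """
    sl = ds.slice_timepoint(timepoint)
    index = {g: i for i, g in enumerate(sl.gene_ids)}
    d_genes = sorted(set(dnb_members) & index.keys())
    p_genes = sorted(set(pathway_members) & index.keys())
    if not d_genes or not p_genes:
        warnings.warn(
            f"empty intersection with slice for pathway {pathway_name!r}", RuntimeWarning
        )
        return PathwayCorrelationSummary(pathway_name, timepoint, 0, 0, 0)

    vals = sl.values
    centred = vals - vals.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1, keepdims=True)
    z = centred / np.where(norms > 0, norms, 1.0)
    zd = z[[index[g] for g in d_genes]]
    zp = z[[index[g] for g in p_genes]]
    r = np.abs(np.clip(zd @ zp.T, -1.0, 1.0))
    high = r > high_threshold
    # exclude self-pairs for genes present in both sets
    for i, dg in enumerate(d_genes):
        for j, pg in enumerate(p_genes):
            if dg == pg:
                high[i, j] = False
    n_pairs = int(high.sum())
    return PathwayCorrelationSummary(
        pathway_name=pathway_name,
        timepoint_label=timepoint,
        n_dnb_genes_involved=int(high.any(axis=1).sum()),
        n_pathway_genes_involved=int(high.any(axis=0).sum()),
        n_pairs=n_pairs,
    )


def bridge_genes(
    ds: ExpressionDataset,
    regulated1: RegulatedGeneResult,
    dnb2_members: Iterable[str],
    dnb2_critical_tp: str,
    dnb2_onset_tp: str,
    min_links: int = 10,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> BridgeGeneResult:
    """Regulated genes of a first module that also link to a second module.

    Reuses the regulated-gene criteria against the second module: at the
    second module's critical time point the gene must correlate (PCC
    p < alpha) with at least ``min_links`` of its members, and its expression
    must differ (t-test p < alpha) between the second module's critical and
    onset time points.  Also reports which first-module regulated genes are
    themselves members of the second module.
    """
    members2 = tuple(sorted(set(dnb2_members)))
    reg1 = list(regulated1.gene_ids())
    overlap = tuple(sorted(set(reg1) & set(members2)))
    if not reg1:
        return BridgeGeneResult(genes={}, overlap_with_dnb2=overlap)

    # a regulated gene that is itself a DNB2 member is linked to the module's
    # *other* members; self-correlation never counts
    links: dict[str, int] = {}
    plain = [g for g in reg1 if g not in set(members2)]
    if plain:
        links.update(_link_counts(ds, dnb2_critical_tp, members2, plain, alpha))
    for g in overlap:
        others = tuple(m for m in members2 if m != g)
        links.update(_link_counts(ds, dnb2_critical_tp, others, [g], alpha))

    linked = [g for g in reg1 if links[g] >= min_links]
    result: dict[str, tuple[int, float]] = {}
    if linked:
        de = _de_pvalues(ds, dnb2_critical_tp, dnb2_onset_tp, linked, equal_var=equal_var)
        for g in linked:
            if de[g] < alpha or alpha >= 1.0:
                result[g] = (links[g], de[g])
    return BridgeGeneResult(genes=result, overlap_with_dnb2=overlap)
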