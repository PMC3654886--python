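"""Composite-index scoring of candidate modules and critical-point flagging.

A module about to drive a critical transition shows three signatures at the
tipping time point: its members fluctuate strongly (high standard deviation),
correlate tightly with each other, and decouple from the rest of the
transcriptome.  The three are summarized in one composite index

    s = SD_in * PCC_in / PCC_out

where SD_in is the average member standard deviation on the ratio scale,
PCC_in the average absolute Pearson correlation over member pairs, and
PCC_out the average absolute correlation between members and all non-members.
Per time point, the highest-s module among the clustered candidates is that
time point's potential network biomarker; time points whose best score stands
far above the rest are flagged as critical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np

from .clustering import GeneModule, abs_pcc_matrix, cluster_all_modules
from .io import ExpressionDataset, TimepointSlice
from .null_model import NullPccSummary

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleScore",
    "CandidateDnb",
    "DnbTrajectory",
    "module_score",
    "candidate_per_timepoint",
    "flag_critical",
    "dnb_trajectory",
]


@dataclass(frozen=True)
class ModuleScore:
    """Components of the composite index for one module on one slice."""

    sd_in: float
    pcc_in: float
    pcc_out: float
    s: float


@dataclass(frozen=True)
class CandidateDnb:
    """The best-scoring module at one time point."""

    timepoint_label: str
    module: GeneModule
    score: ModuleScore


@dataclass(frozen=True)
class DnbTrajectory:
    """Score components of one fixed gene set followed across all time points.

    ``pcc_in_norm`` and ``pcc_out_norm`` divide the raw correlation averages
    by the null mean |PCC| for that time point's sample size, which puts time
    points with different sample counts on a common correlation baseline.
    The normalization cancels in the ratio, so ``s_norm`` equals the raw
    composite index.
    """

    members: tuple[str, ...]
    timepoint_labels: tuple[str, ...]
    sd_in: tuple[float, ...]
    pcc_in_norm: tuple[float, ...]
    pcc_out_norm: tuple[float, ...]
    s_norm: tuple[float, ...]


def _standardized_rows(values: np.ndarray) -> np.ndarray:
    """Rows centred and scaled to unit norm; zero-variance rows become zero."""
    centred = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1, keepdims=True)
    safe = np.where(norms > 0, norms, 1.0)
    return centred / safe


def module_score(slice_: TimepointSlice, members: Iterable[str]) -> ModuleScore:
    """Composite index of a member set on one time-point slice.

    sd_in uses the n-1 denominator (samples per time point are as few as 4).
    Zero-variance genes contribute correlation 0 (their association with
    anything is unmeasurable).  A module fully decoupled from the background
    (PCC_out = 0) gets an infinite score with a warning.
    """
    member_set = set(members)
    if len(member_set) < 2:
        raise ValueError("module must have at least 2 members")
    index = {g: i for i, g in enumerate(slice_.gene_ids)}
    missing = sorted(member_set - index.keys())
    if missing:
        raise KeyError(f"member gene(s) not in slice: {missing[:5]}")
    member_idx = np.array(sorted(index[g] for g in member_set))
    non_idx = np.array([i for i in range(len(slice_.gene_ids)) if i not in set(member_idx)])
    if non_idx.size == 0:
        raise ValueError("slice must contain at least one non-member gene")

    vals = slice_.values
    sd_in = float(vals[member_idx].std(axis=1, ddof=1).mean())

    z = _standardized_rows(vals)
    zm = z[member_idx]
    r_mm = np.abs(zm @ zm.T)
    iu = np.triu_indices(len(member_idx), k=1)
    pcc_in = float(np.clip(r_mm[iu], 0.0, 1.0).mean())
    r_mo = np.abs(zm @ z[non_idx].T)
    pcc_out = float(np.clip(r_mo, 0.0, 1.0).mean())

    if pcc_out == 0.0:
        warnings.warn(
            "PCC_out is exactly 0; composite index reported as +inf", RuntimeWarning
        )
        s = float("inf") if sd_in * pcc_in > 0 else 0.0
    else:
        s = sd_in * pcc_in / pcc_out
    return ModuleScore(sd_in=sd_in, pcc_in=pcc_in, pcc_out=pcc_out, s=s)


def candidate_per_timepoint(
    ds: ExpressionDataset,
    nulls: Mapping[int, NullPccSummary],
    min_size: int = 5,
) -> list[CandidateDnb]:
    """The highest-scoring clustered module at each time point.

    Each time point is clustered at its own sample size's high-|PCC|
    threshold; every module the clustering forms (including intermediate
    merge nodes) is scored and the argmax-s one kept (ties: larger module,
    then lexicographic member order).  Time points where no module clears
    the clustering threshold yield no candidate.
    """
    out: list[CandidateDnb] = []
    for label in ds.timepoint_labels():
        sl = ds.slice_timepoint(label)
        if sl.n_samples not in nulls:
            raise KeyError(
                f"no null summary for sample size {sl.n_samples} (time point {label!r})"
            )
        threshold = nulls[sl.n_samples].high_threshold
        cm = abs_pcc_matrix(sl)
        modules = cluster_all_modules(cm, threshold=threshold, min_size=min_size, timepoint_label=label)
        if not modules:
            logger.info("no module above threshold %.3f at %s", threshold, label)
            continue
        scored = [(module_score(sl, m.members), m) for m in modules]
        scored.sort(key=lambda t: (-t[0].s, -len(t[1]), t[1].sorted_members()))
        best_score, best_module = scored[0]
        out.append(CandidateDnb(timepoint_label=label, module=best_module, score=best_score))
    return out


def flag_critical(candidates: Sequence[CandidateDnb], fold: float = 3.0) -> list[str]:
    """Time points whose candidate score dominates the others.

    A time point is flagged when its candidate's composite index is at least
    ``fold`` times the median of all candidate scores — a deterministic
    reading of "obviously higher than the other time points".  Returns labels
    in the candidates' (time) order.
    """
    if len(candidates) < 3:
        raise ValueError("need at least 3 candidates to define a baseline")
    if not fold > 1.0:
        raise ValueError(f"fold must be > 1, got {fold}")
    scores = [c.score.s for c in candidates]
    med = median(scores)
    if med == 0.0:
        # degenerate baseline: only strictly positive scores can dominate it
        return [c.timepoint_label for c in candidates if c.score.s > 0.0]
    return [c.timepoint_label for c in candidates if c.score.s >= fold * med]


def dnb_trajectory(
    ds: ExpressionDataset,
    members: Iterable[str],
    nulls: Mapping[int, NullPccSummary],
) -> DnbTrajectory:
    """Score components of a fixed member set at every time point.

    The correlation components are divided by the null mean |PCC| for each
    time point's sample size; the composite index is unaffected because the
    factor cancels between numerator and denominator.
    """
    member_tuple = tuple(sorted(set(members)))
    labels: list[str] = []
    sd_in: list[float] = []
    pin: list[float] = []
    pout: list[float] = []
    s_norm: list[float] = []
    for label in ds.timepoint_labels():
        sl = ds.slice_timepoint(label)
        score = module_score(sl, member_tuple)
        baseline = nulls[sl.n_samples].mean_abs_pcc
        labels.append(label)
        sd_in.append(score.sd_in)
        pin.append(score.pcc_in / baseline)
        pout.append(score.pcc_out / baseline)
        s_norm.append(score.s)
    return DnbTrajectory(
        members=member_tuple,
        timepoint_labels=tuple(labels),
        sd_in=tuple(sd_in),
        pcc_in_norm=tuple(pin),
        pcc_out_norm=tuple(pout),
        s_norm=tuple(s_norm),
    )
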