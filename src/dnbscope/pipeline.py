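"""End-to-end orchestration: thresholds → clustering → scoring → flagging →
trajectories → downstream analyses, from one configuration.

The onset time point of a flagged critical point is, by default, the next
time point in sampling order — the transition the module signals is expected
to manifest one sampling interval later.  A flagged point without a
successor gets no downstream stage, with an explicit note in the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .downstream import (
    EnrichmentResult,
    hypergeom_upper,
    pathway_pair_counts,
    regulated_genes,
)
from .io import (
    ExpressionDataset,
    GeneSetCollection,
    read_annotations,
    read_expression_table,
    read_gene_sets,
)
from .null_model import null_summaries
from .scoring import candidate_per_timepoint, dnb_trajectory, flag_critical

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated inputs and parameters for one pipeline run."""

    expression: str
    sample_map: str
    gene_sets: str | None = None
    annotation: str | None = None
    input_scale: str = "log10_ratio"
    n_draws: int = 100_000
    seed: int = 0
    min_size: int = 5
    fold: float = 3.0
    min_links: int = 10
    alpha: float = 0.05
    equal_var: bool = True
    onset_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for attr in ("expression", "sample_map"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr} file not found: {p}")
        for attr in ("gene_sets", "annotation"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr} file not found: {p}")
        if self.n_draws < 1000:
            raise ValueError("n_draws must be >= 1000")
        if not self.fold > 1.0:
            raise ValueError("fold must be > 1")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")
        if self.min_links < 0:
            raise ValueError("min_links must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineReport:
    """Machine-readable result of one run; serializes losslessly to JSON."""

    thresholds: dict[int, dict[str, float]]
    candidates: list[dict[str, Any]]
    flagged: list[str]
    downstream: dict[str, dict[str, Any]]
    notes: list[str]
    provenance: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, indent: int = 2) -> str:
        d = self.to_dict()
        d["thresholds"] = {str(k): v for k, v in d["thresholds"].items()}
        return json.dumps(d, indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineReport":
        d = json.loads(text)
        d["thresholds"] = {int(k): v for k, v in d["thresholds"].items()}
        return cls(**d)


def _next_label(ds: ExpressionDataset, label: str, onset_map: dict[str, str]) -> str | None:
    if label in onset_map:
        return onset_map[label]
    labels = ds.timepoint_labels()
    i = labels.index(label)
    return labels[i + 1] if i + 1 < len(labels) else None


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full analysis described by ``config``.

    Deterministic for a fixed config and seed: all randomness (the
    correlation-null draws) is derived from the master seed.
    """
    logger.info("reading expression table %s (%s)", config.expression, config.input_scale)
    ds = read_expression_table(config.expression, config.sample_map, config.input_scale)
    gene_sets: GeneSetCollection | None = None
    if config.gene_sets:
        gene_sets = read_gene_sets(config.gene_sets)
    annotation = read_annotations(config.annotation) if config.annotation else None

    sizes = sorted({ds.slice_timepoint(l).n_samples for l in ds.timepoint_labels()})
    logger.info("null thresholds for sample sizes %s (%d draws)", sizes, config.n_draws)
    nulls = null_summaries(sizes, n_draws=config.n_draws, seed=config.seed)
    thresholds = {
        n: {"high_threshold": s.high_threshold, "mean_abs_pcc": s.mean_abs_pcc}
        for n, s in nulls.items()
    }

    logger.info("clustering and scoring per time point (min_size=%d)", config.min_size)
    candidates = candidate_per_timepoint(ds, nulls, min_size=config.min_size)
    flagged = flag_critical(candidates, fold=config.fold)
    logger.info("flagged critical time point(s): %s", flagged)

    cand_summaries = [
        {
            "timepoint_label": c.timepoint_label,
            "members": list(c.module.sorted_members()),
            "size": len(c.module),
            "avg_internal_pcc": c.module.avg_internal_pcc,
            "sd_in": c.score.sd_in,
            "pcc_in": c.score.pcc_in,
            "pcc_out": c.score.pcc_out,
            "s": c.score.s,
        }
        for c in candidates
    ]

    notes: list[str] = []
    downstream_out: dict[str, dict[str, Any]] = {}
    by_label = {c.timepoint_label: c for c in candidates}
    for label in flagged:
        members = by_label[label].module.sorted_members()
        entry: dict[str, Any] = {"members": list(members)}

        traj = dnb_trajectory(ds, members, nulls)
        entry["trajectory"] = {
            "timepoint_labels": list(traj.timepoint_labels),
            "sd_in": list(traj.sd_in),
            "pcc_in_norm": list(traj.pcc_in_norm),
            "pcc_out_norm": list(traj.pcc_out_norm),
            "s_norm": list(traj.s_norm),
        }

        onset = _next_label(ds, label, config.onset_map)
        if onset is None:
            notes.append(
                f"critical point {label!r} is the last time point: no onset "
                "point exists, downstream stages skipped"
            )
            downstream_out[label] = entry
            continue
        entry["onset_timepoint"] = onset

        reg = regulated_genes(
            ds,
            members,
            critical_tp=label,
            onset_tp=onset,
            min_links=config.min_links,
            alpha=config.alpha,
            equal_var=config.equal_var,
        )
        entry["regulated"] = {
            "genes": {g: {"n_dnb_links": l, "de_pvalue": p} for g, (l, p) in sorted(reg.genes.items())},
            "n_regulated": len(reg),
        }

        if gene_sets is not None:
            table = []
            for name in gene_sets.names():
                for tp in (label, onset):
                    summary = pathway_pair_counts(
                        ds,
                        tp,
                        members,
                        gene_sets.members(name),
                        high_threshold=nulls[ds.slice_timepoint(tp).n_samples].high_threshold,
                        pathway_name=name,
                    )
                    table.append(
                        {
                            "pathway": name,
                            "timepoint": tp,
                            "n_dnb_genes_involved": summary.n_dnb_genes_involved,
                            "n_pathway_genes_involved": summary.n_pathway_genes_involved,
                            "n_pairs": summary.n_pairs,
                        }
                    )
            entry["pathway_pairs"] = table

        if annotation is not None and len(reg):
            population = [g for g in ds.gene_ids if g in annotation.index]
            related = {g for g in population if annotation[g]}
            reg_in_pop = [g for g in reg.gene_ids() if g in set(population)]
            k = sum(1 for g in reg_in_pop if g in related)
            enr = EnrichmentResult(
                population_size=len(population),
                annotated_in_population=len(related),
                sample_size=len(reg_in_pop),
                annotated_in_sample=k,
                p_value=hypergeom_upper(len(population), len(related), len(reg_in_pop), k),
            )
            entry["enrichment"] = dataclasses.asdict(enr)
        downstream_out[label] = entry

    return PipelineReport(
        thresholds=thresholds,
        candidates=cand_summaries,
        flagged=flagged,
        downstream=downstream_out,
        notes=notes,
        provenance={
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "version": __version__,
        },
    )
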