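"""Synthetic time-course expression data with a planted critical transition.

The generator emulates the statistical structure the detection method
assumes: a small gene module whose intra-correlations and per-gene variances
spike, and whose correlation with the rest of the transcriptome collapses, at
exactly one sampled time point.  Data are drawn as equicorrelated Gaussian
blocks on the log10 scale and exponentiated to the ratio scale, matching how
two-colour array ratios are deposited and back-transformed.

Design (all on the log10 scale, mean 0 unless shifted):

* at ordinary time points every gene has standard deviation ``sigma_base``
  and pairwise correlation ``rho_bg``; the module's internal correlation is
  ``rho_in_base``;
* at the critical time point the module block switches to internal
  correlation ``rho_in_high`` with standard deviation ``sigma_high``, while
  its correlation to the background drops to ``rho_out``;
* at the time point after the critical one (the onset), an optional set of
  ``n_regulated`` background genes joins the module in a single block of
  correlation ``rho_reg`` and receives a mean shift of ``de_shift`` log10
  units (negative by default: down-regulation, which changes the mean
  without inflating the ratio-scale variance the composite index uses) —
  the association-plus-differential-expression signature the regulated-gene
  filter looks for.

The default time design is six ages with 7/6/4/7/6/5 samples.  Ground truth
(module members, regulated genes, critical and onset labels) is recorded for
recovery tests, along with planted gene sets and a disease annotation whose
positives over-sample the planted signal genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionDataset, GeneSetCollection

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "build_covariance",
    "generate_dataset",
    "generate_gene_sets",
    "DEFAULT_TIMEPOINTS",
]

DEFAULT_TIMEPOINTS: tuple[tuple[str, int], ...] = (
    ("10d", 7),
    ("4w", 6),
    ("8w", 4),
    ("12w", 7),
    ("16w", 6),
    ("20w", 5),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-transition generative model.

    ``critical_index`` is 1-based into ``timepoints``.  Correlations are on
    the log10 scale; ``sigma_*`` are log10-scale standard deviations.
    ``n_regulated=0`` disables the onset association/differential-expression
    block.
    """

    n_genes: int = 200
    module_size: int = 20
    critical_index: int = 1
    timepoints: tuple[tuple[str, int], ...] = DEFAULT_TIMEPOINTS
    rho_in_high: float = 0.9
    rho_in_base: float = 0.2
    rho_out: float = 0.05
    rho_bg: float = 0.2
    sigma_base: float = 0.2
    sigma_high: float = 0.6
    n_regulated: int = 0
    rho_reg: float = 0.8
    de_shift: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.module_size < self.n_genes):
            raise ValueError("need 2 <= module_size < n_genes")
        if not (1 <= self.critical_index <= len(self.timepoints)):
            raise ValueError(
                f"critical_index {self.critical_index} outside 1..{len(self.timepoints)}"
            )
        for rho in (self.rho_in_high, self.rho_in_base, self.rho_out, self.rho_bg, self.rho_reg):
            if not (0.0 <= rho < 1.0):
                raise ValueError(f"correlations must be in [0, 1), got {rho}")
        if self.sigma_base <= 0 or self.sigma_high <= 0:
            raise ValueError("sigmas must be positive")
        if self.n_regulated < 0 or self.module_size + self.n_regulated > self.n_genes:
            raise ValueError("module_size + n_regulated must fit in n_genes")

    def is_null(self) -> bool:
        """True when no transition is planted (calibration regime)."""
        return self.sigma_high == self.sigma_base and self.rho_in_high == self.rho_in_base

    # -- layout -----------------------------------------------------------
    @property
    def gene_ids(self) -> tuple[str, ...]:
        width = len(str(self.n_genes))
        return tuple(f"g{i:0{width}d}" for i in range(1, self.n_genes + 1))

    @property
    def module_genes(self) -> tuple[str, ...]:
        return self.gene_ids[: self.module_size]

    @property
    def regulated_genes(self) -> tuple[str, ...]:
        return self.gene_ids[self.module_size : self.module_size + self.n_regulated]

    @property
    def critical_label(self) -> str:
        return self.timepoints[self.critical_index - 1][0]

    @property
    def onset_label(self) -> str | None:
        if self.critical_index < len(self.timepoints):
            return self.timepoints[self.critical_index][0]
        return None


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated dataset plus its ground truth and planted side files."""

    dataset: ExpressionDataset
    truth_module: tuple[str, ...]
    truth_critical_label: str
    truth_regulated: tuple[str, ...]
    truth_onset_label: str | None
    planted_sets: GeneSetCollection
    planted_annotation: pd.Series
    spec: SyntheticSpec


def build_covariance(spec: SyntheticSpec, timepoint_index: int) -> np.ndarray:
    """Log10-scale covariance matrix for one time point (1-based index).

    The matrix is assembled from equicorrelated blocks and verified positive
    semidefinite: eigenvalues below -1e-10 are a hard error, small negative
    round-off is clipped at sampling time.
    """
    if not (1 <= timepoint_index <= len(spec.timepoints)):
        raise ValueError(f"timepoint_index {timepoint_index} out of range")
    g, m = spec.n_genes, spec.module_size
    mod = slice(0, m)
    corr = np.full((g, g), spec.rho_bg)
    sig = np.full(g, spec.sigma_base)

    if timepoint_index == spec.critical_index and not spec.is_null():
        corr[mod, mod] = spec.rho_in_high
        corr[mod, m:] = spec.rho_out
        corr[m:, mod] = spec.rho_out
        sig[mod] = spec.sigma_high
    else:
        corr[mod, mod] = spec.rho_in_base

    onset_index = spec.critical_index + 1
    if timepoint_index == onset_index and spec.n_regulated > 0:
        blk = slice(0, m + spec.n_regulated)
        corr[blk, blk] = spec.rho_reg

    np.fill_diagonal(corr, 1.0)
    cov = corr * np.outer(sig, sig)
    w = np.linalg.eigvalsh(cov)
    if w.min() < -1e-10:
        raise ValueError(
            f"covariance at time point {timepoint_index} is not PSD "
            f"(min eigenvalue {w.min():.3e}); reduce the block correlations"
        )
    return cov


def _mean_vector(spec: SyntheticSpec, timepoint_index: int) -> np.ndarray:
    mu = np.zeros(spec.n_genes)
    if (
        timepoint_index == spec.critical_index + 1
        and spec.n_regulated > 0
        and spec.de_shift != 0.0
    ):
        mu[spec.module_size : spec.module_size + spec.n_regulated] = spec.de_shift
    return mu


def generate_dataset(spec: SyntheticSpec, seed: int | None = None) -> SyntheticDataset:
    """Draw a full time-course dataset from the planted-transition model.

    For each time point, ``n_samples`` i.i.d. multivariate-normal log10
    vectors are drawn from that time point's covariance (plus mean shift) and
    exponentiated with 10**x.  Bit-reproducible for a fixed seed.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    columns: list[str] = []
    blocks: list[np.ndarray] = []
    map_rows: list[tuple[str, str, int]] = []
    for t, (label, n_samples) in enumerate(spec.timepoints, start=1):
        cov = build_covariance(spec, t)
        mu = _mean_vector(spec, t)
        w, v = np.linalg.eigh(cov)
        root = v * np.sqrt(np.clip(w, 0.0, None))
        z = rng.standard_normal((spec.n_genes, n_samples))
        log_vals = mu[:, None] + root @ z
        blocks.append(10.0 ** log_vals)
        for i in range(1, n_samples + 1):
            sid = f"{label}_s{i}"
            columns.append(sid)
            map_rows.append((sid, label, t))

    values = pd.DataFrame(
        np.hstack(blocks), index=list(spec.gene_ids), columns=columns
    )
    values.index.name = "gene_id"
    sample_map = pd.DataFrame(
        map_rows, columns=["sample_id", "timepoint_label", "timepoint_order"]
    ).set_index("sample_id")
    ds = ExpressionDataset(values=values, sample_map=sample_map)

    sets, annotation = generate_gene_sets(spec, seed=seed + 1)
    return SyntheticDataset(
        dataset=ds,
        truth_module=spec.module_genes,
        truth_critical_label=spec.critical_label,
        truth_regulated=spec.regulated_genes,
        truth_onset_label=spec.onset_label,
        planted_sets=sets,
        planted_annotation=annotation,
        spec=spec,
    )


def generate_gene_sets(
    spec: SyntheticSpec,
    n_sets: int = 10,
    enriched_fraction: float = 0.8,
    seed: int = 0,
    baseline_rate: float = 0.15,
    boost: float = 0.5,
) -> tuple[GeneSetCollection, pd.Series]:
    """Random gene sets plus a disease annotation with planted enrichment.

    The first set ("SET01") over-samples the planted module: it contains
    ``round(enriched_fraction * module_size)`` module genes, topped up with
    random background genes.  The annotation marks each gene disease-related
    at ``baseline_rate``, raised by ``boost`` for the planted signal genes
    (module and regulated), so downstream enrichment tests have a positive
    to find.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if not (0.0 <= enriched_fraction <= 1.0):
        raise ValueError("enriched_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = np.array(spec.gene_ids)
    module = list(spec.module_genes)
    background = [g for g in spec.gene_ids if g not in set(module)]

    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    set_size = max(10, min(40, spec.n_genes // 5))
    n_from_module = round(enriched_fraction * len(module))
    chosen_mod = list(rng.choice(module, size=n_from_module, replace=False))
    n_fill = max(1, set_size - n_from_module)
    fill = list(rng.choice(background, size=n_fill, replace=False))
    sets["SET01"] = ("module-enriched set", tuple(sorted(chosen_mod + fill)))
    for i in range(2, n_sets + 1):
        members = rng.choice(genes, size=set_size, replace=False)
        sets[f"SET{i:02d}"] = ("random set", tuple(sorted(members)))

    signal = set(module) | set(spec.regulated_genes)
    p = np.where(np.isin(genes, list(signal)), min(1.0, baseline_rate + boost), baseline_rate)
    flags = rng.random(spec.n_genes) < p
    annotation = pd.Series(flags, index=list(genes), name="disease_related")
    annotation.index.name = "gene_id"
    return GeneSetCollection(sets=sets), annotation
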