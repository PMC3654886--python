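"""Reading and writing expression matrices, sample maps, gene sets and annotations.

The pipeline's universal input is a gene-by-sample matrix of expression
*ratios* (treatment signal / control signal).  Two-colour microarray data is
commonly deposited as log10 ratios; correlations and standard deviations are
computed on the ratio scale, so log10 input is back-transformed with 10**x
at load time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "TimepointSlice",
    "GeneSetCollection",
    "read_expression_table",
    "slice_timepoint",
    "read_sample_map",
    "read_gene_sets",
    "write_gene_sets",
    "read_annotations",
]


@dataclass(frozen=True)
class TimepointSlice:
    """The columns of an expression dataset belonging to one time point.

    ``values`` is a gene-by-sample array on the ratio scale, gene order
    identical to the parent dataset.
    """

    gene_ids: tuple[str, ...]
    values: np.ndarray
    sample_ids: tuple[str, ...]
    timepoint_label: str

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("slice values must be 2-D (genes x samples)")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError("gene_ids length does not match value rows")
        if self.values.shape[1] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match value columns")


@dataclass
class ExpressionDataset:
    """Gene-by-sample ratio-scale expression matrix with a time-point map.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are sample ids, entries are
        strictly positive expression ratios.
    sample_map
        DataFrame indexed by sample id with columns ``timepoint_label`` and
        ``timepoint_order`` (consecutive integers starting at 1).
    """

    values: pd.DataFrame
    sample_map: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.sample_map.index.has_duplicates:
            raise ValueError("duplicate sample ids in sample map")
        missing = [s for s in self.values.columns if s not in self.sample_map.index]
        if missing:
            raise ValueError(f"samples missing from sample map: {missing}")
        if not (self.values.to_numpy() > 0).all():
            raise ValueError("expression values must be strictly positive ratios")
        orders = sorted(self.sample_map["timepoint_order"].unique())
        if orders != list(range(1, len(orders) + 1)):
            raise ValueError(
                f"timepoint_order must be consecutive integers from 1, got {orders}"
            )
        # one label per order and vice versa
        lab_per_order = self.sample_map.groupby("timepoint_order")["timepoint_label"].nunique()
        if (lab_per_order > 1).any():
            raise ValueError("a timepoint_order maps to more than one label")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def timepoint_labels(self) -> list[str]:
        """Labels in increasing ``timepoint_order``."""
        m = self.sample_map[["timepoint_label", "timepoint_order"]].drop_duplicates()
        return m.sort_values("timepoint_order")["timepoint_label"].tolist()

    def samples_at(self, label: str) -> list[str]:
        """Sample ids mapped to ``label``, in dataset column order."""
        chosen = set(self.sample_map.index[self.sample_map["timepoint_label"] == label])
        return [s for s in self.values.columns if s in chosen]

    def slice_timepoint(self, label: str) -> TimepointSlice:
        return slice_timepoint(self, label)


def read_sample_map(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns sample_id, timepoint_label, timepoint_order."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "timepoint_label": str})
    required = {"sample_id", "timepoint_label", "timepoint_order"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample map must have columns {sorted(required)}")
    df["timepoint_order"] = df["timepoint_order"].astype(int)
    return df.set_index("sample_id")


def read_expression_table(
    path: str | Path,
    sample_map_path: str | Path,
    input_scale: str = "log10_ratio",
) -> ExpressionDataset:
    """Load an expression TSV plus its sample map.

    The TSV has a header row of sample ids and a first column ``gene_id``.
    With ``input_scale="log10_ratio"`` every value x is replaced by 10**x
    (values deposited as log10 of the treatment/control ratio); with
    ``"ratio"`` values are taken as is.  Genes with any missing value are
    dropped (correlations require complete vectors) and the count is logged.
    """
    if input_scale not in ("log10_ratio", "ratio"):
        raise ValueError(f"unknown input_scale {input_scale!r}")

    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.index.name != "gene_id":
        logger.warning("first column named %r, expected 'gene_id'", df.index.name)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene id(s) in {path}: {dups[:5]}")

    # locate non-numeric cells precisely before coercion
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        )

    n_before = len(numeric)
    numeric = numeric.dropna(axis=0, how="any")
    dropped = n_before - len(numeric)
    if dropped:
        logger.info("dropped %d gene(s) with missing values", dropped)

    if input_scale == "log10_ratio":
        numeric = 10.0 ** numeric

    sample_map = read_sample_map(sample_map_path)
    unmapped = [s for s in numeric.columns if s not in sample_map.index]
    if unmapped:
        raise ValueError(f"header sample(s) not in sample map: {unmapped}")
    return ExpressionDataset(values=numeric, sample_map=sample_map)


def slice_timepoint(ds: ExpressionDataset, timepoint_label: str) -> TimepointSlice:
    """All columns of one time point, in dataset order.

    Raises if the label is unknown or if fewer than 2 samples map to it
    (correlations are undefined on a single sample).
    """
    known = ds.timepoint_labels()
    if timepoint_label not in known:
        raise KeyError(f"unknown time point {timepoint_label!r}; known: {known}")
    samples = ds.samples_at(timepoint_label)
    if len(samples) < 2:
        raise ValueError(
            f"time point {timepoint_label!r} has {len(samples)} sample(s); "
            "need at least 2 for correlations"
        )
    sub = ds.values[samples]
    return TimepointSlice(
        gene_ids=ds.gene_ids,
        values=sub.to_numpy(dtype=float),
        sample_ids=tuple(samples),
        timepoint_label=timepoint_label,
    )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> (description, members)."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} has no members")

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB member ids."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} field(s), need >= 3")
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = (desc, tuple(members))
    return GeneSetCollection(sets=sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_annotations(path: str | Path) -> pd.Series:
    """Read a TSV with columns gene_id, disease_related (0/1).

    Returns a boolean Series indexed by gene id.  Extra columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns or "disease_related" not in df.columns:
        raise ValueError("annotation table needs columns gene_id, disease_related")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in annotation table")
    return df.set_index("gene_id")["disease_related"].astype(int).astype(bool)
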