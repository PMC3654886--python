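"""Shared fixtures: handmade datasets, null summaries, synthetic defaults."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dnbscope import (
    ExpressionDataset,
    SyntheticSpec,
    generate_dataset,
    null_summaries,
)


def make_dataset(values: np.ndarray, gene_ids, tp_of_sample) -> ExpressionDataset:
    """Build an ExpressionDataset from a ratio-scale array.

    ``tp_of_sample`` is a list of (sample_id, label, order) triples, one per
    column of ``values``.
    """
    df = pd.DataFrame(values, index=list(gene_ids), columns=[s for s, _, _ in tp_of_sample])
    df.index.name = "gene_id"
    sm = pd.DataFrame(tp_of_sample, columns=["sample_id", "timepoint_label", "timepoint_order"])
    return ExpressionDataset(values=df, sample_map=sm.set_index("sample_id"))


def two_timepoint_map(n_a: int, n_b: int, label_a: str = "t1", label_b: str = "t2"):
    rows = [(f"{label_a}_s{i}", label_a, 1) for i in range(n_a)]
    rows += [(f"{label_b}_s{i}", label_b, 2) for i in range(n_b)]
    return rows


@pytest.fixture(scope="session")
def nulls():
    """Null |PCC| summaries at the study's sample sizes, full 100k draws."""
    return null_summaries([4, 5, 6, 7], n_draws=100_000, seed=2024)


@pytest.fixture(scope="session")
def default_synth():
    """One synthetic dataset at the default planted-transition parameters."""
    return generate_dataset(SyntheticSpec(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
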