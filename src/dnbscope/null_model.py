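"""Null distribution of the Pearson correlation coefficient per sample size.

Time points contribute different numbers of samples, so a fixed correlation
cutoff would treat them unequally.  Each sample size therefore gets its own
randomization summary: draw many pairs of independent random vectors of that
length, record |r| for each, and keep (a) the value at the top-5% position of
the descending sort — the "high correlation" threshold used to gate module
merging and pair counting — and (b) the mean |r|, the baseline used to
normalize correlation curves when plotting trajectories.

For i.i.d. continuous draws the null density of r is f(r) ∝ (1−r²)^((n−4)/2),
which gives a closed-form check: the CDF of |r| is the regularized incomplete
beta I_{q²}(1/2, (n−2)/2).  ``analytic_null_abs_quantile`` inverts it and
serves as the oracle for the simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.special import betaincinv

__all__ = ["NullPccSummary", "simulate_null_pcc", "analytic_null_abs_quantile", "null_summaries"]

DEFAULT_N_DRAWS = 100_000


@dataclass(frozen=True)
class NullPccSummary:
    """Randomization summary of |PCC| for one sample size."""

    sample_size: int
    n_draws: int
    high_threshold: float
    mean_abs_pcc: float
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_abs_pcc <= self.high_threshold <= 1.0 + 1e-12):
            raise ValueError(
                f"require 0 <= mean_abs_pcc ({self.mean_abs_pcc}) <= "
                f"high_threshold ({self.high_threshold}) <= 1"
            )


def simulate_null_pcc(
    sample_size: int, n_draws: int = DEFAULT_N_DRAWS, seed: int = 0
) -> NullPccSummary:
    """Randomization null for |PCC| at a given sample size.

    Draws ``n_draws`` independent pairs of standard-normal vectors of length
    ``sample_size``, computes |r| for each pair, sorts descending, and takes
    the value at rank ceil(0.05 * n_draws) (1-based) as the high-correlation
    threshold; the mean of all |r| is the baseline.  Deterministic per seed.
    """
    if sample_size < 2:
        raise ValueError(f"sample_size must be >= 2, got {sample_size}")
    if n_draws < 1000:
        raise ValueError(f"n_draws must be >= 1000, got {n_draws}")

    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_draws, sample_size))
    y = rng.standard_normal((n_draws, sample_size))
    x -= x.mean(axis=1, keepdims=True)
    y -= y.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", x, y)
    den = np.sqrt(np.einsum("ij,ij->i", x, x) * np.einsum("ij,ij->i", y, y))
    abs_r = np.abs(num / den)

    order = np.sort(abs_r)[::-1]
    rank = math.ceil(0.05 * n_draws)  # 1-based position in the descending order
    return NullPccSummary(
        sample_size=sample_size,
        n_draws=n_draws,
        high_threshold=float(order[rank - 1]),
        mean_abs_pcc=float(abs_r.mean()),
        seed=seed,
    )


def analytic_null_abs_quantile(sample_size: int, q: float) -> float:
    """Exact q-quantile of |r| under the null density f(r) ∝ (1−r²)^((n−4)/2).

    With u = r², |r| has CDF I_{u}(1/2, (n−2)/2); inverting the regularized
    incomplete beta gives the quantile.  At n = 4 this reduces to |r| uniform
    on [0, 1].  Requires n >= 3 (the density degenerates below that).
    """
    if sample_size < 3:
        raise ValueError(f"sample_size must be >= 3, got {sample_size}")
    if not (0.0 < q < 1.0):
        raise ValueError(f"quantile level must be in (0, 1), got {q}")
    u = betaincinv(0.5, (sample_size - 2) / 2.0, q)
    return float(np.sqrt(u))


def null_summaries(
    sample_sizes: Iterable[int], n_draws: int = DEFAULT_N_DRAWS, seed: int = 0
) -> dict[int, NullPccSummary]:
    """One cached summary per distinct sample size.

    The per-size seed is derived from ``seed`` and the size itself, so the
    summary for a given size does not depend on which other sizes are
    requested alongside it.
    """
    out: dict[int, NullPccSummary] = {}
    for n in sorted(set(sample_sizes)):
        out[n] = simulate_null_pcc(n, n_draws=n_draws, seed=_derive_seed(seed, n))
    return out


def _derive_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)).generate_state(1)[0] % (2**31))
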