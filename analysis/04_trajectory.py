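#!/usr/bin/env python
"""Follow the flagged module's score components across all time points.

The detected module is held fixed and re-scored at every time point; the
correlation components are divided by each time point's null mean |PCC| so
time points with different sample counts share a baseline (the composite
index is unaffected — the factor cancels).  An early-warning signature is a
single sharp peak of s at the critical point, driven by high SD_in and
PCC_in and low PCC_out there.
"""

import json
from pathlib import Path

import pandas as pd

from dnbscope import dnb_trajectory, null_summaries, read_expression_table

SEED = 11
ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"


def main() -> None:
    ds = read_expression_table(DATA / "expression.tsv", DATA / "sample_map.tsv")
    flags = json.loads((OUT / "flagged.json").read_text())["flagged"]
    cands = pd.read_csv(OUT / "candidates.tsv", sep="\t")
    if not flags:
        print("no flagged time point; nothing to follow")
        return
    label = flags[0]
    members = cands.loc[cands["timepoint"] == label, "members"].item().split(",")

    sizes = {ds.slice_timepoint(l).n_samples for l in ds.timepoint_labels()}
    nulls = null_summaries(sizes, n_draws=100_000, seed=SEED)
    traj = dnb_trajectory(ds, members, nulls)

    df = pd.DataFrame(
        {
            "timepoint": traj.timepoint_labels,
            "sd_in": traj.sd_in,
            "pcc_in_norm": traj.pcc_in_norm,
            "pcc_out_norm": traj.pcc_out_norm,
            "s": traj.s_norm,
        }
    )
    df.to_csv(OUT / "trajectory.tsv", sep="\t", index=False)
    print(f"trajectory of the {len(members)}-gene module flagged at {label!r}:")
    print(df.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
    peak = df.loc[df["s"].idxmax(), "timepoint"]
    print(f"\ncomposite index peaks at {peak!r}; wrote {OUT / 'trajectory.tsv'}")


if __name__ == "__main__":
    main()
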