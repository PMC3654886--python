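#!/usr/bin/env python
"""Generate the study-shaped synthetic time course used by the analysis.

Six ages with 7/6/4/7/6/5 samples, 200 genes.  A 20-gene module is planted
whose variance and internal correlation spike — and whose correlation to the
rest of the transcriptome collapses — at the first time point (10 d); 30
further genes are associated with the module and down-regulated at the next
time point (4 w), giving the regulated-gene filter something to find.
Writes the pipeline's input files plus the ground truth.
"""

import json
from pathlib import Path

import numpy as np

from dnbscope import SyntheticSpec, generate_dataset, write_gene_sets

SEED = 11
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = SyntheticSpec(n_regulated=30)
    sd = generate_dataset(spec, seed=SEED)

    np.log10(sd.dataset.values).to_csv(OUT / "expression.tsv", sep="\t")
    sd.dataset.sample_map.to_csv(OUT / "sample_map.tsv", sep="\t")
    write_gene_sets(sd.planted_sets, OUT / "gene_sets.gmt")
    sd.planted_annotation.astype(int).rename("disease_related").to_frame().to_csv(
        OUT / "annotation.tsv", sep="\t"
    )
    truth = {
        "module": list(sd.truth_module),
        "critical_label": sd.truth_critical_label,
        "onset_label": sd.truth_onset_label,
        "regulated": list(sd.truth_regulated),
        "seed": SEED,
    }
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")

    n = sd.dataset.values.shape
    print(f"wrote {n[0]} genes x {n[1]} samples to {OUT}")
    print(f"planted module: {len(sd.truth_module)} genes, critical point {sd.truth_critical_label!r}, "
          f"onset {sd.truth_onset_label!r}, {len(sd.truth_regulated)} regulated genes")


if __name__ == "__main__":
    main()
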