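#!/usr/bin/env python
"""Downstream footprint of the flagged module: regulated genes, pathway
correlations, disease-gene enrichment.

Disease onset is expected one sampling interval after the critical point, so
regulated genes are selected at the next time point: non-member genes that
correlate (PCC p < 0.05) with at least 3 module members there — the 10-link
rule of a ~95-gene module scaled to these ~6-gene candidates — and are
differentially expressed between the critical and onset points.  The
regulated set is then tested for enrichment in the disease annotation with
the upper-tail hypergeometric, and the module's high-correlation pair counts
against each planted gene set are tabulated at both time points.
"""

import json
from pathlib import Path

import pandas as pd

from dnbscope import (
    hypergeom_upper,
    null_summaries,
    pathway_pair_counts,
    read_annotations,
    read_expression_table,
    read_gene_sets,
    regulated_genes,
)

SEED = 11
MIN_LINKS = 3
ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"


def main() -> None:
    ds = read_expression_table(DATA / "expression.tsv", DATA / "sample_map.tsv")
    flags = json.loads((OUT / "flagged.json").read_text())["flagged"]
    cands = pd.read_csv(OUT / "candidates.tsv", sep="\t")
    if not flags:
        print("no flagged time point; nothing downstream")
        return
    label = flags[0]
    members = cands.loc[cands["timepoint"] == label, "members"].item().split(",")
    labels = ds.timepoint_labels()
    onset = labels[labels.index(label) + 1]

    reg = regulated_genes(ds, members, label, onset, min_links=MIN_LINKS, alpha=0.05)
    pd.DataFrame(
        [(g, l, p) for g, (l, p) in sorted(reg.genes.items())],
        columns=["gene_id", "n_dnb_links", "de_pvalue"],
    ).to_csv(OUT / "regulated_genes.tsv", sep="\t", index=False)

    truth = json.loads((DATA / "truth.json").read_text())
    planted = set(truth["regulated"])
    found = set(reg.gene_ids())
    print(f"regulated genes at onset {onset!r}: {len(found)} found "
          f"({len(found & planted)} of the {len(planted)} planted)")

    ann = read_annotations(DATA / "annotation.tsv")
    related = {g for g in ds.gene_ids if g in ann.index and ann[g]}
    k = len(found & related)
    p = hypergeom_upper(ds.n_genes, len(related), len(found), k)
    print(f"disease-annotation enrichment: {k}/{len(found)} annotated "
          f"(background {len(related)}/{ds.n_genes}), P(X >= k) = {p:.3g}")
    (OUT / "enrichment.json").write_text(json.dumps({
        "population_size": ds.n_genes,
        "annotated_in_population": len(related),
        "sample_size": len(found),
        "annotated_in_sample": k,
        "p_value": p,
    }, indent=2) + "\n")

    sets = read_gene_sets(DATA / "gene_sets.gmt")
    sizes = {ds.slice_timepoint(l).n_samples for l in labels}
    nulls = null_summaries(sizes, n_draws=100_000, seed=SEED)
    rows = []
    for name in sets.names():
        for tp in (label, onset):
            thr = nulls[ds.slice_timepoint(tp).n_samples].high_threshold
            s = pathway_pair_counts(ds, tp, members, sets.members(name), thr, pathway_name=name)
            rows.append({
                "pathway": name,
                "timepoint": "critical" if tp == label else "onset",
                "dnb_genes": s.n_dnb_genes_involved,
                "pathway_genes": s.n_pathway_genes_involved,
                "pairs": s.n_pairs,
            })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "pathway_pairs.tsv", sep="\t", index=False)
    print("\nhigh-correlation pairs between module and planted gene sets:")
    print(table.to_string(index=False))
    print(f"\nwrote regulated_genes.tsv, enrichment.json, pathway_pairs.tsv under {OUT}")


if __name__ == "__main__":
    main()
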