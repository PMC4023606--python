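#!/usr/bin/env python
"""Direction checks on the packaged rice pathway expression table.

Counts, among the flowering-time and GA-metabolism genes, how many are
expressed higher in the two positive-GCA parents (TQ, 93-11) and both of
their hybrids with GL than in GL itself — the per-pathway signature of
transcriptome bias toward the positive-GCA parent — and reports which
parent each hybrid's level is closer to for every gene.
"""

import json
from pathlib import Path

import pandas as pd

from gcabias import bias, quant

OUT = Path("results/pathways")
OUT.mkdir(parents=True, exist_ok=True)

table = quant.load_rice_pathway_rpkm()
expr = table.drop(columns="pathway")
comparisons = ["TQ", "93-11", "GLxTQ", "GLx93-11"]

results = {}
for pathway, genes in table.groupby("pathway").groups.items():
    n_up = bias.count_higher_in_all(expr, genes, comparisons, "GL")
    n_down = sum(
        (expr.loc[g, comparisons] < expr.loc[g, "GL"]).all() for g in genes
    )
    results[pathway] = {"n_genes": len(genes), "higher_than_GL_in_all": int(n_up),
                        "lower_than_GL_in_all": int(n_down)}
    print(f"{pathway}: {n_up}/{len(genes)} genes above GL in TQ, 93-11 and both hybrids; "
          f"{n_down} below GL in all")

rows = []
for gene, row in table.iterrows():
    rows.append({
        "gene": gene,
        "pathway": row["pathway"],
        "closer_parent_GLxTQ": bias.closer_parent(row["GL"], row["TQ"], row["GLxTQ"], eps=0.05),
        "closer_parent_GLx93-11": bias.closer_parent(row["GL"], row["93-11"], row["GLx93-11"], eps=0.05),
    })
closer = pd.DataFrame(rows).set_index("gene")
closer.to_csv(OUT / "closer_parent.tsv", sep="\t")
n_pos = (closer[["closer_parent_GLxTQ", "closer_parent_GLx93-11"]] == "P2").sum().sum()
n_tot = closer[["closer_parent_GLxTQ", "closer_parent_GLx93-11"]].isin(["P1", "P2"]).sum().sum()
print(f"\nhybrid level closer to the positive-GCA parent in {n_pos}/{n_tot} gene-hybrid pairs")

with open(OUT / "direction_counts.json", "w") as fh:
    json.dump(results, fh, indent=2)
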