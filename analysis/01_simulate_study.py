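#!/usr/bin/env python
"""Generate the synthetic study all downstream analyses consume.

Emulates a five-parent half-diallel trial (three yield traits, three
environments, triplicate plots) plus, for one hybrid trio, RNA-seq counts
and gene-body ChIP counts with known ground truth.  Everything is written
as plain text under results/data/.
"""

from pathlib import Path

import pandas as pd

from gcabias import io, synthetic

SEED = 7412
OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)

G_TRUE = {
    "plant_height": (100.0, [6.0, 3.0, 0.0, -3.0, -6.0]),
    "heading_date": (80.0, [5.0, 2.5, 0.0, -2.5, -5.0]),
    "grain_number": (150.0, [10.0, 5.0, 0.0, -5.0, -10.0]),
}

records = []
for k, (trait, (mu, g)) in enumerate(G_TRUE.items()):
    params = synthetic.DiallelSimParams(
        p=5, mu=mu, g=g, sca_sd=1.0, error_sd=2.0, n_env=3, n_rep=3,
        seed=SEED + k, trait=trait,
    )
    records.append(synthetic.simulate_diallel_phenotypes(params))
phenotypes = pd.concat(records, ignore_index=True)
io.write_phenotypes(phenotypes, OUT / "phenotypes.csv")

trio = synthetic.simulate_trio_counts(
    synthetic.TrioSimParams(n_genes=2000, seed=SEED + 10), return_labels=True
)
io.write_counts(trio.counts, OUT / "trio.counts.tsv", OUT / "trio.libs.tsv")
io.write_bed(trio.models, OUT / "gene_models.bed")
trio.labels.rename_axis("gene_id").to_csv(OUT / "trio.true_categories.tsv", sep="\t")

chip = synthetic.simulate_chip_counts(
    trio.models, mark_bias_fraction=0.9, seed=SEED + 20
)
io.write_counts(chip.counts, OUT / "chip_H3K36me3.counts.tsv", OUT / "chip_H3K36me3.libs.tsv")

print(f"phenotypes: {len(phenotypes)} records "
      f"({phenotypes['trait'].nunique()} traits, 15 diallel cells, 3 env x 3 reps)")
print(f"trio counts: {trio.counts.counts.shape[0]} genes x {trio.counts.counts.shape[1]} samples")
print("true category fractions:")
print(trio.labels.value_counts(normalize=True).round(3).to_string())
print(f"ChIP counts written for H3K36me3 (bias fraction 0.9, modified fraction 0.3)")
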