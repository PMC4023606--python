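#!/usr/bin/env python
"""Estimate combining ability from the simulated diallel trial.

Fits the Griffing Method-2 fixed-effects model per trait, reports the GCA
ranking of the five parents, and correlates parental phenotypes with their
hybrids' phenotypes (pooled z-standardized traits).
"""

from pathlib import Path

import pandas as pd

from gcabias import diallel, io

DATA = Path("results/data")
OUT = Path("results/gca")
OUT.mkdir(parents=True, exist_ok=True)

phenotypes = io.read_phenotypes(DATA / "phenotypes.csv")

gca_rows, sca_rows = [], []
for trait in sorted(phenotypes["trait"].unique()):
    means = diallel.cross_means(phenotypes, trait)
    res = diallel.gca_method2(means)
    print(f"\n{trait}: mu = {res.mu:.2f}")
    print("  GCA:", ", ".join(f"{p}={v:+.2f}" for p, v in res.g.sort_values(ascending=False).items()))
    for parent, val in res.g.items():
        gca_rows.append({"parent": parent, "trait": trait, "gca": val, "mu": res.mu})
    for i, pi in enumerate(res.s.index):
        for pj in res.s.columns[i + 1:]:
            sca_rows.append({"cross": f"{pi}x{pj}", "trait": trait, "sca": res.s.loc[pi, pj]})

pd.DataFrame(gca_rows).to_csv(OUT / "gca.tsv", sep="\t", index=False)
pd.DataFrame(sca_rows).to_csv(OUT / "sca.tsv", sep="\t", index=False)

print("\nparent-F1 phenotype correlations (co-parent pairing, pooled z-scores):")
corr_rows = []
for parent in sorted(phenotypes["parent_a"].unique()):
    xs, ys = diallel.parent_f1_pairs(phenotypes, parent)
    r, p, n = diallel.parent_f1_correlation(xs, ys)
    corr_rows.append({"parent": parent, "r": r, "p_value": p, "n_pairs": n})
    print(f"  {parent}: r = {r:+.3f} (p = {p:.2e}, n = {n})")
pd.DataFrame(corr_rows).to_csv(OUT / "parent_f1_correlations.tsv", sep="\t", index=False)
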