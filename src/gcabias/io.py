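"""Readers and writers for the pipeline's on-disk formats.

Phenotypes travel as long-format CSV; counts as TSV (gene_id + one column
per sample) with a two-column library-size sidecar TSV; gene models as
BED6 or GFF3.  Internally all coordinates are 0-based half-open (BED
convention); GFF3 is converted on the way in/out (1-based closed).
"""

from __future__ import annotations

import os
import tempfile

import pandas as pd

from .quant import CountMatrix

PHENOTYPE_COLUMNS = ["parent_a", "parent_b", "env", "rep", "trait", "value"]

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "read_counts",
    "write_counts",
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
]


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype CSV missing columns: {sorted(missing)}")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df[PHENOTYPE_COLUMNS].to_csv(path, index=False)


def read_counts(counts_path, lib_sizes_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    libs = pd.read_csv(lib_sizes_path, sep="\t", index_col=0)
    return CountMatrix(counts=counts, lib_sizes=libs.iloc[:, 0].astype(float))


def write_counts(cm: CountMatrix, counts_path, lib_sizes_path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    cm.lib_sizes.rename("lib_size").rename_axis("sample").to_csv(lib_sizes_path, sep="\t")


def read_bed(path) -> pd.DataFrame:
    """BED6 gene models (0-based half-open, as stored)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
    )
    return df[["gene_id", "chrom", "start", "end", "strand"]]


def write_bed(models: pd.DataFrame, path) -> None:
    out = models.assign(score=0)[["chrom", "start", "end", "gene_id", "score", "strand"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_gff3(path, feature_type: str = "gene") -> pd.DataFrame:
    """Gene models from GFF3 (1-based closed on disk -> 0-based half-open)."""
    import gffutils

    with tempfile.NamedTemporaryFile(suffix=".db", delete=False) as tmp:
        dbpath = tmp.name
    try:
        db = gffutils.create_db(
            str(path), dbpath, force=True, keep_order=True, merge_strategy="create_unique"
        )
        rows = [
            {
                "gene_id": feat.id,
                "chrom": feat.seqid,
                "start": feat.start - 1,
                "end": feat.end,
                "strand": feat.strand,
            }
            for feat in db.features_of_type(feature_type)
        ]
    finally:
        if os.path.exists(dbpath):
            os.unlink(dbpath)
    return pd.DataFrame(rows)


def write_gff3(models: pd.DataFrame, path, source: str = "gcabias") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in models.itertuples():
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )
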