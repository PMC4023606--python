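"""Per-gene read-count containers and RPKM normalization.

RPKM (Reads Per Kilobase per Million mapped reads) for a gene with read
count ``C``, library size ``N`` and gene-body length ``L`` (bp) is

    RPKM = 1e9 * C / (N * L)

Both nuclear RNA-seq and gene-body ChIP-seq signal are normalized with the
same formula over the same gene-body interval (end - start), so the two
assays share this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "rpkm",
    "rpkm_matrix",
    "expressed_genes",
    "load_rice_pathway_rpkm",
]


@dataclass
class CountMatrix:
    """Integer per-gene read counts with per-sample library sizes.

    Parameters
    ----------
    counts : DataFrame
        Genes (rows, indexed by gene id) by samples (columns); non-negative.
    lib_sizes : Series
        Total mapped reads per sample.  May exceed the column sum (reads
        assigned to features are a subset of all mapped reads).
    """

    counts: pd.DataFrame
    lib_sizes: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        self.lib_sizes = self.lib_sizes.reindex(self.counts.columns)
        if self.lib_sizes.isna().any():
            missing = list(self.lib_sizes.index[self.lib_sizes.isna()])
            raise ValueError(f"library size missing for samples: {missing}")
        if (self.lib_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


def rpkm(count, lib_size, length_bp):
    """Scalar/array RPKM = 1e9 * C / (N * L)."""
    count = np.asarray(count, dtype=float)
    lib_size = np.asarray(lib_size, dtype=float)
    length_bp = np.asarray(length_bp, dtype=float)
    if (lib_size <= 0).any():
        raise ValueError("lib_size must be > 0")
    if (length_bp <= 0).any():
        raise ValueError("length_bp must be > 0")
    if (count < 0).any():
        raise ValueError("count must be >= 0")
    return 1e9 * count / (lib_size * length_bp)


def rpkm_matrix(cm: CountMatrix, models: pd.DataFrame) -> pd.DataFrame:
    """RPKM per gene x sample.

    ``models`` is a gene-model table indexed by (or containing a ``gene_id``
    column with) gene ids, with ``start``/``end`` columns in 0-based
    half-open coordinates; length is ``end - start``.  Genes in ``cm``
    without a model are dropped with a warning.
    """
    if "gene_id" in models.columns:
        models = models.set_index("gene_id")
    lengths = (models["end"] - models["start"]).astype(float)
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0])
        raise ValueError(f"non-positive gene length for: {bad}")
    shared = cm.gene_ids.intersection(lengths.index)
    if len(shared) == 0:
        raise ValueError("no genes shared between counts and gene models")
    missing = cm.gene_ids.difference(lengths.index)
    if len(missing):
        warnings.warn(
            f"dropping {len(missing)} gene(s) without a model "
            f"(e.g. {list(missing[:3])})",
            stacklevel=2,
        )
    # keep original row order for the genes retained
    keep = [g for g in cm.gene_ids if g in set(shared)]
    counts = cm.counts.loc[keep]
    L = lengths.loc[keep].to_numpy()[:, None]
    N = cm.lib_sizes.to_numpy()[None, :]
    vals = 1e9 * counts.to_numpy(dtype=float) / (N * L)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def expressed_genes(expr: pd.DataFrame, sample: str, threshold: float = 0.0) -> pd.Index:
    """Genes with RPKM strictly above ``threshold`` in ``sample``."""
    if sample not in expr.columns:
        raise KeyError(f"unknown sample {sample!r}")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    col = expr[sample]
    return expr.index[col > threshold]


def load_rice_pathway_rpkm() -> pd.DataFrame:
    """Published RPKM values for rice flowering-time and GA-metabolism genes.

    Twelve genes quantified in the parents GL (Guangluai 4), TQ (Teqing) and
    93-11 and the F1 hybrids GLxTQ, GLx93-11 and 93-11xTQ; indexed by gene
    symbol with a ``pathway`` column (``flowering`` / ``ga_metabolism``).
    """
    with resources.files("gcabias.data").joinpath("rice_pathway_rpkm.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return df
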