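"""Gene-body histone-mark quantification and parental modification bias.

ChIP-seq reads assigned to gene bodies (one count per gene per sample per
mark) are normalized to RPKM exactly like expression counts.  A gene is
"modified" when its gene-body signal clears an RPKM threshold and a
minimum read count; F1-versus-parent differences in modification level are
tested with the same exact count test used for expression, at a stricter
FDR (default 0.001), and the similarity fraction is the share of modified
genes whose F1 level is statistically indistinguishable from the parent's.
"""

from __future__ import annotations

import pandas as pd

from .degtest import call_degs
from .quant import CountMatrix, rpkm_matrix

__all__ = [
    "gene_body_rpkm",
    "modified_gene_set",
    "modification_similarity",
    "mark_overlap",
]


def gene_body_rpkm(chip_counts: CountMatrix, models: pd.DataFrame) -> pd.DataFrame:
    """Gene-body RPKM per gene x sample for one mark."""
    return rpkm_matrix(chip_counts, models)


def modified_gene_set(
    signal: pd.DataFrame,
    sample: str,
    min_rpkm: float = 0.0,
    counts: CountMatrix | None = None,
    min_count: int = 10,
) -> pd.Index:
    """Genes carrying the mark in ``sample``.

    ``signal`` is the gene-body RPKM table.  With ``min_rpkm == 0`` the
    rule is strict (RPKM > 0); otherwise RPKM >= min_rpkm.  When raw
    ``counts`` are supplied, genes under ``min_count`` reads are excluded
    to keep one-read genes out of the modified set.
    """
    if sample not in signal.columns:
        raise KeyError(f"unknown sample {sample!r}")
    if min_rpkm < 0:
        raise ValueError("min_rpkm must be >= 0")
    col = signal[sample]
    keep = col > 0 if min_rpkm == 0 else col >= min_rpkm
    if counts is not None:
        c = counts.counts[sample].reindex(signal.index)
        keep &= c >= min_count
    return signal.index[keep]


def modification_similarity(
    chip_counts: CountMatrix,
    f1_sample: str,
    parent_sample: str,
    models: pd.DataFrame,
    fdr_threshold: float = 0.001,
    min_rpkm: float = 0.0,
    min_count: int = 10,
):
    """Fraction of modified genes with F1 signal similar to the parent.

    The universe is the union of the modified sets of the two samples; a
    gene is similar when its BH q-value from the exact count test is at or
    above ``fdr_threshold``.  Returns ``(fraction, per_gene_calls)`` where
    the calls cover the universe.
    """
    signal = gene_body_rpkm(chip_counts, models)
    mod_f1 = modified_gene_set(signal, f1_sample, min_rpkm, chip_counts, min_count)
    mod_p = modified_gene_set(signal, parent_sample, min_rpkm, chip_counts, min_count)
    universe = mod_f1.union(mod_p)
    if len(universe) == 0:
        raise ValueError("no modified genes in either sample")
    sub = CountMatrix(
        counts=chip_counts.counts.loc[universe, [f1_sample, parent_sample]],
        lib_sizes=chip_counts.lib_sizes[[f1_sample, parent_sample]],
    )
    # no fold-change gate here: similarity is purely statistical (q >= threshold)
    calls = call_degs(sub, f1_sample, parent_sample, fc_threshold=1.0, q_threshold=fdr_threshold)
    similar = calls["q_value"] >= fdr_threshold
    frac = float(similar.reindex(universe, fill_value=True).mean())
    return frac, calls.assign(similar=similar)


def mark_overlap(set_a, set_b) -> dict:
    """Overlap between two modified-gene sets.

    Returns the Jaccard fraction ``|A & B| / |A | B|`` plus both
    directional fractions; all NaN when both sets are empty.
    """
    A, B = set(set_a), set(set_b)
    inter = len(A & B)
    union = len(A | B)
    nan = float("nan")
    return {
        "jaccard": inter / union if union else nan,
        "frac_of_a": inter / len(A) if A else nan,
        "frac_of_b": inter / len(B) if B else nan,
        "n_intersection": inter,
        "n_union": union,
    }
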