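"""Parental-bias analysis of F1 expression.

Given differential calls of the F1 against each parent and normalized
expression for the trio, every tested gene falls in exactly one category:

* ``non_deg`` — not differential against either parent;
* ``equal_P1`` / ``equal_P2`` — differential against exactly one parent,
  i.e. statistically indistinguishable from (equal to) the *other* parent;
* ``over_parents`` — differential against both parents with F1 expression
  strictly outside the parental range;
* ``between_parents`` — differential against both parents but inside the
  parental range.

Aggregate summaries report, per hybrid, the fraction of expressed genes
similar to each parent, the DEG fraction, the category split among DEGs,
and among equal-to-one-parent genes the split between the two parents
("parental bias").  Sample relationships are summarized by hierarchical
clustering of log-expression profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

CATEGORIES = ("equal_P1", "equal_P2", "over_parents", "between_parents", "non_deg")

__all__ = [
    "CATEGORIES",
    "BiasSummary",
    "classify_trio",
    "closer_parent",
    "similarity_to_parent",
    "count_higher_in_all",
    "bias_summary",
    "cluster_samples",
    "linkage_to_newick",
]


def classify_trio(
    deg_vs_p1: pd.DataFrame,
    deg_vs_p2: pd.DataFrame,
    expr: pd.DataFrame,
    p1: str = "P1",
    p2: str = "P2",
    f1: str = "F1",
) -> pd.DataFrame:
    """Categorize each tested gene's F1 expression relative to the parents.

    ``deg_vs_p1``/``deg_vs_p2`` are :func:`~gcabias.degtest.call_degs`
    outputs for F1-vs-P1 and F1-vs-P2; ``expr`` holds normalized (RPKM)
    expression with columns for the three samples.  The gene universe is
    the union of the two tested sets; range position uses strict
    inequalities, so an F1 exactly on a parental boundary counts as inside
    the range.
    """
    genes = deg_vs_p1.index.union(deg_vs_p2.index)
    missing = genes.difference(expr.index)
    if len(missing):
        raise ValueError(f"expression missing for tested genes, e.g. {list(missing[:3])}")
    sig1 = deg_vs_p1["is_deg"].reindex(genes, fill_value=False).to_numpy()
    sig2 = deg_vs_p2["is_deg"].reindex(genes, fill_value=False).to_numpy()
    e = expr.loc[genes]
    v1, v2, vf = (e[c].to_numpy(dtype=float) for c in (p1, p2, f1))
    outside = (vf > np.maximum(v1, v2)) | (vf < np.minimum(v1, v2))

    category = np.where(
        ~sig1 & ~sig2,
        "non_deg",
        np.where(
            sig1 & ~sig2,
            "equal_P2",
            np.where(
                ~sig1 & sig2,
                "equal_P1",
                np.where(outside, "over_parents", "between_parents"),
            ),
        ),
    )
    closer = [closer_parent(a, b, f, eps=_eps_for(expr)) for a, b, f in zip(v1, v2, vf)]
    return pd.DataFrame({"category": category, "closer_parent": closer}, index=genes)


def _eps_for(expr: pd.DataFrame) -> float:
    vals = expr.to_numpy(dtype=float)
    pos = vals[vals > 0]
    return 0.5 * pos.min() if pos.size else 0.0


def closer_parent(p1_val: float, p2_val: float, f1_val: float, eps: float = 0.0) -> str:
    """Which parent the F1 level is nearer to on the log2 ratio scale.

    Distance is ``|log2((F1+e)/(P+e))|`` where ``e`` is 0 except when a
    value involved is 0, in which case ``eps`` (half the smallest nonzero
    value of the matrix) is used.  Returns ``'tie'`` on equality and
    ``'undefined'`` when all three values are zero.
    """
    if p1_val == p2_val == f1_val == 0:
        return "undefined"
    e = eps if min(p1_val, p2_val, f1_val) == 0 else 0.0
    d1 = abs(np.log2((f1_val + e) / (p1_val + e)))
    d2 = abs(np.log2((f1_val + e) / (p2_val + e)))
    if np.isclose(d1, d2):
        return "tie"
    return "P1" if d1 < d2 else "P2"


def similarity_to_parent(deg_calls: pd.DataFrame, expressed: pd.Index) -> float:
    """Fraction of expressed genes not differential versus that parent.

    Expressed genes that were not testable (zero in both samples) count as
    similar; the two per-parent fractions of a hybrid may sum above 1.
    """
    if len(expressed) == 0:
        raise ValueError("expressed gene set is empty")
    is_deg = deg_calls["is_deg"].reindex(expressed, fill_value=False)
    return float(1.0 - is_deg.mean())


def count_higher_in_all(
    expr: pd.DataFrame,
    genes,
    comparison_samples,
    reference_sample: str,
) -> int:
    """Number of genes strictly higher in every comparison sample than in the reference."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    for s in list(comparison_samples) + [reference_sample]:
        if s not in expr.columns:
            raise KeyError(f"unknown sample {s!r}")
    sub = expr.loc[genes]
    ref = sub[reference_sample].to_numpy(dtype=float)
    comp = sub[list(comparison_samples)].to_numpy(dtype=float)
    return int((comp > ref[:, None]).all(axis=1).sum())


@dataclass
class BiasSummary:
    """Per-hybrid bias fractions, each with its denominator recorded.

    ``frac_similar_*`` are over expressed genes; ``frac_deg`` over tested
    genes; category fractions over DEG trio genes; ``frac_equal_bias_*``
    over equal-to-one-parent genes.  Undefined fractions (zero
    denominator) are NaN.
    """

    hybrid_id: str
    frac_similar_p1: float
    frac_similar_p2: float
    frac_deg: float
    frac_equal_parent: float
    frac_over: float
    frac_between: float
    frac_equal_bias_p1: float
    frac_equal_bias_p2: float
    n_expressed: int
    n_tested: int
    n_deg: int
    n_equal_parent: int

    def as_dict(self) -> dict:
        return asdict(self)


def bias_summary(
    classification: pd.DataFrame,
    frac_similar_p1: float,
    frac_similar_p2: float,
    n_expressed: int,
    hybrid_id: str = "F1",
) -> BiasSummary:
    """Aggregate a per-gene trio classification into bias fractions."""
    cat = classification["category"]
    n_tested = len(cat)
    counts = cat.value_counts().reindex(CATEGORIES, fill_value=0)
    n_deg = int(n_tested - counts["non_deg"])
    n_equal = int(counts["equal_P1"] + counts["equal_P2"])

    def _frac(num, den):
        return float(num / den) if den > 0 else float("nan")

    return BiasSummary(
        hybrid_id=hybrid_id,
        frac_similar_p1=frac_similar_p1,
        frac_similar_p2=frac_similar_p2,
        frac_deg=_frac(n_deg, n_tested),
        frac_equal_parent=_frac(n_equal, n_deg),
        frac_over=_frac(counts["over_parents"], n_deg),
        frac_between=_frac(counts["between_parents"], n_deg),
        frac_equal_bias_p1=_frac(counts["equal_P1"], n_equal),
        frac_equal_bias_p2=_frac(counts["equal_P2"], n_equal),
        n_expressed=int(n_expressed),
        n_tested=int(n_tested),
        n_deg=n_deg,
        n_equal_parent=n_equal,
    )


def cluster_samples(
    expr: pd.DataFrame,
    distance: str = "correlation",
    linkage_method: str = "average",
    log_transform: bool = True,
):
    """Agglomerative clustering of samples by expression profile.

    Default distance is ``1 - Pearson correlation`` of ``log2(rpkm + 1)``
    profiles with average linkage.  Samples are ordered lexicographically
    before clustering so ties break deterministically.  Returns
    ``(linkage_matrix, ordered_sample_labels)``; serialize with
    :func:`linkage_to_newick`.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    expr = expr[sorted(expr.columns)]
    mat = expr.to_numpy(dtype=float).T
    if not np.isfinite(mat).all():
        raise ValueError("expression must be finite")
    if log_transform:
        mat = np.log2(mat + 1.0)
    if distance == "correlation":
        sd = mat.std(axis=1)
        if (sd == 0).any():
            bad = expr.columns[np.where(sd == 0)[0][0]]
            raise ValueError(f"zero-variance sample under correlation distance: {bad!r}")
        dmat = 1.0 - np.corrcoef(mat)
        np.fill_diagonal(dmat, 0.0)
        dmat = np.clip((dmat + dmat.T) / 2.0, 0.0, None)
        condensed = squareform(dmat, checks=False)
    elif distance == "euclidean":
        condensed = pdist(mat)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    Z = hierarchy.linkage(condensed, method=linkage_method)
    return Z, list(expr.columns)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a SciPy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def _fmt(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = _fmt(node.left, node.dist)
        right = _fmt(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    inner = f"({_fmt(tree.left, tree.dist)},{_fmt(tree.right, tree.dist)})"
    return inner + ";"
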