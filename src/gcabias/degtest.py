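"""Two-library differential expression: the Audic-Claverie exact count test
with Benjamini-Hochberg FDR control.

The test conditions on the count ``x`` observed in one library and asks how
surprising the count ``y`` in the other library is, given library sizes
``N1`` and ``N2``:

    p(y | x) = (N2/N1)**y * (x+y)! / (x! * y! * (1 + N2/N1)**(x+y+1))

which is the negative-binomial pmf NB(y; x+1, N1/(N1+N2)).  Tail sums are
evaluated through the regularized incomplete beta function, so arbitrarily
deep counts cost O(1).  A two-sided p-value doubles the smaller tail
(capped at 1).  No replication is assumed: each library is a single pooled
sample, as in designs where replicate plots are pooled before sequencing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import betainc, gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ac_probability",
    "ac_tail_probabilities",
    "ac_two_sided_p",
    "bh_fdr",
    "call_degs",
]


def _validate_counts(x, y, n1, n2):
    x = np.asarray(x)
    y = np.asarray(y)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative integers")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    return x.astype(float), y.astype(float)


def ac_probability(x, y, n1, n2):
    """p(y|x): probability of count ``y`` in library 2 given ``x`` in library 1.

    Computed in log space for stability; vectorizes over x/y.
    """
    x, y = _validate_counts(x, y, n1, n2)
    r = n2 / n1
    logp = (
        y * np.log(r)
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * np.log1p(r)
    )
    return np.exp(logp)


def ac_tail_probabilities(x, y, n1, n2):
    """(P(Y <= y | x), P(Y >= y | x)) under the conditional count model.

    Uses the negative-binomial / incomplete-beta identity
    P(Y <= y) = I_{N1/(N1+N2)}(x+1, y+1).
    """
    x, y = _validate_counts(x, y, n1, n2)
    p1 = n1 / (n1 + n2)
    lower = betainc(x + 1, y + 1, p1)
    upper = np.where(y > 0, betainc(np.maximum(y, 1), x + 1, 1.0 - p1), 1.0)
    return lower, upper


def ac_two_sided_p(x, y, n1, n2):
    """Two-sided Audic-Claverie p-value: 2 * min(lower, upper) tail, capped at 1."""
    lower, upper = ac_tail_probabilities(x, y, n1, n2)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    counts,
    sample_a: str,
    sample_b: str,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.05,
    use_raw_p: bool = False,
) -> pd.DataFrame:
    """Differential calls between two samples of a :class:`~gcabias.quant.CountMatrix`.

    A gene is differential iff its library-size-normalized fold change is
    *strictly* greater than ``fc_threshold`` and its BH q-value (or raw
    p-value when ``use_raw_p``) is below ``q_threshold``.  Genes with zero
    counts in both samples are excluded from testing; a gene with one zero
    and one positive count has infinite fold change (no pseudocount is
    added).  The BH family is all genes tested for this sample pair.

    Returns a DataFrame indexed by gene with columns ``count_a``,
    ``count_b``, ``fold_change``, ``direction`` (``a_higher`` /
    ``b_higher`` / ``none``), ``p_value``, ``q_value``, ``is_deg``.
    """
    if sample_a == sample_b:
        raise ValueError("the two samples must differ")
    for s in (sample_a, sample_b):
        if s not in counts.samples:
            raise KeyError(f"unknown sample {s!r}")
    xa = counts.counts[sample_a].to_numpy()
    xb = counts.counts[sample_b].to_numpy()
    tested = (xa > 0) | (xb > 0)
    xa, xb = xa[tested], xb[tested]
    genes = counts.gene_ids[tested]
    n1 = float(counts.lib_sizes[sample_a])
    n2 = float(counts.lib_sizes[sample_b])

    ra, rb = xa / n1, xb / n2
    hi, lo = np.maximum(ra, rb), np.minimum(ra, rb)
    fc = np.where(lo > 0, hi / np.where(lo > 0, lo, 1.0), np.inf)
    direction = np.where(ra > rb, "a_higher", np.where(rb > ra, "b_higher", "none"))

    p = ac_two_sided_p(xa, xb, n1, n2)
    q = bh_fdr(p)
    crit = p if use_raw_p else q
    is_deg = (fc > fc_threshold) & (crit < q_threshold)

    return pd.DataFrame(
        {
            "count_a": xa,
            "count_b": xb,
            "fold_change": fc,
            "direction": direction,
            "p_value": p,
            "q_value": q,
            "is_deg": is_deg,
        },
        index=genes,
    )
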