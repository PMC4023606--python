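"""Griffing fixed-effects combining-ability analysis for half diallels.

A half diallel crosses ``p`` inbred parents in all ``p*(p-1)/2`` pairwise
combinations without reciprocals.  The cell mean of cross ``i x j`` is
modeled as

    x_ij = mu + g_i + g_j + s_ij          (i != j)
    x_ii = mu + 2*g_i + s_ii              (parent selfs, Method 2 only)

with general combining abilities (GCA) ``g_i`` constrained to sum to zero
and specific combining abilities (SCA) ``s_ij`` under Griffing's
restrictions.  Method 2 analyses parents plus one set of F1s; Method 4
analyses crosses only.  Effects are fixed (Griffing's Model I); no
genotype-by-environment term is modeled — cell means are two-stage
averages, over replicates within an environment and then over
environments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import lstsq, null_space

__all__ = [
    "DiallelMeans",
    "CombiningAbilityResult",
    "cross_means",
    "gca_method2",
    "gca_method4",
    "least_squares_oracle",
    "parent_f1_correlation",
    "parent_f1_pairs",
]

_ZERO_TOL = 1e-9


@dataclass
class DiallelMeans:
    """Symmetric table of half-diallel cell means.

    ``cell_means`` is a p x p DataFrame (parents as index and columns,
    ``x_ij == x_ji``); the diagonal holds parent selfs and may be NaN when
    only crosses were phenotyped (Method 4).
    """

    cell_means: pd.DataFrame
    trait: str = ""

    def __post_init__(self) -> None:
        X = self.cell_means
        if X.shape[0] != X.shape[1] or not X.index.equals(X.columns):
            raise ValueError("cell_means must be square with matching labels")
        if self.p < 3:
            raise ValueError("a diallel needs at least 3 parents")
        a = X.to_numpy(dtype=float)
        off = ~np.eye(self.p, dtype=bool)
        if np.isnan(a[off]).any():
            i, j = np.argwhere(np.isnan(a) & off)[0]
            raise ValueError(
                f"incomplete diallel: missing cross {X.index[i]} x {X.columns[j]}"
            )
        if not np.allclose(a[off], a.T[off], equal_nan=True):
            raise ValueError("cell_means must be symmetric")

    @property
    def p(self) -> int:
        return self.cell_means.shape[0]

    @property
    def parents(self) -> pd.Index:
        return self.cell_means.index

    @property
    def has_diagonal(self) -> bool:
        return not np.isnan(np.diag(self.cell_means.to_numpy(dtype=float))).any()


@dataclass
class CombiningAbilityResult:
    mu: float
    g: pd.Series
    s: pd.DataFrame
    method: int
    trait: str = ""

    def __post_init__(self) -> None:
        assert abs(self.g.sum()) < _ZERO_TOL, "GCA effects must sum to zero"


def cross_means(records: pd.DataFrame, trait: str) -> DiallelMeans:
    """Aggregate long-format phenotype records into a diallel cell-mean table.

    ``records`` columns: ``parent_a``, ``parent_b``, ``env``, ``rep``,
    ``trait``, ``value``.  Reciprocal records (i,j) and (j,i) are pooled
    into one unordered cell.  Aggregation is two-stage and unweighted:
    mean over replicates within each environment, then mean over
    environments.
    """
    sub = records[records["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    a = sub["parent_a"].astype(str)
    b = sub["parent_b"].astype(str)
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    sub = sub.assign(_lo=lo, _hi=hi)
    env_means = sub.groupby(["_lo", "_hi", "env"], sort=True)["value"].mean()
    cell = env_means.groupby(["_lo", "_hi"]).mean()

    parents = sorted(set(lo) | set(hi))
    X = pd.DataFrame(np.nan, index=parents, columns=parents)
    for (i, j), v in cell.items():
        X.loc[i, j] = v
        X.loc[j, i] = v
    return DiallelMeans(cell_means=X, trait=trait)


def gca_method2(means: DiallelMeans) -> CombiningAbilityResult:
    """Griffing Method 2 (parents + one set of F1s), Model I, closed form.

    With ``T_i = sum_j x_ij`` (self counted once) and ``G`` the total over
    the p(p+1)/2 distinct cells:

        mu  = 2G / (p(p+1))
        g_i = (T_i + x_ii - 2G/p) / (p+2)
        s_ij = x_ij - (T_i + x_ii + T_j + x_jj)/(p+2) + 2G/((p+1)(p+2))

    equivalent to least squares under sum(g)=0 and, for each i,
    ``sum_j s_ij + s_ii = 0``.
    """
    if not means.has_diagonal:
        raise ValueError("Method 2 requires parent selfs on the diagonal")
    X = means.cell_means.to_numpy(dtype=float)
    p = means.p
    G = np.triu(X).sum()
    T = X.sum(axis=1)
    d = np.diag(X)
    mu = 2.0 * G / (p * (p + 1))
    g = (T + d - 2.0 * G / p) / (p + 2)
    g = g - g.mean()  # remove accumulated rounding; analytically zero-sum
    row = (T + d) / (p + 2)
    s = X - row[:, None] - row[None, :] + 2.0 * G / ((p + 1) * (p + 2))
    return CombiningAbilityResult(
        mu=mu,
        g=pd.Series(g, index=means.parents, name="gca"),
        s=pd.DataFrame(s, index=means.parents, columns=means.parents),
        method=2,
        trait=means.trait,
    )


def gca_method4(means: DiallelMeans) -> CombiningAbilityResult:
    """Griffing Method 4 (crosses only), Model I, closed form.

    With ``x_i. = sum_{j != i} x_ij`` and ``x.. = sum_{i<j} x_ij``:

        mu  = 2 x.. / (p(p-1))
        g_i = (p x_i. - 2 x..) / (p(p-2))
        s_ij = x_ij - mu - g_i - g_j
    """
    X = means.cell_means.to_numpy(dtype=float).copy()
    p = means.p
    np.fill_diagonal(X, 0.0)
    xi = X.sum(axis=1)
    xdd = np.triu(X).sum()
    mu = 2.0 * xdd / (p * (p - 1))
    g = (p * xi - 2.0 * xdd) / (p * (p - 2))
    g = g - g.mean()
    s = X - mu - g[:, None] - g[None, :]
    np.fill_diagonal(s, np.nan)
    return CombiningAbilityResult(
        mu=mu,
        g=pd.Series(g, index=means.parents, name="gca"),
        s=pd.DataFrame(s, index=means.parents, columns=means.parents),
        method=4,
        trait=means.trait,
    )


def least_squares_oracle(means: DiallelMeans, method: int = 2) -> CombiningAbilityResult:
    """Brute-force constrained least squares for the diallel model.

    Builds the full design matrix over the observed cells and solves
    ``min ||A theta - x||`` within the null space of the constraint matrix
    (zero-sum GCA; Griffing's SCA restrictions for the chosen method).
    Intended as an independent check of the closed-form estimators.
    """
    if method not in (2, 4):
        raise ValueError("method must be 2 or 4")
    if method == 2 and not means.has_diagonal:
        raise ValueError("Method 2 requires parent selfs on the diagonal")
    p = means.p
    X = means.cell_means.to_numpy(dtype=float)
    if method == 2:
        cells = [(i, j) for i in range(p) for j in range(i, p)]
    else:
        cells = [(i, j) for i in range(p) for j in range(i + 1, p)]
    sidx = {c: 1 + p + k for k, c in enumerate(cells)}
    nparam = 1 + p + len(cells)
    A = np.zeros((len(cells), nparam))
    b = np.empty(len(cells))
    for r, (i, j) in enumerate(cells):
        A[r, 0] = 1.0
        A[r, 1 + i] += 1.0
        A[r, 1 + j] += 1.0
        A[r, sidx[(i, j)]] = 1.0
        b[r] = X[i, j]
    constraints = [np.concatenate(([0.0], np.ones(p), np.zeros(len(cells))))]
    for i in range(p):
        row = np.zeros(nparam)
        for j in range(p):
            if i == j and method == 4:
                continue
            key = (min(i, j), max(i, j))
            row[sidx[key]] += 1.0
        if method == 2:
            row[sidx[(i, i)]] += 1.0  # self enters its own row twice
        constraints.append(row)
    N = null_space(np.asarray(constraints))
    coef, *_ = lstsq(A @ N, b)
    theta = N @ coef
    mu = theta[0]
    g = theta[1 : 1 + p]
    s = np.full((p, p), np.nan)
    for (i, j), k in sidx.items():
        s[i, j] = s[j, i] = theta[k]
    return CombiningAbilityResult(
        mu=mu,
        g=pd.Series(g - g.mean(), index=means.parents, name="gca"),
        s=pd.DataFrame(s, index=means.parents, columns=means.parents),
        method=method,
        trait=means.trait,
    )


def parent_f1_correlation(parent_values, f1_values):
    """Pearson correlation between parent and F1 phenotypes.

    Returns ``(r, p_value, n)``; the two-sided p-value comes from
    ``t = r*sqrt(n-2)/sqrt(1-r^2)`` on n-2 degrees of freedom.
    """
    x = np.asarray(parent_values, dtype=float)
    y = np.asarray(f1_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be paired 1-d vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, pval = stats.pearsonr(x, y)
    return float(r), float(pval), n


def parent_f1_pairs(
    records: pd.DataFrame,
    parent: str,
    scheme: str = "pooled-standardized-traits",
    partner_side: str = "co-parent",
):
    """Build (parent phenotype, F1 phenotype) pairs for one parent's crosses.

    For every cross involving ``parent`` and every trait, the F1 cell mean
    is paired with a parental phenotype: the co-parent's self value
    (``partner_side='co-parent'``) or ``parent``'s own self value
    (``partner_side='self'``).  Under the default pooled scheme each
    trait's parent and F1 values are z-standardized before pooling, so
    traits on different scales can share one correlation; ``scheme='per-trait'``
    returns a dict of per-trait pairs instead.
    """
    if scheme not in ("pooled-standardized-traits", "per-trait"):
        raise ValueError(f"unknown pairing scheme {scheme!r}")
    if partner_side not in ("co-parent", "self"):
        raise ValueError(f"unknown partner_side {partner_side!r}")
    traits = sorted(records["trait"].unique())
    per_trait: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for trait in traits:
        means = cross_means(records, trait)
        X = means.cell_means
        if parent not in X.index:
            raise KeyError(f"unknown parent {parent!r}")
        others = [q for q in X.index if q != parent]
        px = np.array(
            [X.loc[q, q] if partner_side == "co-parent" else X.loc[parent, parent] for q in others]
        )
        f1 = np.array([X.loc[parent, q] for q in others])
        per_trait[trait] = (px, f1)
    if scheme == "per-trait":
        return per_trait

    def _z(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    xs = np.concatenate([_z(px) for px, _ in per_trait.values()])
    ys = np.concatenate([_z(f1) for _, f1 in per_trait.values()])
    return xs, ys
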