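"""Synthetic data with known ground truth for every pipeline stage.

Four generators emulate the study design the pipeline targets:

* a half-diallel phenotype trial (``p`` inbred parents, all pairwise
  crosses without reciprocals, replicated plots in several environments)
  under the additive GCA + SCA + plot-error model;
* parent/parent/F1 ("trio") RNA-seq count matrices in which each gene's F1
  expectation follows one of the recognized categories — equal to the
  designated high-GCA parent, equal to the other parent, outside the
  parental range, or intermediate between the parents;
* non-overlapping gene models on synthetic chromosomes;
* gene-body ChIP-seq counts in which a tunable fraction of modified genes
  carries the designated parent's signal level in the F1.

Counts are negative binomial with variance ``m + dispersion * m**2``
(Poisson when ``dispersion == 0``), the usual RNA-seq overdispersion model
with a clean noise-free limit.  All generators take explicit seeds; there
is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .quant import CountMatrix

__all__ = [
    "DiallelSimParams",
    "TrioSimParams",
    "TrioSimResult",
    "ChipSimResult",
    "simulate_diallel_phenotypes",
    "simulate_trio_counts",
    "simulate_gene_models",
    "simulate_chip_counts",
]

TRIO_SAMPLES = ("P1", "P2", "F1")  # P1 is the designated high-GCA parent


@dataclass
class DiallelSimParams:
    """Ground truth for one trait of a half-diallel trial.

    ``g`` is recentred to sum to zero.  SCA effects are drawn once per
    cross from N(0, sca_sd^2) and held fixed across environments and
    replicates; plot error N(0, error_sd^2) is drawn per record.
    """

    p: int
    mu: float
    g: Sequence[float]
    sca_sd: float = 0.0
    error_sd: float = 0.0
    n_env: int = 1
    n_rep: int = 1
    seed: int = 0
    trait: str = "trait"

    def __post_init__(self) -> None:
        if self.p < 3:
            raise ValueError("p must be >= 3")
        g = np.asarray(self.g, dtype=float)
        if g.shape != (self.p,):
            raise ValueError("g must have length p")
        self.g = g - g.mean()
        if self.sca_sd < 0 or self.error_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_env < 1 or self.n_rep < 1:
            raise ValueError("n_env and n_rep must be >= 1")


def simulate_diallel_phenotypes(params: DiallelSimParams) -> pd.DataFrame:
    """Long-format phenotype records for a half diallel with parent selfs.

    One record per (cross-or-self, environment, replicate); the cell
    expectation is ``mu + g_i + g_j + s_ij`` for cross i x j and
    ``mu + 2 g_i + s_ii`` for parent i.
    """
    rng = np.random.default_rng(params.seed)
    p = params.p
    parents = [f"P{i+1}" for i in range(p)]
    pairs = [(i, j) for i in range(p) for j in range(i, p)]
    s = {pair: rng.normal(0.0, params.sca_sd) if params.sca_sd > 0 else 0.0 for pair in pairs}
    rows = []
    for i, j in pairs:
        expect = params.mu + params.g[i] + params.g[j] + s[(i, j)]
        for env in range(1, params.n_env + 1):
            for rep in range(1, params.n_rep + 1):
                noise = rng.normal(0.0, params.error_sd) if params.error_sd > 0 else 0.0
                rows.append(
                    {
                        "parent_a": parents[i],
                        "parent_b": parents[j],
                        "env": f"E{env}",
                        "rep": rep,
                        "trait": params.trait,
                        "value": expect + noise,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class TrioSimParams:
    """Ground truth for a parent/parent/F1 expression experiment.

    Category fractions refer to the F1's expected expression relative to
    the parents; the remainder ``1 - sum(fractions)`` of genes has all
    three means equal.  Parents differ by ``parent_fold`` on every
    differential gene, the direction (which parent is higher-expressed)
    drawn independently per gene so the two parental profiles decorrelate.
    ``over_multiple`` places out-of-range F1 means at that multiple of the
    higher parent (or, for half of the over genes, at the lower parent
    divided by it) so the category remains identifiable under a strict
    2-fold rule; intermediate genes sit at the geometric mid-parent.
    """

    n_genes: int = 2000
    frac_equal_high: float = 0.55
    frac_equal_low: float = 0.15
    frac_over: float = 0.10
    frac_between: float = 0.10
    dispersion: float = 0.01
    lib_sizes: float | Sequence[float] = 1e7
    length_range: tuple[int, int] = (500, 5000)
    parent_fold: float = 8.0
    over_multiple: float = 4.0
    base_rpkm_median: float = 10.0
    base_rpkm_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.frac_equal_high, self.frac_equal_low, self.frac_over, self.frac_between)
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("category fractions must lie in [0, 1]")
        if sum(fr) > 1 + 1e-12:
            raise ValueError("category fractions must sum to <= 1")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        libs = np.broadcast_to(np.asarray(self.lib_sizes, dtype=float), (3,))
        if (libs <= 0).any():
            raise ValueError("lib_sizes must be positive")
        self.lib_sizes = libs.copy()
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.parent_fold <= 1 or self.over_multiple <= 1:
            raise ValueError("parent_fold and over_multiple must exceed 1")


@dataclass
class TrioSimResult:
    counts: CountMatrix
    models: pd.DataFrame
    labels: pd.Series = None  # true category per gene, when requested
    expected_rpkm: pd.DataFrame = None


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, var = mean + dispersion*mean^2); Poisson when dispersion == 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(size_param, size_param / (size_param + mean[pos]))
    return out


def simulate_trio_counts(
    params: TrioSimParams, return_labels: bool = False
) -> TrioSimResult:
    """Counts for samples P1 (designated parent), P2, F1.

    Per differential gene, P1's expected RPKM is a log-normal base level
    ``a`` and P2's is ``a * parent_fold`` or ``a / parent_fold`` with equal
    probability.  The F1 expectation then follows the gene's category:
    the P1 value (``equal_P1``), the P2 value (``equal_P2``), the
    geometric mid-parent (``between_parents``), or outside the parental
    range by ``over_multiple`` (``over_parents``, above or below with
    equal probability).  Remainder genes have all three means at ``a``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    models = simulate_gene_models(
        n, params.length_range, seed=rng.integers(2**31)
    )
    lengths = (models["end"] - models["start"]).to_numpy(dtype=float)

    counts_per_cat = _category_counts(
        n,
        {
            "equal_P1": params.frac_equal_high,
            "equal_P2": params.frac_equal_low,
            "over_parents": params.frac_over,
            "between_parents": params.frac_between,
        },
    )
    labels = np.concatenate(
        [np.repeat(cat, k) for cat, k in counts_per_cat.items()]
    )
    rng.shuffle(labels)

    a = params.base_rpkm_median * rng.lognormal(0.0, params.base_rpkm_sigma, n)
    direction = np.where(rng.random(n) < 0.5, 1.0, -1.0)  # which parent is higher
    p1 = a.copy()
    p2 = np.where(labels == "non_deg", a, a * params.parent_fold**direction)
    hi, lo = np.maximum(p1, p2), np.minimum(p1, p2)
    f1 = np.empty(n)
    over_up = rng.random(n) < 0.5
    for cat, val in (
        ("equal_P1", p1),
        ("equal_P2", p2),
        ("between_parents", np.sqrt(p1 * p2)),
        ("non_deg", a),
    ):
        m = labels == cat
        f1[m] = val[m]
    m = labels == "over_parents"
    f1[m] = np.where(over_up[m], hi[m] * params.over_multiple, lo[m] / params.over_multiple)

    expected = pd.DataFrame(
        {"P1": p1, "P2": p2, "F1": f1}, index=models["gene_id"].to_numpy()
    )
    counts = {}
    for k, sample in enumerate(TRIO_SAMPLES):
        mean = expected[sample].to_numpy() * lengths * params.lib_sizes[k] / 1e9
        counts[sample] = _nb_draw(rng, mean, params.dispersion)
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=expected.index),
        lib_sizes=pd.Series(params.lib_sizes, index=list(TRIO_SAMPLES), dtype=float),
    )
    lab = pd.Series(labels, index=expected.index, name="category") if return_labels else None
    return TrioSimResult(counts=cm, models=models, labels=lab, expected_rpkm=expected)


def _category_counts(n: int, fractions: dict[str, float]) -> dict[str, int]:
    counts = {cat: int(round(f * n)) for cat, f in fractions.items()}
    used = sum(counts.values())
    if used > n:  # rounding overshoot: trim the largest category
        big = max(counts, key=counts.get)
        counts[big] -= used - n
        used = n
    counts["non_deg"] = n - used
    return counts


def simulate_gene_models(
    n_genes: int,
    length_range: tuple[int, int] = (500, 5000),
    seed: int = 0,
    genes_per_chrom: int = 1000,
    max_gap: int = 2000,
) -> pd.DataFrame:
    """Non-overlapping gene models laid out left to right on synthetic chromosomes.

    Returns a BED-like frame (``gene_id``, ``chrom``, ``start``, ``end``,
    ``strand``) in 0-based half-open coordinates; length = end - start is
    uniform on ``length_range``.
    """
    lo, hi = length_range
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if lo <= 0 or hi < lo:
        raise ValueError("length_range must satisfy 0 < min <= max")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    gaps = rng.integers(1, max_gap + 1, size=n_genes)
    rows = []
    pos = 0
    width = len(str(n_genes))
    for k in range(n_genes):
        chrom = f"chr{k // genes_per_chrom + 1}"
        if k % genes_per_chrom == 0:
            pos = 0
        start = pos + int(gaps[k])
        end = start + int(lengths[k])
        rows.append(
            {
                "gene_id": f"g{k + 1:0{width}d}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
        pos = end
    return pd.DataFrame(rows)


@dataclass
class ChipSimResult:
    counts: CountMatrix
    models: pd.DataFrame
    modified: pd.Series
    biased_to_designated: pd.Series


def simulate_chip_counts(
    models: pd.DataFrame,
    mark_bias_fraction: float,
    modified_fraction: float = 0.3,
    lib_sizes: float | Sequence[float] = 1e7,
    dispersion: float = 0.01,
    parent_fold: float = 4.0,
    signal_rpkm_median: float = 5.0,
    signal_rpkm_sigma: float = 0.5,
    background_mean: float = 0.2,
    seed: int = 0,
) -> ChipSimResult:
    """Gene-body ChIP counts for samples P1 (designated parent), P2, F1.

    ``modified_fraction`` of genes carry the mark (log-normal gene-body
    signal; P2 at ``1/parent_fold`` of P1).  Of those, ``mark_bias_fraction``
    have the F1 at P1's level and the rest at P2's level.  Unmodified genes
    see Poisson background at ``background_mean`` reads in every sample.
    """
    if not 0 <= mark_bias_fraction <= 1:
        raise ValueError("mark_bias_fraction must lie in [0, 1]")
    if not 0 <= modified_fraction <= 1:
        raise ValueError("modified_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(models)
    libs = np.broadcast_to(np.asarray(lib_sizes, dtype=float), (3,)).copy()
    lengths = (models["end"] - models["start"]).to_numpy(dtype=float)
    genes = models["gene_id"].to_numpy()

    modified = rng.random(n) < modified_fraction
    biased = rng.random(n) < mark_bias_fraction
    sig = signal_rpkm_median * rng.lognormal(0.0, signal_rpkm_sigma, n)
    rp1 = np.where(modified, sig, 0.0)
    rp2 = rp1 / parent_fold
    rf1 = np.where(biased, rp1, rp2)

    counts = {}
    for k, (sample, r) in enumerate(zip(TRIO_SAMPLES, (rp1, rp2, rf1))):
        mean = r * lengths * libs[k] / 1e9
        c = _nb_draw(rng, mean, dispersion)
        c = c + rng.poisson(background_mean, n)
        counts[sample] = c
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes),
        lib_sizes=pd.Series(libs, index=list(TRIO_SAMPLES), dtype=float),
    )
    return ChipSimResult(
        counts=cm,
        models=models,
        modified=pd.Series(modified, index=genes, name="modified"),
        biased_to_designated=pd.Series(
            np.where(modified, biased, False), index=genes, name="biased_to_designated"
        ),
    )
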