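import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcabias.diallel import (
    DiallelMeans,
    cross_means,
    gca_method2,
    gca_method4,
    least_squares_oracle,
    parent_f1_correlation,
    parent_f1_pairs,
)


def _means_from_array(X, parents=None):
    p = X.shape[0]
    parents = parents or [f"P{i+1}" for i in range(p)]
    return DiallelMeans(pd.DataFrame(X, index=parents, columns=parents, dtype=float))


def _random_table(rng, p, with_diagonal=True):
    X = rng.normal(50, 10, (p, p))
    X = (X + X.T) / 2
    if not with_diagonal:
        np.fill_diagonal(X, np.nan)
    return _means_from_array(X)


NOISE_FREE_P3 = np.array([[12.0, 11.0, 10.0], [11.0, 10.0, 9.0], [10.0, 9.0, 8.0]])


class TestCrossMeans:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["parent_a", "parent_b", "env", "rep", "trait", "value"])

    def test_single_record_per_cell(self):
        rec = self._records(
            [
                ("A", "A", "E1", 1, "t", 5.0),
                ("A", "B", "E1", 1, "t", 7.0),
                ("A", "C", "E1", 1, "t", 6.0),
                ("B", "B", "E1", 1, "t", 3.0),
                ("B", "C", "E1", 1, "t", 4.0),
                ("C", "C", "E1", 1, "t", 2.0),
            ]
        )
        m = cross_means(rec, "t")
        assert m.cell_means.loc["A", "B"] == 7.0
        assert m.cell_means.loc["C", "C"] == 2.0

    def test_two_stage_unweighted_mean(self):
        # env A has reps (10, 20) -> 15; env B has (30,) -> 30; cell = 22.5
        rows = [
            ("A", "B", "E1", 1, "t", 10.0),
            ("A", "B", "E1", 2, "t", 20.0),
            ("A", "B", "E2", 1, "t", 30.0),
        ]
        # complete the diallel so validation passes
        for pair in [("A", "A"), ("B", "B"), ("C", "C"), ("A", "C"), ("B", "C")]:
            rows.append((*pair, "E1", 1, "t", 1.0))
        m = cross_means(self._records(rows), "t")
        assert m.cell_means.loc["A", "B"] == pytest.approx(22.5)

    def test_reciprocals_pooled(self):
        rows = [
            ("A", "B", "E1", 1, "t", 10.0),
            ("B", "A", "E1", 2, "t", 20.0),
        ]
        for pair in [("A", "A"), ("B", "B"), ("C", "C"), ("A", "C"), ("B", "C")]:
            rows.append((*pair, "E1", 1, "t", 1.0))
        m = cross_means(self._records(rows), "t")
        assert m.cell_means.loc["A", "B"] == pytest.approx(15.0)
        assert m.cell_means.loc["B", "A"] == pytest.approx(15.0)

    def test_missing_cross_named_in_error(self):
        rows = [
            ("A", "A", "E1", 1, "t", 5.0),
            ("B", "B", "E1", 1, "t", 3.0),
            ("C", "C", "E1", 1, "t", 2.0),
            ("A", "B", "E1", 1, "t", 7.0),
            ("A", "C", "E1", 1, "t", 6.0),
        ]
        with pytest.raises(ValueError, match="B x C"):
            cross_means(self._records(rows), "t")


class TestMethod2:
    def test_noise_free_p3_recovery(self):
        res = gca_method2(_means_from_array(NOISE_FREE_P3))
        assert res.mu == pytest.approx(10.0, abs=1e-12)
        np.testing.assert_allclose(res.g.to_numpy(), [1.0, 0.0, -1.0], atol=1e-12)
        np.testing.assert_allclose(res.s.to_numpy(), 0.0, atol=1e-12)

    def test_constant_table_gives_zero_effects(self):
        res = gca_method2(_means_from_array(np.full((4, 4), 7.0)))
        assert res.mu == pytest.approx(7.0)
        np.testing.assert_allclose(res.g.to_numpy(), 0.0, atol=1e-12)
        np.testing.assert_allclose(res.s.to_numpy(), 0.0, atol=1e-12)

    def test_location_invariance(self, rng):
        m = _random_table(rng, 5)
        shifted = DiallelMeans(m.cell_means + 13.5)
        r0, r1 = gca_method2(m), gca_method2(shifted)
        assert r1.mu == pytest.approx(r0.mu + 13.5)
        np.testing.assert_allclose(r0.g.to_numpy(), r1.g.to_numpy(), atol=1e-9)
        np.testing.assert_allclose(r0.s.to_numpy(), r1.s.to_numpy(), atol=1e-9)

    def test_label_permutation_equivariance(self, rng):
        m = _random_table(rng, 5)
        perm = ["P3", "P1", "P5", "P2", "P4"]
        permuted = DiallelMeans(m.cell_means.loc[perm, perm])
        r0, r1 = gca_method2(m), gca_method2(permuted)
        for parent in perm:
            assert r1.g[parent] == pytest.approx(r0.g[parent])

    def test_requires_diagonal(self, rng):
        with pytest.raises(ValueError, match="diagonal"):
            gca_method2(_random_table(rng, 4, with_diagonal=False))


class TestMethod4:
    def test_hand_computed_p3(self):
        X = np.array([[np.nan, 11.0, 10.0], [11.0, np.nan, 9.0], [10.0, 9.0, np.nan]])
        res = gca_method4(_means_from_array(X))
        # x1.=21, x2.=20, x3.=19, x..=30 -> g = (3*x_i. - 2*x..)/3
        assert res.mu == pytest.approx(10.0)
        np.testing.assert_allclose(res.g.to_numpy(), [1.0, 0.0, -1.0], atol=1e-12)

    def test_constant_crosses(self):
        X = np.full((5, 5), 4.0)
        np.fill_diagonal(X, np.nan)
        res = gca_method4(_means_from_array(X))
        assert res.mu == pytest.approx(4.0)
        np.testing.assert_allclose(res.g.to_numpy(), 0.0, atol=1e-12)

    def test_sca_row_sums_vanish(self, rng):
        res = gca_method4(_random_table(rng, 6, with_diagonal=False))
        s = res.s.to_numpy().copy()
        np.fill_diagonal(s, 0.0)
        np.testing.assert_allclose(s.sum(axis=1), 0.0, atol=1e-9)


class TestOracleAgreement:
    """Closed-form estimators must match brute-force constrained least squares."""

    @pytest.mark.parametrize("method", [2, 4])
    def test_random_tables(self, method):
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = int(rng.integers(3, 9))
            m = _random_table(rng, p, with_diagonal=(method == 2))
            est = gca_method2(m) if method == 2 else gca_method4(m)
            ora = least_squares_oracle(m, method)
            assert abs(est.mu - ora.mu) < 1e-8
            np.testing.assert_allclose(est.g.to_numpy(), ora.g.to_numpy(), atol=1e-8)
            mask = ~np.isnan(est.s.to_numpy())
            np.testing.assert_allclose(
                est.s.to_numpy()[mask], ora.s.to_numpy()[mask], atol=1e-8
            )

    def test_gca_sums_to_zero(self, rng):
        for p in (3, 5, 8):
            res = gca_method2(_random_table(rng, p))
            assert abs(res.g.sum()) < 1e-9


class TestParentF1Correlation:
    def test_perfect_linear_relation(self):
        x = np.arange(1.0, 7.0)
        r, p, n = parent_f1_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert n == 6

    def test_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.8])
        r, p, n = parent_f1_correlation(x, y)
        direct = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(direct, abs=1e-12)
        # two-sided p from the t transform
        from scipy import stats

        t = direct * np.sqrt(n - 2) / np.sqrt(1 - direct**2)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), n - 2), rel=1e-9)

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            parent_f1_correlation([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_pairs_builder_schemes(self):
        from gcabias.synthetic import DiallelSimParams, simulate_diallel_phenotypes

        records = pd.concat(
            [
                simulate_diallel_phenotypes(
                    DiallelSimParams(p=4, mu=m, g=[2, 1, -1, -2], error_sd=0.5,
                                     seed=s, trait=t)
                )
                for s, (t, m) in enumerate([("h", 100.0), ("d", 80.0)])
            ],
            ignore_index=True,
        )
        per_trait = parent_f1_pairs(records, "P1", scheme="per-trait")
        assert set(per_trait) == {"h", "d"}
        assert all(len(px) == 3 for px, _ in per_trait.values())
        xs, ys = parent_f1_pairs(records, "P1")
        assert len(xs) == len(ys) == 6  # 3 crosses x 2 traits, pooled z-scores
        assert abs(xs.mean()) < 1e-9


@settings(derandomize=True, max_examples=25)
@given(shift=st.floats(-100, 100), seed=st.integers(0, 1000))
def test_method4_location_invariance_property(shift, seed):
    rng = np.random.default_rng(seed)
    m = _random_table(rng, 5, with_diagonal=False)
    shifted = DiallelMeans(m.cell_means + shift)
    r0, r1 = gca_method4(m), gca_method4(shifted)
    assert r1.mu == pytest.approx(r0.mu + shift, abs=1e-8)
    np.testing.assert_allclose(r0.g.to_numpy(), r1.g.to_numpy(), atol=1e-8)
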