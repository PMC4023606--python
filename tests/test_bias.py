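import itertools

import numpy as np
import pandas as pd
import pytest

from gcabias.bias import (
    bias_summary,
    classify_trio,
    closer_parent,
    cluster_samples,
    count_higher_in_all,
    linkage_to_newick,
    similarity_to_parent,
)

GA_GENES = ["OsCPS1", "OsKAO", "OsGA3ox2", "OsGA20ox2", "OsGA2ox6"]


def _deg_frame(genes, flags):
    return pd.DataFrame({"is_deg": list(flags)}, index=list(genes))


class TestClassifyTrio:
    def oracle(self, sig1, sig2, position):
        """Independent truth table: significance flags x range position."""
        if not sig1 and not sig2:
            return "non_deg"
        if sig1 and not sig2:
            return "equal_P2"
        if sig2 and not sig1:
            return "equal_P1"
        return "over_parents" if position == "outside" else "between_parents"

    @pytest.mark.parametrize(
        "sig1, sig2, position",
        list(itertools.product([False, True], [False, True], ["below", "inside", "above"])),
    )
    def test_truth_table(self, sig1, sig2, position):
        f1 = {"below": 0.5, "inside": 5.0, "above": 30.0}[position]
        expr = pd.DataFrame({"P1": [2.0], "P2": [10.0], "F1": [f1]}, index=["g"])
        out = classify_trio(_deg_frame(["g"], [sig1]), _deg_frame(["g"], [sig2]), expr)
        expected = self.oracle(sig1, sig2, "outside" if position != "inside" else "inside")
        assert out.loc["g", "category"] == expected

    def test_published_ga20ox2_levels_fall_between_parents(self, pathway_rpkm):
        # GL 12.92, TQ 3.15, F1(GLxTQ) 9.36: inside the parental range
        row = pathway_rpkm.loc["OsGA20ox2"]
        expr = pd.DataFrame(
            {"P1": [row["GL"]], "P2": [row["TQ"]], "F1": [row["GLxTQ"]]}, index=["g"]
        )
        out = classify_trio(_deg_frame(["g"], [True]), _deg_frame(["g"], [True]), expr)
        assert out.loc["g", "category"] == "between_parents"

    def test_boundary_value_counts_as_inside(self):
        expr = pd.DataFrame({"P1": [2.0], "P2": [10.0], "F1": [10.0]}, index=["g"])
        out = classify_trio(_deg_frame(["g"], [True]), _deg_frame(["g"], [True]), expr)
        assert out.loc["g", "category"] == "between_parents"

    def test_missing_expression_is_error(self):
        expr = pd.DataFrame({"P1": [], "P2": [], "F1": []})
        with pytest.raises(ValueError, match="missing"):
            classify_trio(_deg_frame(["g"], [True]), _deg_frame(["g"], [True]), expr)

    def test_partition_is_exhaustive_and_exclusive(self, rng):
        n = 200
        genes = [f"g{i}" for i in range(n)]
        expr = pd.DataFrame(
            rng.lognormal(1, 1, (n, 3)), index=genes, columns=["P1", "P2", "F1"]
        )
        d1 = _deg_frame(genes, rng.random(n) < 0.5)
        d2 = _deg_frame(genes, rng.random(n) < 0.5)
        out = classify_trio(d1, d2, expr)
        assert len(out) == n
        counts = out["category"].value_counts()
        deg_total = counts.drop("non_deg", errors="ignore").sum()
        both_sig = (d1["is_deg"] | d2["is_deg"]).sum()
        assert deg_total == both_sig


class TestCloserParent:
    def test_exact_match_wins(self):
        assert closer_parent(5.0, 9.0, 5.0) == "P1"

    def test_published_osprr1_is_closer_to_tq(self, pathway_rpkm):
        row = pathway_rpkm.loc["OsPRR1"]
        # P1=GL 35.49, P2=TQ 92.53, F1 122.26: log-ratio distance favors TQ
        assert closer_parent(row["GL"], row["TQ"], row["GLxTQ"]) == "P2"

    def test_equal_parents_tie(self):
        assert closer_parent(4.0, 4.0, 7.0) == "tie"

    def test_all_zero_undefined(self):
        assert closer_parent(0.0, 0.0, 0.0) == "undefined"

    def test_zero_handling_uses_epsilon(self):
        assert closer_parent(0.0, 10.0, 0.0, eps=0.05) == "P1"


class TestSimilarity:
    def test_no_degs_means_full_similarity(self):
        calls = _deg_frame(["a", "b", "c"], [False, False, False])
        assert similarity_to_parent(calls, pd.Index(["a", "b", "c"])) == 1.0

    def test_simple_fraction(self):
        calls = _deg_frame(list("abcdefghij"), [True] * 3 + [False] * 7)
        assert similarity_to_parent(calls, pd.Index(list("abcdefghij"))) == pytest.approx(0.7)

    def test_untested_expressed_genes_count_as_similar(self):
        calls = _deg_frame(["a"], [True])
        assert similarity_to_parent(calls, pd.Index(["a", "b"])) == pytest.approx(0.5)

    def test_empty_expressed_set_is_error(self):
        with pytest.raises(ValueError):
            similarity_to_parent(_deg_frame(["a"], [False]), pd.Index([]))


class TestCountHigherInAll:
    def test_published_ga_pathway_direction(self, pathway_rpkm):
        """Three GA-pathway genes exceed the GL level in both positive-GCA
        parents and both hybrids derived from them."""
        expr = pathway_rpkm.drop(columns="pathway")
        n = count_higher_in_all(
            expr, GA_GENES, ["TQ", "93-11", "GLxTQ", "GLx93-11"], "GL"
        )
        assert n == 3

    def test_self_reference_never_counts(self, pathway_rpkm):
        expr = pathway_rpkm.drop(columns="pathway")
        assert count_higher_in_all(expr, GA_GENES, ["GL", "TQ"], "GL") == 0

    def test_all_zero_rows_never_counted(self):
        expr = pd.DataFrame({"A": [0.0], "B": [0.0], "C": [0.0]}, index=["g"])
        assert count_higher_in_all(expr, ["g"], ["A", "B"], "C") == 0

    def test_empty_gene_set_is_error(self, pathway_rpkm):
        with pytest.raises(ValueError):
            count_higher_in_all(pathway_rpkm, [], ["TQ"], "GL")


class TestBiasSummary:
    def _classification(self, cats):
        return pd.DataFrame(
            {"category": cats, "closer_parent": "P1"},
            index=[f"g{i}" for i in range(len(cats))],
        )

    def test_hand_computed_fractions(self):
        cats = ["equal_P1"] * 6 + ["equal_P2"] * 2 + ["over_parents", "between_parents"]
        s = bias_summary(self._classification(cats), 0.9, 0.8, n_expressed=100)
        assert s.frac_equal_parent == pytest.approx(0.8)
        assert s.frac_equal_bias_p1 == pytest.approx(0.75)
        assert s.frac_equal_bias_p2 == pytest.approx(0.25)
        assert s.frac_over == pytest.approx(0.1)
        assert s.frac_deg == pytest.approx(1.0)
        assert s.frac_equal_bias_p1 + s.frac_equal_bias_p2 == pytest.approx(1.0)

    def test_category_fractions_partition_degs(self):
        cats = ["equal_P1"] * 5 + ["over_parents"] * 3 + ["between_parents"] * 2 + ["non_deg"] * 10
        s = bias_summary(self._classification(cats), 1.0, 1.0, n_expressed=20)
        assert s.n_deg == 10
        assert s.frac_equal_parent + s.frac_over + s.frac_between == pytest.approx(1.0)

    def test_non_deg_only_gives_undefined_categories(self):
        s = bias_summary(self._classification(["non_deg"] * 5), 1.0, 1.0, n_expressed=5)
        assert s.frac_deg == 0.0
        assert np.isnan(s.frac_equal_parent)
        assert np.isnan(s.frac_equal_bias_p1)


class TestClusterSamples:
    def test_duplicate_samples_merge_first_at_zero_height(self, rng):
        prof = rng.lognormal(1, 1, 50)
        expr = pd.DataFrame(
            {"A": prof, "B": prof, "C": rng.lognormal(1, 1, 50)},
            index=[f"g{i}" for i in range(50)],
        )
        Z, labels = cluster_samples(expr)
        first = sorted(labels[int(Z[0, 0])] + labels[int(Z[0, 1])])
        assert "".join(first) == "AB"
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_three_sample_topology(self):
        # construct profiles with d(A,B) < d(A,C) = d(B,C)
        base = np.linspace(1, 10, 40)
        expr = pd.DataFrame(
            {
                "A": base,
                "B": base + np.sin(np.arange(40)) * 0.1,
                "C": base[::-1],
            }
        )
        Z, labels = cluster_samples(expr, log_transform=False)
        newick = linkage_to_newick(Z, labels)
        start = newick.rindex("(")
        inner = newick[start + 1 : newick.index(")", start)]
        assert set(x.split(":")[0] for x in inner.split(",")) == {"A", "B"}

    def test_zero_variance_sample_named_in_error(self):
        expr = pd.DataFrame({"A": [1.0, 2.0], "B": [3.0, 3.0]})
        with pytest.raises(ValueError, match="B"):
            cluster_samples(expr)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            cluster_samples(pd.DataFrame({"A": [1.0, 2.0]}))
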