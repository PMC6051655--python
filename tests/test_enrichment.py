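import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retrotime import (
    RepeatLocus,
    build_taxonomy,
    class_enrichment,
    fisher_exact_2x2,
    ora_gmt,
    read_gmt,
)
from retrotime.synthetic_data import simulate_gmt, write_gmt


def enumeration_p(a, b, c, d, sided="two"):
    """Brute-force hypergeometric enumeration with exact binomials."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = math.comb(n, row1)

    def prob(k):
        return math.comb(col1, k) * math.comb(n - col1, row1 - k) / denom

    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    p_obs = prob(a)
    if sided == "two":
        return sum(prob(k) for k in range(lo, hi + 1)
                   if prob(k) <= p_obs * (1 + 1e-12))
    return sum(prob(k) for k in range(a, hi + 1))


class TestFisher2x2:
    def test_balanced_table(self):
        p, odds = fisher_exact_2x2(5, 5, 5, 5)
        assert p == pytest.approx(1.0) and odds == pytest.approx(1.0)

    def test_extreme_table_closed_form(self):
        """[[10,0],[0,10]]: only the two corner tables are as extreme, so
        two-sided p = 2 / C(20,10)."""
        p, _ = fisher_exact_2x2(10, 0, 0, 10)
        assert p == pytest.approx(2 / math.comb(20, 10), abs=1e-12)

    @pytest.mark.parametrize("table", [
        (3, 7, 2, 8), (0, 5, 5, 0), (1, 1, 1, 1), (12, 3, 4, 11),
        (0, 0, 3, 5), (6, 0, 2, 9),
    ])
    def test_matches_enumeration(self, table):
        for sided in ("two", "greater"):
            p, _ = fisher_exact_2x2(*table, sided=sided)
            assert p == pytest.approx(enumeration_p(*table, sided=sided),
                                      abs=1e-10)

    @settings(deadline=None, max_examples=100)
    @given(st.tuples(st.integers(0, 12), st.integers(0, 12),
                     st.integers(0, 12), st.integers(0, 12)))
    def test_transpose_invariance(self, table):
        a, b, c, d = table
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        p1, _ = fisher_exact_2x2(a, b, c, d)
        p2, _ = fisher_exact_2x2(a, c, b, d)
        assert p1 == pytest.approx(p2, abs=1e-10)

    def test_haldane_correction_on_zero_cell(self):
        _, odds = fisher_exact_2x2(4, 0, 2, 6)
        assert odds == pytest.approx((4.5 * 6.5) / (0.5 * 2.5))

    def test_negative_cell_errors(self):
        with pytest.raises(ValueError, match="negative"):
            fisher_exact_2x2(-1, 2, 3, 4)


@pytest.fixture(scope="module")
def toy_taxonomy():
    loci = []
    i = 0
    for cls, fam, n in [("LTR", "ERVK", 150), ("LINE", "L1", 300),
                        ("SINE", "Alu", 450), ("DNA", "hAT", 100)]:
        for _ in range(n):
            loci.append(RepeatLocus("chr1", i * 10, i * 10 + 5, "+",
                                    f"{cls}_{i}", fam, cls))
            i += 1
    return build_taxonomy(loci)


class TestClassEnrichment:
    def test_set_equal_to_background_is_flat(self, toy_taxonomy):
        sets = {"all": toy_taxonomy.subfamilies()}
        out = class_enrichment(sets, toy_taxonomy)
        assert np.allclose(out["p"], 1.0)

    def test_planted_ltr_bias_recovered(self):
        """Background 1000 subfamilies, 15% LTR; an up-set of 100 holding 60
        LTR members must flag LTR with OR > 1 at p < 0.001."""
        rng = np.random.default_rng(30)
        loci = []
        classes = ["LTR"] * 150 + ["SINE"] * 850
        for i, cls in enumerate(classes):
            loci.append(RepeatLocus("chr1", i * 10, i * 10 + 5, "+",
                                    f"SF{i:04d}", cls, cls))
        tax = build_taxonomy(loci)
        ltr = sorted(tax.members("class_", "LTR"))
        sine = sorted(tax.members("class_", "SINE"))
        up = (list(rng.choice(ltr, 60, replace=False))
              + list(rng.choice(sine, 40, replace=False)))
        out = class_enrichment({"up": up}, tax)
        row = out[(out["set"] == "up") & (out["category"] == "LTR")].iloc[0]
        assert row["odds_ratio"] > 1 and row["p"] < 0.001
        assert row["flag"] == "***"

    def test_2x2_margins(self, toy_taxonomy):
        sets = {"s": sorted(toy_taxonomy.members("class_", "LTR"))[:50]}
        out = class_enrichment(sets, toy_taxonomy)
        n_bg = toy_taxonomy.n_subfamilies
        for _, row in out.iterrows():
            assert row["a"] + row["b"] == 50
            assert row["a"] + row["b"] + row["c"] + row["d"] == n_bg

    def test_disjoint_cluster_a_values_sum(self, toy_taxonomy):
        subfams = toy_taxonomy.subfamilies()
        clusters = {"c1": subfams[:100], "c2": subfams[100:250]}
        out = class_enrichment(clusters, toy_taxonomy)
        union = set(clusters["c1"]) | set(clusters["c2"])
        for cls in ["LTR", "LINE", "SINE", "DNA"]:
            total = sum(out[(out["set"] == s) & (out["category"] == cls)]
                        ["a"].iloc[0] for s in clusters)
            expected = len(toy_taxonomy.members("class_", cls) & union)
            assert total == expected

    def test_empty_set_errors(self, toy_taxonomy):
        with pytest.raises(ValueError, match="empty"):
            class_enrichment({"s": []}, toy_taxonomy)

    def test_unknown_member_errors(self, toy_taxonomy):
        with pytest.raises(KeyError, match="nonexistent"):
            class_enrichment({"s": ["nonexistent"]}, toy_taxonomy)

    def test_bh_monotone_in_rank(self, toy_taxonomy):
        sets = {"s": sorted(toy_taxonomy.members("class_", "LTR"))[:50]}
        out = class_enrichment(sets, toy_taxonomy).sort_values("p")
        assert (np.diff(out["p_adj"].to_numpy()) >= -1e-12).all()


class TestOraGmt:
    def test_single_gene_single_set(self):
        background = [f"G{i}" for i in range(100)]
        gmt = {"S": {"G0"}}
        out = ora_gmt(["G0"], background, gmt)
        # drawing 1 gene from 100 with 1 in the set: p = 1/100
        assert out["p"].iloc[0] == pytest.approx(0.01, abs=1e-12)

    def test_disjoint_set_not_enriched(self):
        background = [f"G{i}" for i in range(100)]
        gmt = {"S": {"G90", "G91", "G92"}}
        out = ora_gmt([f"G{i}" for i in range(20)], background, gmt)
        assert out["odds_ratio"].iloc[0] <= 1
        assert out["p"].iloc[0] >= 0.5

    def test_enriched_set_top_ranked(self):
        sets, gene_list, background = simulate_gmt(seed=31)
        out = ora_gmt(gene_list, background, sets)
        assert out["gene_set"].iloc[0] == "SET_3"
        assert bool(out["significant"].iloc[0])
        assert (out.loc[out["significant"], "p_adj"] < 0.05).all()

    def test_gene_outside_background_errors(self):
        with pytest.raises(ValueError, match="outside background"):
            ora_gmt(["X"], ["A", "B"], {"S": {"A"}})

    def test_gmt_file_roundtrip_and_errors(self, tmp_path):
        sets, _, _ = simulate_gmt(n_sets=3, enriched_set=1, seed=32)
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets
        bad = tmp_path / "bad.gmt"
        bad.write_text("SET_A\tdesc\tG1\nBROKEN_LINE\n")
        with pytest.raises(ValueError, match=":2"):
            read_gmt(bad)
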