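"""Overrepresentation statistics against brute-force and permutation oracles."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dipackit as dk
from dipackit.io import read_gmt, write_gmt


def hypergeom_tail_oracle(overlap, n_universe, n_set, n_selection):
    """Brute-force upper tail by direct pmf enumeration with binomials."""
    total = comb(n_universe, n_selection)
    return sum(
        comb(n_set, k) * comb(n_universe - n_set, n_selection - k)
        for k in range(overlap, min(n_set, n_selection) + 1)
    ) / total


def make_universe(n):
    return [f"g{i}" for i in range(n)]


class TestHypergeometric:
    def test_worked_example_matches_enumeration(self):
        """N=20, K=5, n=6, overlap=4: enumerated tail ~ 0.01393."""
        universe = make_universe(20)
        gene_set = universe[:5]
        selection = universe[1:5] + universe[10:12]  # overlap 4
        overlap, odds, p = dk.hypergeometric_enrichment(selection, gene_set, universe)
        assert overlap == 4
        expected = hypergeom_tail_oracle(4, 20, 5, 6)
        assert expected == pytest.approx(0.0139318885, rel=1e-8)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_disjoint_selection_p_one(self):
        universe = make_universe(30)
        _, _, p = dk.hypergeometric_enrichment(universe[:5], universe[10:15], universe)
        assert p == pytest.approx(1.0)

    def test_degenerate_everything_overlaps(self):
        universe = make_universe(8)
        overlap, _, p = dk.hypergeometric_enrichment(universe, universe, universe)
        assert overlap == 8
        assert p == pytest.approx(1.0)

    def test_subset_violation_rejected(self):
        with pytest.raises(ValueError):
            dk.hypergeometric_enrichment(["x"], ["g0"], make_universe(5))
        with pytest.raises(ValueError):
            dk.hypergeometric_enrichment([], [], [])

    def test_monotone_in_overlap_at_fixed_margins(self):
        universe = make_universe(100)
        ps = []
        for k in range(0, 21):
            gene_set = universe[:20]
            selection = universe[:k] + universe[50 : 50 + 30 - k]
            _, _, p = dk.hypergeometric_enrichment(selection, gene_set, universe)
            ps.append(p)
        assert all(p1 >= p2 - 1e-15 for p1, p2 in zip(ps[:-1], ps[1:]))

    def test_agrees_with_permutation_null(self):
        """Empirical tail over 20,000 random selections within 3 MC errors."""
        rng = np.random.default_rng(2024)
        n_universe, n_set, n_selection, observed = 20, 5, 6, 3
        p_exact = hypergeom_tail_oracle(observed, n_universe, n_set, n_selection)
        draws = np.zeros(20000)
        idx = np.arange(n_universe)
        for i in range(20000):
            sel = rng.choice(idx, size=n_selection, replace=False)
            draws[i] = (sel < n_set).sum()
        p_perm = (draws >= observed).mean()
        mc_se = np.sqrt(p_exact * (1 - p_exact) / 20000)
        assert abs(p_perm - p_exact) < 3 * mc_se


class TestFisherUnion:
    def test_cross_product_odds_ratio(self):
        """Table [[10,90],[5,895]]: OR = 10*895/(90*5) ~ 19.89."""
        universe = make_universe(1000)
        targets = universe[:100]  # a + b
        union = universe[:10] + universe[100:105]  # a=10 in targets, c=5 outside
        odds, p = dk.fisher_union_test(union, targets, universe)
        assert odds == pytest.approx((10 * 895) / (90 * 5), rel=1e-12)
        assert 0.0 < p < 1.0

    def test_empty_margin_flags_undefined_or(self):
        universe = make_universe(50)
        with pytest.warns(UserWarning, match="margin"):
            odds, p = dk.fisher_union_test(universe[:10], [], universe)
        assert np.isnan(odds)
        assert p == pytest.approx(1.0)

    def test_one_sided_fisher_equals_hypergeometric_tail(self):
        """Exact identity on random 2x2 tables (both are the same tail sum)."""
        rng = np.random.default_rng(5)
        for _ in range(300):
            n_universe = int(rng.integers(10, 200))
            n_set = int(rng.integers(1, n_universe))
            n_sel = int(rng.integers(1, n_universe))
            a_max = min(n_set, n_sel)
            a_min = max(0, n_set + n_sel - n_universe)
            a = int(rng.integers(a_min, a_max + 1))
            table = [
                [a, n_set - a],
                [n_sel - a, n_universe - n_set - n_sel + a],
            ]
            _, p_fisher = stats.fisher_exact(table, alternative="greater")
            p_hyper = stats.hypergeom.sf(a - 1, n_universe, n_set, n_sel)
            assert p_fisher == pytest.approx(p_hyper, abs=1e-12)

    def test_uniform_p_under_independence(self):
        """Two-sided Fisher p is stochastically >= uniform under the null."""
        rng = np.random.default_rng(99)
        pvals = []
        universe = make_universe(200)
        for _ in range(300):
            union = list(rng.choice(universe, size=40, replace=False))
            targets = list(rng.choice(universe, size=30, replace=False))
            _, p = dk.fisher_union_test(union, targets, universe)
            pvals.append(p)
        # discrete exact tests are conservative: empirical CDF below the diagonal
        pvals = np.sort(pvals)
        ecdf = np.arange(1, 301) / 300
        assert (pvals >= ecdf - 0.12).all()  # KS-style band at n=300


class TestEnrichCollection:
    def test_planted_set_minimizes_p_in_its_dpg(self, planted_run):
        truth, result = planted_run["truth"], planted_run["result"]
        coll = dk.generate_gene_sets(truth, n_decoy_sets=10, set_size=40, seed=5)
        table = dk.enrich_collection(result, coll, dpgs=[7, 8], alpha=0.001)
        for dpg in (7, 8):
            col = table[table["dpg"] == dpg].set_index("set")
            assert col["pvalue"].idxmin() == f"DPG{dpg}_signature"
            assert col.loc[f"DPG{dpg}_signature", "significant"]

    def test_bh_runs_within_dpg_family(self, planted_run):
        truth, result = planted_run["truth"], planted_run["result"]
        coll = dk.generate_gene_sets(truth, n_decoy_sets=5, set_size=30, seed=6)
        table = dk.enrich_collection(result, coll, dpgs=[8], alpha=0.05)
        sub = table[table["dpg"] == 8]
        np.testing.assert_allclose(
            sub["padj"].to_numpy(), dk.bh_adjust(sub["pvalue"].to_numpy())
        )

    def test_decoy_false_positive_control(self, planted_run):
        """Decoy-only collection: essentially nothing passes a strict padj cut."""
        truth, result = planted_run["truth"], planted_run["result"]
        rng_sets = dk.generate_gene_sets(truth, n_decoy_sets=50, set_size=30, seed=11)
        decoys = dk.GeneSetCollection(
            sets={k: v for k, v in rng_sets.sets.items() if k.startswith("DECOY")},
            category="tissue",
        )
        table = dk.enrich_collection(result, decoys, alpha=0.001)
        assert table["significant"].mean() <= 0.01

    def test_unknown_dpg_label_rejected(self, planted_run):
        coll = dk.GeneSetCollection(sets={"s": {"G00001": 1.0}})
        with pytest.raises(ValueError, match="DPG"):
            dk.enrich_collection(planted_run["result"], coll, dpgs=[99])

    def test_go_term_ids_survive_round_trip(self, tmp_path, planted_run):
        """GO-style set names (e.g. GO:0007586) stay verbatim through GMT and results."""
        members = {g: 1.0 for g in list(planted_run["result"].universe)[:20]}
        coll = dk.GeneSetCollection(
            sets={"GO:0007586": members}, category="GO",
            descriptions={"GO:0007586": "digestion"},
        )
        path = tmp_path / "go.gmt"
        write_gmt(coll, path)
        back = read_gmt(path, category="GO")
        assert back.set_names() == ["GO:0007586"]
        table = dk.enrich_collection(planted_run["result"], back, dpgs=[0])
        assert set(table["set"]) == {"GO:0007586"}

    def test_heatmap_matrices_shapes(self, planted_run):
        truth, result = planted_run["truth"], planted_run["result"]
        coll = dk.generate_gene_sets(truth, n_decoy_sets=2, set_size=30, seed=8)
        table = dk.enrich_collection(result, coll, dpgs=[4, 5])
        p_mat, n_mat = dk.enrichment_heatmap_data(table)
        assert p_mat.shape == (len(coll.sets), 2)
        assert n_mat.shape == p_mat.shape
        assert (n_mat.to_numpy() >= 0).all()
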