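"""DiPaC decision table, superclusters, asymmetry test and export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dipackit as dk
from dipackit.dipac import _classify_vectorized

CFG = dk.DipacConfig()

#: DPG swap under the (x, y) -> (-x, -y), up<->down mirror
MIRROR = {0: 0, 1: 6, 6: 1, 2: 7, 7: 2, 3: 8, 8: 3, 4: 9, 9: 4, 5: 10, 10: 5}


def random_coordinates(n, seed):
    rng = np.random.default_rng(seed)
    x = rng.uniform(-6, 6, n)
    y = rng.uniform(-6, 6, n)
    change = rng.choice(["none", "up", "down"], n)
    return x, y, change


class TestClassifyGene:
    @pytest.mark.parametrize(
        "x, y, change, expected",
        [
            # canonical shapes of the intervention comparison
            (3.0, 0.2, "down", 8),   # downregulated to near-reference level
            (0.0, 0.0, "none", 0),   # identity case
            (-2.5, 1.8, "up", 4),    # excessive induction beyond the reference
            (2.0, 3.1, "up", 5),     # induced although already above the reference
            (4.0, 2.0, "down", 7),   # downregulated but still above the window
            (4.0, -4.0, "down", 9),  # overshot below the window
            (0.0, -4.0, "down", 10), # adversely downregulated from inside it
            (-4.0, -2.0, "up", 2),   # rising toward the window from below
            (-4.0, 0.0, "up", 3),    # risen into the window
            (0.0, -2.0, "none", 1),  # stays below, no transition
            (0.0, 2.0, "none", 6),   # stays above, no transition
            (0.5, 0.5, "up", 0),     # significant move entirely inside the window
        ],
    )
    def test_decision_table(self, x, y, change, expected):
        assert dk.classify_gene(x, y, change, CFG) == expected

    def test_nonfinite_coordinates_rejected(self):
        for bad in (np.nan, np.inf):
            with pytest.raises(ValueError):
                dk.classify_gene(bad, 0.0, "none", CFG)
            with pytest.raises(ValueError):
                dk.classify_gene(0.0, bad, "up", CFG)

    def test_unknown_change_rejected(self):
        with pytest.raises(ValueError):
            dk.classify_gene(0.0, 0.0, "sideways", CFG)


class TestPartitionProperties:
    def test_vectorized_equals_naive_loop(self):
        x, y, change = random_coordinates(10000, seed=42)
        vec = _classify_vectorized(x, y, change, CFG.t)
        naive = np.array(
            [dk.classify_gene(xi, yi, ci, CFG) for xi, yi, ci in zip(x, y, change)]
        )
        np.testing.assert_array_equal(vec, naive)

    def test_partition_and_supercluster_map(self):
        x, y, change = random_coordinates(10000, seed=7)
        coords = pd.DataFrame({"x": x, "y": y, "change": change})
        result = dk.classify_all(coords, CFG)
        assert result.dpg_counts.sum() == len(coords)
        assert set(result.table["dpg"]) <= set(range(11))
        for d, sc in dk.SUPERCLUSTER_OF.items():
            sub = result.table[result.table["dpg"] == d]
            assert (sub["supercluster"] == sc).all()
        assert dk.SUPERCLUSTER_OF == {
            7: "SC1", 8: "SC1", 9: "SC1", 10: "SC1",
            2: "SC2", 3: "SC2", 4: "SC2", 5: "SC2",
            0: "SC3", 1: "SC3", 6: "SC3",
        }

    @settings(max_examples=500, deadline=None, derandomize=True)
    @given(
        st.floats(-20, 20),
        st.floats(-20, 20),
        st.sampled_from(["none", "up", "down"]),
    )
    def test_mirror_symmetry(self, x, y, change):
        """Negating both axes and swapping up/down mirrors the DPG labels."""
        flipped = {"up": "down", "down": "up", "none": "none"}[change]
        d1 = dk.classify_gene(x, y, change, CFG)
        d2 = dk.classify_gene(-x, -y, flipped, CFG)
        assert d2 == MIRROR[d1]

    def test_favorable_group_semantics(self):
        """DPG3/8 end inside the reference window; DPG7 stays above it, below x.

        Change calls are drawn consistently with the trajectory (a "down" call
        implies the end state lies below the start), as the direct B-vs-A
        contrast produces them in practice.
        """
        rng = np.random.default_rng(3)
        x = rng.uniform(-6, 6, 10000)
        y = rng.uniform(-6, 6, 10000)
        moved = rng.random(10000) < 0.7
        change = np.where(moved, np.where(y > x, "up", "down"), "none")
        coords = pd.DataFrame({"x": x, "y": y, "change": change})
        table = dk.classify_all(coords, CFG).table
        ended_inside = table[table["dpg"].isin([3, 8])]
        assert (ended_inside["y"].abs() <= CFG.t).all()
        dpg7 = table[table["dpg"] == 7]
        assert (dpg7["y"] > CFG.t).all() and (dpg7["y"] < dpg7["x"]).all()


class TestBuildCoordinates:
    @staticmethod
    def deg_frame(genes, log2fc, padj):
        return pd.DataFrame(
            {
                "log2fc": log2fc,
                "se": 0.1,
                "pvalue": padj,
                "padj": padj,
                "mean_expr": 10.0,
            },
            index=genes,
        )

    def test_intersection_and_change_gate(self):
        a = self.deg_frame(["g1", "g2", "g3"], [2.0, 1.0, 0.0], [0.01, 0.01, 0.01])
        b = self.deg_frame(["g1", "g2", "g3"], [0.5, 1.0, 0.0], [0.01, 0.01, 0.01])
        ba = self.deg_frame(["g1", "g2"], [-1.5, 0.8], [0.01, 0.2])
        coords = dk.build_coordinates(a, b, ba, CFG)
        assert list(coords.index) == ["g1", "g2"]  # g3 dropped (intersection)
        assert coords.loc["g1", "change"] == "down"
        # padj 0.2 >= alpha_change: no call regardless of fold change
        assert coords.loc["g2", "change"] == "none"
        assert coords.loc["g1", "x"] == 2.0 and coords.loc["g1", "y"] == 0.5

    def test_empty_intersection_errors(self):
        a = self.deg_frame(["g1"], [1.0], [0.5])
        b = self.deg_frame(["g2"], [1.0], [0.5])
        with pytest.raises(ValueError, match="no genes"):
            dk.build_coordinates(a, b, b, CFG)

    def test_min_abs_change_gate(self):
        cfg = dk.DipacConfig(min_abs_change=1.0)
        a = self.deg_frame(["g1"], [3.0], [0.01])
        b = self.deg_frame(["g1"], [2.5], [0.01])
        ba = self.deg_frame(["g1"], [-0.5], [0.001])  # significant but small
        coords = dk.build_coordinates(a, b, ba, cfg)
        assert coords.loc["g1", "change"] == "none"


class TestAsymmetryTest:
    def test_printed_supercluster_counts_are_extreme(self):
        """690 of 1,043 SC1 genes moved toward the reference: p below 2.2e-16."""
        assert dk.supercluster_asymmetry_test(690, 1043) <= 2.2e-16

    def test_symmetric_null_and_enumerated_tail(self):
        assert dk.supercluster_asymmetry_test(5, 10) == pytest.approx(1.0)
        # all 10 successes: both one-sided extremes, 2/2^10 by enumeration
        assert dk.supercluster_asymmetry_test(10, 10) == pytest.approx(2 / 1024)

    def test_symmetry_in_k(self):
        for n, k in [(17, 3), (40, 11), (1043, 690)]:
            assert dk.supercluster_asymmetry_test(k, n) == pytest.approx(
                dk.supercluster_asymmetry_test(n - k, n), rel=1e-12
            )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            dk.supercluster_asymmetry_test(5, 0)
        with pytest.raises(ValueError):
            dk.supercluster_asymmetry_test(11, 10)


class TestExport:
    def test_round_trip_and_cutoff_sidecar(self, tmp_path):
        x, y, change = random_coordinates(50, seed=1)
        coords = pd.DataFrame(
            {"x": x, "y": y, "change": change},
            index=[f"g{i}" for i in range(50)],
        )
        result = dk.classify_all(coords, dk.DipacConfig(t=1.5))
        path = tmp_path / "dipa.tsv"
        sidecar = dk.export_dipa_plot_data(result, str(path))
        back = pd.read_csv(path, sep="\t", index_col=0)
        assert list(back["dpg"]) == list(result.table["dpg"])
        assert list(back["supercluster"]) == list(result.table["supercluster"])
        cuts = pd.read_csv(sidecar, sep="\t")
        assert sorted(cuts["value"]) == [-1.5, -1.5, 1.5, 1.5]

    def test_empty_result_writes_header_only(self, tmp_path):
        coords = pd.DataFrame(columns=["x", "y", "change"])
        result = dk.classify_all(coords, CFG)
        path = tmp_path / "empty.tsv"
        dk.export_dipa_plot_data(result, str(path))
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("gene_id")
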