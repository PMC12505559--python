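"""Overrepresentation analysis of DPGs against gene-set collections.

Each (gene set, DPG) pair is scored with a one-sided upper-tail
hypergeometric test on the 2x2 table of set membership versus DPG membership,
conditioned on the universe of genes actually classified by DiPaC. P-values
are Benjamini-Hochberg adjusted within each DPG column of a collection.
A two-sided Fisher exact test on the union of several DPGs against a TF
target set reproduces the union-enrichment statistic.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection
from .deg import bh_adjust
from .dipac import DipacResult

__all__ = [
    "hypergeometric_enrichment",
    "enrich_collection",
    "enrichment_heatmap_data",
    "fisher_union_test",
]


def _contingency(
    selection: set, gene_set: set, universe: set
) -> tuple[int, int, int, int]:
    a = len(selection & gene_set)
    b = len(gene_set) - a
    c = len(selection) - a
    d = len(universe) - len(gene_set) - len(selection) + a
    return a, b, c, d


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    # Haldane half-count correction only when a zero cell occurs
    if min(a, b, c, d) == 0:
        a, b, c, d = (v + 0.5 for v in (a, b, c, d))
    return (a * d) / (b * c)


def hypergeometric_enrichment(
    selection: Iterable[str], gene_set: Iterable[str], universe: Iterable[str]
) -> tuple[int, float, float]:
    """Upper-tail hypergeometric overrepresentation of ``gene_set`` in ``selection``.

    Returns (overlap, odds_ratio, pvalue) with p = P(X >= overlap) for X
    hypergeometric with population N=|universe|, K=|gene_set| successes and
    n=|selection| draws. The odds ratio is the sample cross-product from the
    2x2 table, Haldane-corrected only if a cell is zero.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    selection = set(selection)
    gene_set = set(gene_set)
    if not selection <= universe or not gene_set <= universe:
        raise ValueError("selection and gene_set must be subsets of the universe")
    a, b, c, d = _contingency(selection, gene_set, universe)
    n_universe = len(universe)
    pvalue = float(
        stats.hypergeom.sf(a - 1, n_universe, len(gene_set), len(selection))
    )
    return a, _sample_odds_ratio(a, b, c, d), min(pvalue, 1.0)


def enrich_collection(
    dipac: DipacResult,
    collection: GeneSetCollection,
    dpgs: Iterable[int] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every set in ``collection`` per DPG.

    The universe is the set of classified genes; collection members outside it
    are dropped (harmonized). BH adjustment runs within each DPG column, i.e.
    across the sets of one collection for one DPG. Returns a long table with
    one row per (set, dpg).
    """
    universe = dipac.universe
    harmonized, _ = collection.harmonize(universe)
    if dpgs is None:
        dpgs = [int(d) for d in sorted(dipac.table["dpg"].unique())]
    else:
        dpgs = [int(d) for d in dpgs]
        unknown = set(dpgs) - set(range(11))
        if unknown:
            raise ValueError(f"unknown DPG labels: {sorted(unknown)}")

    rows = []
    for dpg in dpgs:
        selection = set(dipac.genes_in_dpg(dpg))
        for name in harmonized.set_names():
            members = harmonized.members(name)
            overlap, odds, p = hypergeometric_enrichment(selection, members, universe)
            rows.append(
                {
                    "set": name,
                    "dpg": dpg,
                    "overlap": overlap,
                    "set_size": len(members),
                    "selection_size": len(selection),
                    "universe_size": len(universe),
                    "odds_ratio": odds,
                    "pvalue": p,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        table["padj"] = []
        table["significant"] = []
        return table
    table["padj"] = np.nan
    for dpg in dpgs:
        mask = table["dpg"] == dpg
        table.loc[mask, "padj"] = bh_adjust(table.loc[mask, "pvalue"].to_numpy())
    table["significant"] = table["padj"] < alpha
    return table


def enrichment_heatmap_data(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot an enrichment table into heatmap matrices.

    Returns (neglog10_p, overlap_counts), both sets x DPGs — the color scale
    and the per-cell gene counts of the tissue-by-DPG heatmaps.
    """
    neglog = table.assign(neglog10_p=-np.log10(table["pvalue"].clip(lower=1e-300)))
    p_mat = neglog.pivot(index="set", columns="dpg", values="neglog10_p")
    n_mat = table.pivot(index="set", columns="dpg", values="overlap")
    return p_mat, n_mat


def fisher_union_test(
    selection_union: Iterable[str],
    tf_targets: Iterable[str],
    universe: Iterable[str],
) -> tuple[float, float]:
    """Two-sided Fisher exact test of a DPG union against a TF target set.

    Returns (odds_ratio, pvalue); the odds ratio is the sample cross-product
    a*d/(b*c) of the 2x2 table (union membership x target membership). A zero
    margin makes the odds ratio undefined (NaN, with a warning); the p-value
    is still computed (and equals 1 in that case).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    selection_union = set(selection_union)
    tf_targets = set(tf_targets)
    if not selection_union <= universe or not tf_targets <= universe:
        raise ValueError("inputs must be subsets of the universe")
    a, b, c, d = _contingency(selection_union, tf_targets, universe)
    _, pvalue = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        warnings.warn("empty table margin: odds ratio undefined", stacklevel=2)
        return float("nan"), float(pvalue)
    with np.errstate(divide="ignore"):
        odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return float(odds), float(pvalue)
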