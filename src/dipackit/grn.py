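"""Gene-regulatory-network (GRN) impact scoring of transcription factors.

For a given DPG, each TF with an annotated regulon gets a per-target impact
score — the regulon edge weight times the magnitude of the target's transition
log2 fold change (end state B versus start state A) — for every regulon member
inside the DPG. The TF's summary impact is the median target score; TFs are
first gated by hypergeometric overrepresentation of their regulon in the DPG
(BH-adjusted across TFs) and the survivors are ranked by descending summary.

The per-target score definition (weight x |delta log2FC|, median summary,
enrichment gating) is this package's explicit reconstruction of a "GRN impact
score": it is deliberately simple, monotone in both edge confidence and effect
size, and carries log2 units. Treat cross-study comparisons of absolute score
values with care.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GeneSetCollection
from .deg import bh_adjust
from .dipac import DipacResult
from .enrichment import hypergeometric_enrichment

__all__ = ["gene_impact_score", "tf_impact_summary", "ImpactTable"]


def gene_impact_score(regulon_weight: float, delta: float) -> float:
    """Impact of one regulon edge: weight times |transition log2 fold change|."""
    if not (0.0 < regulon_weight <= 1.0):
        raise ValueError("regulon weight must lie in (0, 1]")
    return regulon_weight * abs(delta)


@dataclass
class ImpactTable:
    """Ranked TF impact summaries plus box-plot-ready target scores.

    ``summary`` has one row per TF (n_targets, summary, enrich_p, padj, rank;
    rank is NaN for TFs failing the enrichment gate); ``target_scores`` is long
    format (tf, gene, score) restricted to regulon members inside the DPG.
    """

    dpg: int
    summary: pd.DataFrame
    target_scores: pd.DataFrame

    def ranked(self) -> pd.DataFrame:
        """Only TFs passing the enrichment gate, in rank order."""
        out = self.summary.dropna(subset=["rank"]).sort_values("rank")
        return out


def tf_impact_summary(
    dipac: DipacResult,
    deg_b_vs_a: pd.DataFrame,
    regulons: GeneSetCollection,
    dpg: int,
    alpha: float = 0.05,
) -> ImpactTable:
    """Score and rank every TF regulon for one DPG.

    Per TF, target scores are computed for regulon members classified into
    ``dpg`` and present in the transition DE table; the summary is their
    median. The enrichment p-value is the one-sided hypergeometric of the
    (harmonized) regulon against the DPG members over the classified universe;
    TFs with BH-adjusted enrichment p < ``alpha`` receive dense ranks by
    descending summary impact.
    """
    if regulons.category != "TF":
        raise ValueError("regulon collection must have category 'TF'")
    universe = dipac.universe
    harmonized, _ = regulons.harmonize(universe)
    members_in_dpg = set(dipac.genes_in_dpg(dpg))
    if not members_in_dpg:
        warnings.warn(f"DPG{dpg} has no member genes", stacklevel=2)

    rows = []
    score_rows = []
    for tf in harmonized.set_names():
        regulon = harmonized.sets[tf]
        targets = sorted(set(regulon) & members_in_dpg)
        scores = {}
        for gene in targets:
            if gene not in deg_b_vs_a.index:
                continue
            delta = float(deg_b_vs_a.loc[gene, "log2fc"])
            scores[gene] = gene_impact_score(regulon[gene], delta)
        _, _, enrich_p = hypergeometric_enrichment(
            members_in_dpg, set(regulon), universe
        )
        rows.append(
            {
                "tf": tf,
                "n_targets": len(scores),
                "summary": float(np.median(list(scores.values()))) if scores else np.nan,
                "enrich_p": enrich_p,
            }
        )
        for gene, s in scores.items():
            score_rows.append({"tf": tf, "gene": gene, "score": s})

    summary = pd.DataFrame(rows).set_index("tf") if rows else pd.DataFrame(
        columns=["n_targets", "summary", "enrich_p"]
    )
    if not summary.empty:
        summary["padj"] = bh_adjust(summary["enrich_p"].to_numpy())
        passing = summary[
            (summary["padj"] < alpha) & summary["summary"].notna()
        ].sort_values("summary", ascending=False)
        summary["rank"] = np.nan
        summary.loc[passing.index, "rank"] = passing["summary"].rank(
            method="dense", ascending=False
        )
    else:
        summary["padj"] = []
        summary["rank"] = []
    target_scores = (
        pd.DataFrame(score_rows)
        if score_rows
        else pd.DataFrame(columns=["tf", "gene", "score"])
    )
    return ImpactTable(dpg=dpg, summary=summary, target_scores=target_scores)
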