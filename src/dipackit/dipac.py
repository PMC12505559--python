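"""Supervised differentiation pattern clustering (DiPaC).

Every gene is placed in a 2-D plane of log2 fold changes versus a reference
cell state (PHH): x is the fold change of the starting state A over the
reference, y that of the end state B over the reference. A significance-gated
"change call" from the direct B-vs-A contrast says whether the gene moved
between the two states, and a fixed logical decision table with a symmetric
cut-off t on both axes assigns one of eleven differentiation pattern groups
(DPG0-10). DPGs aggregate into three superclusters: SC1 (down in B vs A,
DPG7-10), SC2 (up in B vs A, DPG2-5), SC3 (no relevant change, DPG0/1/6).

The decision table with cut t:

==========  =========================  =====
change      region                     DPG
==========  =========================  =====
none        y < -t                     1
none        |y| <= t                   0
none        y > t                      6
up          x < -t and y < -t          2
up          x < -t and |y| <= t        3
up          x < -t and y > t           4
up          x >= -t and y > t          5
up          x >= -t and y <= t         0
down        x > t and y > t            7
down        x > t and |y| <= t         8
down        x > t and y < -t           9
down        x <= t and y < -t          10
down        x <= t and y >= -t         0
==========  =========================  =====

So DPG2/3/7/8 hold genes whose trajectory ends at (DPG3/8) or moves toward
(DPG2/7) the reference expression window, DPG4/9 overshoot it, and DPG5/10
move away although they started inside or beyond it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DipacConfig",
    "DipacResult",
    "SUPERCLUSTER_OF",
    "build_coordinates",
    "classify_gene",
    "classify_all",
    "supercluster_asymmetry_test",
    "export_dipa_plot_data",
]

#: fixed DPG -> supercluster map
SUPERCLUSTER_OF: dict[int, str] = {
    **{d: "SC1" for d in (7, 8, 9, 10)},
    **{d: "SC2" for d in (2, 3, 4, 5)},
    **{d: "SC3" for d in (0, 1, 6)},
}

CHANGE_NONE, CHANGE_UP, CHANGE_DOWN = "none", "up", "down"


@dataclass
class DipacConfig:
    """Cut-offs of the clustering approach.

    t : symmetric axis cut-off in log2 units (default 1.0, i.e. 2-fold).
    alpha_change : adjusted-p threshold gating the B-vs-A change call.
    min_abs_change : minimum |log2fc(B vs A)| additionally required for a call.
    """

    t: float = 1.0
    alpha_change: float = 0.05
    min_abs_change: float = 0.0

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError("cut-off t must be positive")
        if not (0.0 < self.alpha_change < 1.0):
            raise ValueError("alpha_change must be in (0, 1)")
        if self.min_abs_change < 0:
            raise ValueError("min_abs_change must be non-negative")


@dataclass
class DipacResult:
    """Per-gene coordinates, change call, DPG and supercluster labels."""

    table: pd.DataFrame  # columns: x, y, change, dpg, supercluster
    config: DipacConfig
    dpg_counts: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        counts = self.table["dpg"].value_counts()
        self.dpg_counts = counts.reindex(range(11), fill_value=0).astype(int)
        self.dpg_counts.index.name = "dpg"

    def genes_in_dpg(self, dpg: int) -> pd.Index:
        return self.table.index[self.table["dpg"] == dpg]

    def genes_in_supercluster(self, sc: str) -> pd.Index:
        return self.table.index[self.table["supercluster"] == sc]

    @property
    def universe(self) -> set[str]:
        return set(self.table.index)


def build_coordinates(
    deg_a_vs_ref: pd.DataFrame,
    deg_b_vs_ref: pd.DataFrame,
    deg_b_vs_a: pd.DataFrame,
    cfg: DipacConfig,
) -> pd.DataFrame:
    """Assemble the (x, y, change) table from three DE contrasts.

    x = log2fc of A over the reference, y = log2fc of B over the reference.
    The change call is ``up``/``down`` iff the direct B-vs-A contrast is
    significant (padj < alpha_change) and its |log2fc| >= min_abs_change;
    direction follows the sign of that log2fc. Genes missing from any table
    are dropped (logged).
    """
    common = deg_a_vs_ref.index.intersection(deg_b_vs_ref.index).intersection(
        deg_b_vs_a.index
    )
    if len(common) == 0:
        raise ValueError("the three DE tables share no genes")
    n_dropped = (
        len(deg_a_vs_ref.index.union(deg_b_vs_ref.index).union(deg_b_vs_a.index))
        - len(common)
    )
    if n_dropped:
        logger.info("build_coordinates: dropped %d genes outside the intersection", n_dropped)

    x = deg_a_vs_ref.loc[common, "log2fc"].to_numpy()
    y = deg_b_vs_ref.loc[common, "log2fc"].to_numpy()
    fc_ba = deg_b_vs_a.loc[common, "log2fc"].to_numpy()
    padj_ba = deg_b_vs_a.loc[common, "padj"].to_numpy()

    significant = (padj_ba < cfg.alpha_change) & (np.abs(fc_ba) >= cfg.min_abs_change)
    change = np.where(
        significant, np.where(fc_ba > 0, CHANGE_UP, CHANGE_DOWN), CHANGE_NONE
    )
    return pd.DataFrame({"x": x, "y": y, "change": change}, index=common)


def classify_gene(x: float, y: float, change: str, cfg: DipacConfig) -> int:
    """Assign a single gene's DPG label from its plane position and change call."""
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("coordinates must be finite")
    t = cfg.t
    if change == CHANGE_NONE:
        if y < -t:
            return 1
        if y > t:
            return 6
        return 0
    if change == CHANGE_UP:
        if x < -t:
            if y < -t:
                return 2
            if y > t:
                return 4
            return 3
        return 5 if y > t else 0
    if change == CHANGE_DOWN:
        if x > t:
            if y > t:
                return 7
            if y < -t:
                return 9
            return 8
        return 10 if y < -t else 0
    raise ValueError(f"unknown change call: {change!r}")


def _classify_vectorized(
    x: np.ndarray, y: np.ndarray, change: np.ndarray, t: float
) -> np.ndarray:
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("coordinates must be finite")
    dpg = np.zeros(len(x), dtype=int)
    none_ = change == CHANGE_NONE
    up = change == CHANGE_UP
    down = change == CHANGE_DOWN
    if not (none_ | up | down).all():
        bad = np.unique(change[~(none_ | up | down)])
        raise ValueError(f"unknown change calls: {bad}")

    dpg[none_ & (y < -t)] = 1
    dpg[none_ & (y > t)] = 6

    left = x < -t
    dpg[up & left & (y < -t)] = 2
    dpg[up & left & (np.abs(y) <= t)] = 3
    dpg[up & left & (y > t)] = 4
    dpg[up & ~left & (y > t)] = 5

    right = x > t
    dpg[down & right & (y > t)] = 7
    dpg[down & right & (np.abs(y) <= t)] = 8
    dpg[down & right & (y < -t)] = 9
    dpg[down & ~right & (y < -t)] = 10
    return dpg


def classify_all(coords: pd.DataFrame, cfg: DipacConfig) -> DipacResult:
    """Classify every gene in a (x, y, change) table; attach superclusters."""
    dpg = _classify_vectorized(
        coords["x"].to_numpy(dtype=float),
        coords["y"].to_numpy(dtype=float),
        coords["change"].to_numpy(),
        cfg.t,
    )
    table = coords.copy()
    table["dpg"] = dpg
    table["supercluster"] = [SUPERCLUSTER_OF[d] for d in dpg]
    return DipacResult(table=table, config=cfg)


def supercluster_asymmetry_test(n_favorable: int, n_total: int) -> float:
    """Two-sided exact binomial test of ``n_favorable`` in ``n_total`` vs p=0.5.

    Used to ask whether, within a supercluster, more genes moved toward the
    reference expression window (e.g. DPG7+8 within SC1) than away from it
    (DPG9+10). Two-sided by summing all outcomes whose point probability does
    not exceed that of the observed count.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_favorable <= n_total):
        raise ValueError("n_favorable must lie in [0, n_total]")
    return stats.binomtest(n_favorable, n_total, p=0.5, alternative="two-sided").pvalue


def export_dipa_plot_data(result: DipacResult, path: str) -> str:
    """Write the DiPa-plot table plus a sidecar with the cut-off lines.

    The main TSV has columns gene, x, y, dpg, supercluster; the sidecar
    ``<path>.cutoffs.tsv`` lists the four dotted lines at +-t. Returns the
    sidecar path.
    """
    out = result.table[["x", "y", "dpg", "supercluster"]].copy()
    out.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")
    t = result.config.t
    sidecar = f"{path}.cutoffs.tsv"
    pd.DataFrame(
        {"axis": ["x", "x", "y", "y"], "value": [-t, t, -t, t]}
    ).to_csv(sidecar, sep="\t", index=False, float_format="%.6g")
    return sidecar
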