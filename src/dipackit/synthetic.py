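"""Synthetic inputs with planted ground truth.

Emulates a four-group bulk RNA-seq design (iPSC, WT-HLC, KO-HLC, PHH; four
biological replicates each, ~20,000 genes) with negative-binomial counts,
gene blocks planted on each DPG trajectory shape, gene-set collections
correlated with the planted blocks, and saturating-exponential secretion
traces — so that every downstream stage of the pipeline can be tested against
known truth without any external download.

Counts follow NB(mean mu, dispersion alpha) with variance mu + alpha mu^2 and
a single alpha shared across genes. A gene planted in DPG d has group-mean
log2 deviations from the reference (PHH) that the DiPaC decision table maps
to d when evaluated on the noise-free log2 ratios: deviations sit at
+-effect_size (default 4 log2 units, far outside the default cut t = 1) or at
the half-effect for the "toward but not reaching the window" shapes. Filler
(DPG0) genes share one mean across all groups, drawn log-uniformly from
``base_mean_range``. Per-sample library-size factors drawn log-uniformly from
``size_factor_range`` multiply all means, exercising normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneSetCollection, TraceSet

__all__ = [
    "SyntheticDesign",
    "SyntheticTruth",
    "generate_counts",
    "generate_gene_sets",
    "generate_traces",
    "DEFAULT_BLOCK_SIZES",
]

#: default planted block sizes per DPG (intervention-scale design)
DEFAULT_BLOCK_SIZES: dict[int, int] = {
    1: 100,
    2: 180,
    3: 171,
    4: 3,
    5: 343,
    6: 100,
    7: 237,
    8: 453,
    9: 11,
    10: 342,
}


def _trajectory(dpg: int, e: float) -> tuple[float, float, str]:
    """Planted (x, y, change) in log2 units for each DPG shape.

    x is the state-A (WT-HLC) and y the state-B (KO-HLC) deviation from the
    reference. Requires e > 2t for the half-effect shapes (DPG2/7) to clear
    the cut.
    """
    half = e / 2.0
    return {
        1: (-e, -e, "none"),
        2: (-e, -half, "up"),
        3: (-e, 0.0, "up"),
        4: (-e, e, "up"),
        5: (0.0, e, "up"),
        6: (e, e, "none"),
        7: (e, half, "down"),
        8: (e, 0.0, "down"),
        9: (e, -e, "down"),
        10: (0.0, -e, "down"),
    }[dpg]


@dataclass
class SyntheticDesign:
    """Parameters of the synthetic count experiment."""

    n_genes: int = 20000
    groups: tuple[str, ...] = ("iPSC", "WT-HLC", "KO-HLC", "PHH")
    replicates_per_group: int = 4
    dpg_block_sizes: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_BLOCK_SIZES)
    )
    base_mean_range: tuple[float, float] = (20.0, 2000.0)
    dispersion: float = 0.05
    effect_size: float = 4.0
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    # states the planted trajectories refer to (A -> B versus the reference)
    @property
    def state_a(self) -> str:
        return self.groups[1]

    @property
    def state_b(self) -> str:
        return self.groups[2]

    @property
    def reference(self) -> str:
        return self.groups[-1]

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.replicates_per_group <= 0:
            raise ValueError("n_genes and replicates_per_group must be positive")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        bad = set(self.dpg_block_sizes) - set(range(1, 11))
        if bad:
            raise ValueError(f"plantable DPG labels are 1-10, got {sorted(bad)}")
        total = sum(self.dpg_block_sizes.values())
        if total > self.n_genes:
            raise ValueError(
                f"planted block sizes sum to {total} > n_genes = {self.n_genes}"
            )
        lo, hi = self.base_mean_range
        if not (0 < lo <= hi):
            raise ValueError("base_mean_range must be positive and ordered")


@dataclass
class SyntheticTruth:
    """Ground truth recorded while generating synthetic inputs."""

    gene_dpg: dict[str, int] = field(default_factory=dict)
    gene_sets_truth: dict[str, int] = field(default_factory=dict)
    trace_params: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    universe: list[str] = field(default_factory=list)
    planted_xy: dict[str, tuple[float, float]] = field(default_factory=dict)


def generate_counts(design: SyntheticDesign) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a seeded NB count matrix with planted DPG trajectory blocks.

    Planted genes get deterministic group-mean log2 offsets versus the
    reference; the iPSC group (outside the A->B transition) receives an
    independent +-effect_size offset per planted gene so all four groups are
    transcriptionally distinct. Generation is bit-reproducible from
    ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]

    log_lo, log_hi = np.log(design.base_mean_range[0]), np.log(design.base_mean_range[1])
    base = np.exp(rng.uniform(log_lo, log_hi, size=n))

    # assign planted blocks to a random subset of genes
    order = rng.permutation(n)
    truth = SyntheticTruth(universe=list(gene_ids))
    offsets = np.zeros((n, len(design.groups)))  # log2 deviation from reference
    group_index = {g: i for i, g in enumerate(design.groups)}
    if design.dpg_block_sizes:
        if len(design.groups) < 3:
            raise ValueError("planting DPG blocks needs at least 3 groups (A, B, reference)")
        ia = group_index[design.state_a]
        ib = group_index[design.state_b]
        i_start = group_index[design.groups[0]]

    pos = 0
    for dpg in sorted(design.dpg_block_sizes):
        size = design.dpg_block_sizes[dpg]
        block = order[pos : pos + size]
        pos += size
        x, y, _ = _trajectory(dpg, design.effect_size)
        offsets[block, ia] = x
        offsets[block, ib] = y
        if i_start not in (ia, ib):
            signs = rng.choice([-1.0, 1.0], size=size)
            offsets[block, i_start] = signs * design.effect_size
        for g in block:
            truth.gene_dpg[gene_ids[g]] = dpg
            truth.planted_xy[gene_ids[g]] = (x, y)

    lo_sf, hi_sf = design.size_factor_range
    n_samples = len(design.groups) * design.replicates_per_group
    size_factors = np.exp(rng.uniform(np.log(lo_sf), np.log(hi_sf), size=n_samples))

    sample_ids, sample_groups = [], []
    mu = np.empty((n, n_samples))
    col = 0
    for g in design.groups:
        for r in range(design.replicates_per_group):
            sample_ids.append(f"{g}_{r + 1}")
            sample_groups.append(g)
            mu[:, col] = base * np.exp2(offsets[:, group_index[g]]) * size_factors[col]
            col += 1

    if design.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / design.dispersion
        p = shape / (shape + mu)
        counts = rng.negative_binomial(shape, p)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        sample_group=pd.Series(sample_groups, index=sample_ids, name="group"),
    )
    return cm, truth


def generate_gene_sets(
    truth: SyntheticTruth,
    n_decoy_sets: int = 20,
    set_size: int = 50,
    seed: int = 0,
    category: str = "tissue",
    enriched_fraction: float = 0.8,
) -> GeneSetCollection:
    """Gene sets correlated with the planted blocks, plus uniform decoys.

    One set per planted DPG block draws at least ``enriched_fraction`` of its
    members from inside the block (all of it when the block is smaller) and
    the remainder uniformly from outside; decoys are uniform draws from the
    whole universe. Output is GMT-serializable and reproducible from ``seed``.
    """
    if not truth.gene_dpg:
        raise ValueError("truth carries no planted genes")
    universe = list(truth.universe)
    if set_size > len(universe):
        raise ValueError("set_size exceeds the gene universe")
    rng = np.random.default_rng(seed)

    blocks: dict[int, list[str]] = {}
    for gene, dpg in truth.gene_dpg.items():
        blocks.setdefault(dpg, []).append(gene)

    sets: dict[str, dict[str, float]] = {}
    for dpg in sorted(blocks):
        block = blocks[dpg]
        n_inside = min(len(block), max(int(math.ceil(enriched_fraction * set_size)), 1))
        inside = list(rng.choice(block, size=n_inside, replace=False))
        outside_pool = [g for g in universe if g not in set(block)]
        n_outside = min(set_size - n_inside, len(outside_pool))
        outside = list(rng.choice(outside_pool, size=n_outside, replace=False))
        name = f"DPG{dpg}_signature"
        sets[name] = {g: 1.0 for g in inside + outside}
        truth.gene_sets_truth[name] = dpg
    for i in range(n_decoy_sets):
        members = list(rng.choice(universe, size=set_size, replace=False))
        sets[f"DECOY_{i:03d}"] = {g: 1.0 for g in members}

    return GeneSetCollection(sets=sets, category=category, universe=set(universe))


def generate_traces(
    n_traces_per_group: int,
    params_by_group: dict[str, tuple[float, float, float]],
    noise_sd: float = 0.0,
    t_max: float = 60.0,
    dt: float = 1.0,
    seed: int = 0,
    param_cv: float = 0.0,
    t_lag: float = 0.0,
) -> tuple[TraceSet, SyntheticTruth]:
    """Saturating-exponential secretion traces I(t) = b + A(1 - exp(-kt)) + noise.

    Sampled on a regular grid over [0, t_max] (default 60 time units, the
    length of the confocal capture window). ``params_by_group`` maps each
    condition to its (amplitude A, rate k, baseline b); ``param_cv`` > 0 adds
    lognormal per-trace variation around A and k to mimic biological spread.
    ``t_lag`` > 0 delays secretion onset, holding the trace at its baseline
    for the first frames the way pre-stimulus acquisition does; the rise then
    follows A(1 - exp(-k (t - t_lag))). True per-trace parameters are
    recorded in the returned truth.
    """
    if t_max <= 0 or dt <= 0:
        raise ValueError("t_max and dt must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if t_lag < 0:
        raise ValueError("t_lag must be non-negative")
    for g, (a, k, _b) in params_by_group.items():
        if a <= 0 or k <= 0:
            raise ValueError(f"group {g!r}: amplitude and rate must be positive")
    time = np.arange(0.0, t_max + dt / 2.0, dt)
    if len(time) < 5:
        raise ValueError("grid has fewer than 5 time points; decrease dt")

    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    rows = []
    for group, (a0, k0, b0) in params_by_group.items():
        for i in range(n_traces_per_group):
            if param_cv > 0:
                a = a0 * rng.lognormal(0.0, param_cv)
                k = k0 * rng.lognormal(0.0, param_cv)
            else:
                a, k = a0, k0
            tid = f"{group}_{i + 1}"
            intensity = b0 + a * (1.0 - np.exp(-k * np.maximum(time - t_lag, 0.0)))
            if noise_sd > 0:
                intensity = intensity + rng.normal(0.0, noise_sd, size=len(time))
            truth.trace_params[tid] = (a, k, b0)
            rows.append(
                pd.DataFrame(
                    {
                        "trace_id": tid,
                        "group": group,
                        "time": time,
                        "intensity": intensity,
                    }
                )
            )
    return TraceSet(data=pd.concat(rows, ignore_index=True)), truth
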