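"""Core in-memory containers shared across the pipeline.

The pipeline is organised around three inputs: a gene x sample count matrix
with a sample-to-group assignment, collections of named gene sets (tissue
signatures, GO terms, TF regulons), and per-canaliculus fluorescence traces.
Each gets a thin container that validates its invariants once at construction
so downstream stages can assume well-formed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "GeneSetCollection", "TraceSet"]


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer counts plus sample grouping.

    Parameters
    ----------
    counts
        DataFrame with unique gene ids as index and unique sample ids as
        columns; values must be non-negative integers.
    sample_group
        Series mapping every sample id in ``counts.columns`` to a group label
        (e.g. ``iPSC``, ``WT-HLC``, ``KO-HLC``, ``PHH``).
    """

    counts: pd.DataFrame
    sample_group: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        if self.counts.columns.has_duplicates:
            raise ValueError("sample ids must be unique")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.sample_group.index)
        if missing:
            raise ValueError(f"samples without a group assignment: {sorted(missing)}")
        # keep only relevant samples, in matrix order
        self.sample_group = self.sample_group.reindex(self.counts.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.sample_group:
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in(self, group: str) -> list[str]:
        """Sample ids assigned to ``group`` (order of the matrix columns)."""
        hits = [s for s in self.counts.columns if self.sample_group[s] == group]
        if not hits:
            raise KeyError(f"unknown group label: {group!r}")
        return hits

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-member weights in (0, 1].

    ``sets`` maps set name -> {gene id -> weight}; unweighted collections
    (plain GMT) carry weight 1 for every member. ``category`` is one of
    ``tissue``, ``GO``, ``TF``.
    """

    sets: dict[str, dict[str, float]]
    category: str = "tissue"
    universe: set[str] | None = None
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            for gene, w in members.items():
                if not (0.0 < w <= 1.0):
                    raise ValueError(
                        f"weight for {gene!r} in set {name!r} outside (0, 1]: {w}"
                    )

    def set_names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> set[str]:
        return set(self.sets[name])

    def harmonize(self, universe: set[str]) -> tuple["GeneSetCollection", int]:
        """Restrict all sets to ``universe``; returns (collection, n_dropped)."""
        dropped = 0
        new_sets: dict[str, dict[str, float]] = {}
        for name, members in self.sets.items():
            kept = {g: w for g, w in members.items() if g in universe}
            dropped += len(members) - len(kept)
            new_sets[name] = kept
        return (
            GeneSetCollection(
                sets=new_sets,
                category=self.category,
                universe=set(universe),
                descriptions=dict(self.descriptions),
            ),
            dropped,
        )


@dataclass
class TraceSet:
    """Per-canaliculus fluorescence time series, grouped by condition.

    ``data`` is long format with columns ``trace_id``, ``group``, ``time``,
    ``intensity``; ``areas`` optionally maps trace_id -> lumen area (um^2).
    Each trace must have at least 5 strictly increasing time points.
    """

    data: pd.DataFrame
    areas: pd.Series | None = None

    REQUIRED = ("trace_id", "group", "time", "intensity")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"trace table missing columns: {missing}")
        for tid, sub in self.data.groupby("trace_id", sort=False):
            t = sub["time"].to_numpy(dtype=float)
            if len(t) < 5:
                raise ValueError(f"trace {tid!r} has fewer than 5 time points")
            if not np.all(np.diff(t) > 0):
                raise ValueError(f"trace {tid!r} time points not strictly increasing")
            if sub["group"].isna().any() or (sub["group"] == "").any():
                raise ValueError(f"trace {tid!r} has an empty group label")

    def trace_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["trace_id"]))

    def get(self, trace_id: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.data[self.data["trace_id"] == trace_id]
        if sub.empty:
            raise KeyError(f"unknown trace id: {trace_id!r}")
        return sub["time"].to_numpy(dtype=float), sub["intensity"].to_numpy(dtype=float)

    def group_of(self, trace_id: str) -> str:
        sub = self.data.loc[self.data["trace_id"] == trace_id, "group"]
        if sub.empty:
            raise KeyError(f"unknown trace id: {trace_id!r}")
        return str(sub.iloc[0])
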