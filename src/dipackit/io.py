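"""Readers and writers for the plain-text interchange formats.

Counts travel as TSV (genes as rows) or MatrixMarket triplets with sidecar
row/column name files; sample sheets as two-column TSV; gene sets as GMT with
optional ``gene:weight`` tokens; traces and areas as long-format CSV.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CountMatrix, GeneSetCollection, TraceSet

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_sample_sheet",
    "write_sample_sheet",
    "load_count_matrix",
    "read_gmt",
    "write_gmt",
    "read_traces_csv",
    "write_traces_csv",
    "read_areas_csv",
]


# ---------------------------------------------------------------- counts

def read_counts_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes-by-samples TSV (header = sample ids, first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(np.int64)


def write_counts_tsv(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_mtx(
    mtx_path: str | os.PathLike,
    genes_path: str | os.PathLike,
    samples_path: str | os.PathLike,
) -> pd.DataFrame:
    mat = scipy.io.mmread(os.fspath(mtx_path))
    genes = pd.read_csv(genes_path, header=None)[0].astype(str)
    samples = pd.read_csv(samples_path, header=None)[0].astype(str)
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    return pd.DataFrame(dense.astype(np.int64), index=genes, columns=samples)


def write_counts_mtx(
    counts: pd.DataFrame,
    mtx_path: str | os.PathLike,
    genes_path: str | os.PathLike,
    samples_path: str | os.PathLike,
) -> None:
    scipy.io.mmwrite(os.fspath(mtx_path), scipy.sparse.coo_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(genes_path, index=False, header=False)
    pd.Series(counts.columns).to_csv(samples_path, index=False, header=False)


def read_sample_sheet(path: str | os.PathLike) -> pd.Series:
    """Read a TSV with columns ``sample_id`` and ``group``."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError("sample sheet needs columns 'sample_id' and 'group'")
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"], name="group")


def write_sample_sheet(sample_group: pd.Series, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"sample_id": sample_group.index, "group": sample_group.to_numpy()}
    ).to_csv(path, sep="\t", index=False)


def load_count_matrix(
    counts_path: str | os.PathLike,
    sample_sheet_path: str | os.PathLike,
    genes_path: str | os.PathLike | None = None,
    samples_path: str | os.PathLike | None = None,
) -> CountMatrix:
    """Load counts (TSV, or MTX when sidecar name files are given) plus groups."""
    if genes_path is not None and samples_path is not None:
        counts = read_counts_mtx(counts_path, genes_path, samples_path)
    else:
        counts = read_counts_tsv(counts_path)
    groups = read_sample_sheet(sample_sheet_path)
    return CountMatrix(counts=counts, sample_group=groups)


# ---------------------------------------------------------------- gene sets

def read_gmt(path: str | os.PathLike, category: str = "tissue") -> GeneSetCollection:
    """Parse GMT; members may be ``gene`` or ``gene:weight`` tokens."""
    sets: dict[str, dict[str, float]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, desc, *members = fields
            parsed: dict[str, float] = {}
            for token in members:
                if not token:
                    continue
                if ":" in token:
                    gene, w = token.rsplit(":", 1)
                    parsed[gene] = float(w)
                else:
                    parsed[token] = 1.0
            sets[name] = parsed
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, category=category, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, collection.category)
            tokens = [
                gene if w == 1.0 else f"{gene}:{w:g}" for gene, w in members.items()
            ]
            fh.write("\t".join([name, desc, *tokens]) + "\n")


# ---------------------------------------------------------------- traces

def read_traces_csv(
    path: str | os.PathLike, areas_path: str | os.PathLike | None = None
) -> TraceSet:
    data = pd.read_csv(path)
    areas = read_areas_csv(areas_path) if areas_path is not None else None
    return TraceSet(data=data, areas=areas)


def write_traces_csv(traces: TraceSet, path: str | os.PathLike) -> None:
    traces.data.to_csv(path, index=False)


def read_areas_csv(path: str | os.PathLike) -> pd.Series:
    """Read a per-trace area table (columns trace_id, area_um2)."""
    df = pd.read_csv(path)
    if not {"trace_id", "area_um2"} <= set(df.columns):
        raise ValueError("area table needs columns 'trace_id' and 'area_um2'")
    return pd.Series(df["area_um2"].to_numpy(dtype=float), index=df["trace_id"])
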