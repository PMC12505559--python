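"""End-to-end orchestration: counts -> DE -> DiPaC -> enrichment -> impact,
plus PCA QC and trace kinetics, written as a diff-able results bundle.

Every numeric output is TSV with fixed column order and 6 significant digits;
the run manifest is JSON carrying the config hash, seed and library versions,
so identical configurations reproduce byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import sklearn
import scipy
import yaml
from sklearn.decomposition import PCA

from . import __version__
from .canaliculi import compare_groups, summarize_kinetics
from .containers import CountMatrix, GeneSetCollection, TraceSet
from .deg import normalized_counts, test_differential_expression, top_deg_table
from .dipac import (
    DipacConfig,
    classify_all,
    build_coordinates,
    export_dipa_plot_data,
    supercluster_asymmetry_test,
)
from .enrichment import enrich_collection
from .grn import tf_impact_summary
from . import io as dio

__all__ = ["RunConfig", "pca_top_variable", "run_all", "stage_rng"]

FLOAT_FORMAT = "%.6g"

#: fixed stage indices for counter-based seed expansion; appending stages
#: never shifts the streams of existing ones
STAGE_INDEX = {
    "deg": 1,
    "dipac": 2,
    "enrichment": 3,
    "impact": 4,
    "kinetics": 5,
    "pca": 6,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Per-stage generator derived from the single global seed."""
    return np.random.default_rng([seed, STAGE_INDEX[stage]])


def pca_top_variable(
    cm: CountMatrix, n_top: int = 1000, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the samples on the most variable genes.

    Counts are size-factor normalized and log2(x+1)-transformed; the ``n_top``
    genes with the highest variance are kept (clipped to the gene count with a
    warning) and centered per gene. Returns (sample coordinates, per-PC
    variance fractions).
    """
    if cm.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_top > cm.n_genes:
        warnings.warn(
            f"n_top = {n_top} exceeds the {cm.n_genes} available genes; clipping",
            stacklevel=2,
        )
        n_top = cm.n_genes
    log_norm = np.log2(normalized_counts(cm) + 1.0)
    variances = log_norm.var(axis=1, ddof=1)
    top = variances.sort_values(ascending=False, kind="stable").index[:n_top]
    x = log_norm.loc[top].to_numpy().T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    k = n_components or min(x.shape)
    pca = PCA(n_components=min(k, *x.shape), svd_solver="full")
    coords = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=cm.sample_ids, columns=cols),
        pca.explained_variance_ratio_,
    )


@dataclass
class RunConfig:
    """Everything one end-to-end run needs.

    ``mode`` selects the transition contrast: ``differentiation`` compares
    iPSC -> (WT-)HLC, ``intervention`` WT-HLC -> KO-HLC; either way the
    fold-change plane is anchored to the reference (PHH).
    """

    counts_path: str
    sample_sheet_path: str
    out_dir: str
    mode: str = "intervention"
    group_a: str | None = None
    group_b: str | None = None
    reference: str = "PHH"
    gene_set_paths: dict[str, str] = field(default_factory=dict)  # category -> GMT
    traces_path: str | None = None
    areas_path: str | None = None
    dipac: DipacConfig = field(default_factory=DipacConfig)
    deg_alpha: float = 0.001
    enrich_alpha: float = 0.05
    impact_alpha: float = 0.05
    impact_dpgs: tuple[int, ...] = (7, 8)
    kinetics_metrics: tuple[str, ...] = ("amplitude", "half_time")
    top_k: int = 15
    seed: int = 0

    DEFAULT_AB = {
        "differentiation": ("iPSC", "WT-HLC"),
        "intervention": ("WT-HLC", "KO-HLC"),
    }

    def __post_init__(self) -> None:
        if self.mode not in self.DEFAULT_AB:
            raise ValueError(f"mode must be one of {sorted(self.DEFAULT_AB)}")
        a, b = self.DEFAULT_AB[self.mode]
        self.group_a = self.group_a or a
        self.group_b = self.group_b or b

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        dipac_raw = raw.pop("dipac", None)
        cfg = cls(**raw)
        if dipac_raw:
            cfg.dipac = DipacConfig(**dipac_raw)
        return cfg

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if not isinstance(v, DipacConfig)
        }
        d["dipac"] = self.dipac.__dict__
        for k, v in list(d.items()):
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FORMAT)


def run_all(cfg: RunConfig) -> dict:
    """Execute every configured stage; returns the manifest dictionary.

    Stage failures abort with a stage-tagged message; outputs written before
    the failure are listed in the raised error so partial bundles are
    recognizable.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_sha256": cfg.digest(),
        "seed": cfg.seed,
        "versions": {
            "dipackit": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "stages": [],
    }

    def emit(name: str, df: pd.DataFrame, index_label: str = "gene_id") -> None:
        path = out / name
        _write_tsv(df, path, index_label)
        written.append(name)

    def run_stage(stage: str, fn) -> None:
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
            raise RuntimeError(
                f"stage {stage!r} failed: {exc}; outputs written so far: {written}"
            ) from exc
        manifest["stages"].append(stage)

    cm = dio.load_count_matrix(cfg.counts_path, cfg.sample_sheet_path)
    state: dict = {}

    def _deg() -> None:
        state["deg_a"] = test_differential_expression(cm, cfg.reference, cfg.group_a)
        state["deg_b"] = test_differential_expression(cm, cfg.reference, cfg.group_b)
        state["deg_ba"] = test_differential_expression(cm, cfg.group_a, cfg.group_b)
        emit(f"deg_{cfg.group_a}_vs_{cfg.reference}.tsv", state["deg_a"])
        emit(f"deg_{cfg.group_b}_vs_{cfg.reference}.tsv", state["deg_b"])
        emit(f"deg_{cfg.group_b}_vs_{cfg.group_a}.tsv", state["deg_ba"])
        emit("top_deg.tsv", top_deg_table(state["deg_ba"], cfg.deg_alpha, cfg.top_k))

    def _dipac() -> None:
        coords = build_coordinates(
            state["deg_a"], state["deg_b"], state["deg_ba"], cfg.dipac
        )
        result = classify_all(coords, cfg.dipac)
        state["dipac"] = result
        export_dipa_plot_data(result, str(out / "dipac.tsv"))
        written.extend(["dipac.tsv", "dipac.tsv.cutoffs.tsv"])
        counts = result.dpg_counts
        sc1 = counts[[7, 8, 9, 10]].sum()
        favorable = counts[[7, 8]].sum()
        summary = {
            "dpg_counts": {int(k): int(v) for k, v in counts.items()},
            "supercluster_counts": {
                sc: int((result.table["supercluster"] == sc).sum())
                for sc in ("SC1", "SC2", "SC3")
            },
            "sc1_favorable": int(favorable),
            "sc1_total": int(sc1),
            "sc1_asymmetry_p": (
                float(supercluster_asymmetry_test(int(favorable), int(sc1)))
                if sc1 > 0
                else None
            ),
        }
        (out / "dipac_summary.json").write_text(json.dumps(summary, indent=2))
        written.append("dipac_summary.json")

    def _enrich() -> None:
        for category, path in cfg.gene_set_paths.items():
            coll = dio.read_gmt(path, category=category)
            table = enrich_collection(
                state["dipac"], coll, alpha=cfg.enrich_alpha
            )
            emit(f"enrichment_{category}.tsv", table.set_index("set"), "set")
            if category == "TF":
                state["regulons"] = coll

    def _impact() -> None:
        if "regulons" not in state:
            return
        for dpg in cfg.impact_dpgs:
            table = tf_impact_summary(
                state["dipac"], state["deg_ba"], state["regulons"], dpg,
                alpha=cfg.impact_alpha,
            )
            emit(f"impact_dpg{dpg}.tsv", table.summary, "tf")
            emit(
                f"impact_dpg{dpg}_targets.tsv",
                table.target_scores.set_index("tf"),
                "tf",
            )

    def _kinetics() -> None:
        if cfg.traces_path is None:
            return
        traces = dio.read_traces_csv(cfg.traces_path, cfg.areas_path)
        summaries = summarize_kinetics(traces)
        emit("kinetics.tsv", summaries, "trace_id")
        report = {}
        for metric in cfg.kinetics_metrics:
            if summaries[metric].notna().sum() == 0:
                continue
            comp = compare_groups(summaries, metric)
            report[metric] = {
                "kruskal_p": comp.kruskal_p,
                "n_undefined_excluded": comp.n_undefined_excluded,
                "pairwise": comp.pairwise.to_dict(orient="records"),
                "group_stats": comp.group_stats.to_dict(orient="index"),
            }
        (out / "kinetics_tests.json").write_text(json.dumps(report, indent=2))
        written.append("kinetics_tests.json")

    def _pca() -> None:
        coords, var_frac = pca_top_variable(cm, n_top=min(1000, cm.n_genes))
        emit("pca.tsv", coords, "sample_id")
        (out / "pca_variance.json").write_text(
            json.dumps({"variance_fraction": [round(float(v), 6) for v in var_frac]})
        )
        written.append("pca_variance.json")

    run_stage("deg", _deg)
    run_stage("dipac", _dipac)
    run_stage("enrichment", _enrich)
    run_stage("impact", _impact)
    run_stage("kinetics", _kinetics)
    run_stage("pca", _pca)

    manifest["outputs"] = sorted(written)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
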