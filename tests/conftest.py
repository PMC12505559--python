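import numpy as np
import pandas as pd
import pytest

import dipackit as dk


def make_count_matrix(counts: np.ndarray, groups: list[str]) -> dk.CountMatrix:
    """Small helper: counts array (genes x samples) + per-sample group labels."""
    counts = np.asarray(counts)
    genes = [f"g{i}" for i in range(counts.shape[0])]
    samples = [f"s{j}" for j in range(counts.shape[1])]
    return dk.CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        sample_group=pd.Series(groups, index=samples),
    )


@pytest.fixture(scope="session")
def planted_run():
    """A seeded synthetic experiment with every DPG planted, classified end-to-end.

    Session-scoped because DE on three contrasts is the expensive part; the
    result is treated as read-only by all consumers.
    """
    design = dk.SyntheticDesign(
        n_genes=2000,
        dpg_block_sizes={d: 40 for d in range(1, 11)},
        dispersion=0.05,
        seed=5,
    )
    cm, truth = dk.generate_counts(design)
    deg_a = dk.test_differential_expression(cm, "PHH", "WT-HLC")
    deg_b = dk.test_differential_expression(cm, "PHH", "KO-HLC")
    deg_ba = dk.test_differential_expression(cm, "WT-HLC", "KO-HLC")
    cfg = dk.DipacConfig()
    coords = dk.build_coordinates(deg_a, deg_b, deg_ba, cfg)
    result = dk.classify_all(coords, cfg)
    return {
        "design": design,
        "cm": cm,
        "truth": truth,
        "deg_a": deg_a,
        "deg_b": deg_b,
        "deg_ba": deg_ba,
        "cfg": cfg,
        "result": result,
    }
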