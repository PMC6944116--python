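import numpy as np
import pandas as pd
import pytest

from uvg2.io import ExpressionDataset


def make_dataset(
    n_genes=20,
    n_rep=3,
    platform="microarray",
    seed=0,
    effects=None,
    noise_sd=0.3,
):
    """Small expression dataset with optional per-(condition,fraction) shifts.

    ``effects`` maps (condition, fraction) -> per-gene shift array.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    baseline = rng.normal(8.0, 1.0, n_genes)
    sample_ids, meta_rows, cols = [], [], []
    for cond in ("AS", "G2", "UVG2"):
        for frac in ("total", "polysome"):
            for r in range(1, n_rep + 1):
                sid = f"{cond}_{frac}_r{r}"
                sample_ids.append(sid)
                meta_rows.append((sid, cond, frac, r))
                shift = np.zeros(n_genes)
                if effects and (cond, frac) in effects:
                    shift = np.asarray(effects[(cond, frac)], dtype=float)
                col = baseline + shift + rng.normal(0, noise_sd, n_genes)
                cols.append(col)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "condition", "fraction", "replicate"]
    ).set_index("sample_id")
    values = np.column_stack(cols)
    if platform == "rnaseq":
        values = np.round(2.0**values)
    return ExpressionDataset(
        gene_ids=genes,
        sample_ids=sample_ids,
        values=values,
        sample_meta=meta,
        platform=platform,
    )


@pytest.fixture
def small_dataset():
    return make_dataset()
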