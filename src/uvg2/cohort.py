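"""Relating pathway deregulation to UV-signature mutation load.

Cohort samples are partitioned by UV-signature mutation (USM) load per Mb
into zero / low / mid / high subgroups at the published boundaries (3.6 and
54.6 mutations per Mb, closed mid interval; the zero group is exactly zero
load). PDS is related to load by Spearman rank correlation, and subgroup PDS
distributions are compared pairwise by two-sided rank-sum tests with
Benjamini–Hochberg adjustment. Single-gene deregulation scores are ranked by
their low-versus-high group separation to surface the major contributing
genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "subgroup_by_load",
    "correlate",
    "compare_groups",
    "rank_gene_contributions",
    "DEFAULT_COMPARISONS",
    "SUBGROUP_ORDER",
]

SUBGROUP_ORDER = ("zero", "low", "mid", "high")

DEFAULT_COMPARISONS = (
    ("zero", "low"),
    ("zero", "mid"),
    ("zero", "high"),
    ("low", "mid"),
    ("low", "high"),
)


def subgroup_by_load(
    loads: pd.Series, boundaries: tuple = (3.6, 54.6)
) -> tuple[pd.Series, dict]:
    """Assign each sample to a USM-load subgroup.

    zero: load == 0; low: 0 < load < boundaries[0];
    mid: boundaries[0] <= load <= boundaries[1] (closed interval);
    high: load > boundaries[1]. Returns (labels, counts).
    """
    lo, hi = boundaries
    if not (0 < lo < hi):
        raise ValueError("boundaries must be strictly increasing and positive")
    x = loads.astype(float)
    if (x < 0).any():
        bad = list(x.index[x < 0])[:5]
        raise ValueError(f"negative mutation load for sample(s): {bad}")
    labels = pd.Series(
        np.select(
            [x == 0, x < lo, x <= hi],
            ["zero", "low", "mid"],
            default="high",
        ),
        index=x.index,
        name="subgroup",
    )
    counts = {g: int((labels == g).sum()) for g in SUBGROUP_ORDER}
    return labels, counts


def correlate(pds: pd.Series, loads: pd.Series) -> dict:
    """Spearman rank correlation between PDS and mutation load.

    Mid-ranks for ties; p value from the t approximation. Returns
    ``{"rho", "n", "p"}``; rho is NaN (with a warning) when either input is
    constant.
    """
    joined = pd.concat([pds.rename("pds"), loads.rename("load")], axis=1).dropna()
    n = len(joined)
    if n < 10:
        raise ValueError(f"need >= 10 paired samples, got {n}")
    if joined["pds"].nunique() == 1 or joined["load"].nunique() == 1:
        warnings.warn("constant input: Spearman correlation undefined")
        return {"rho": np.nan, "n": n, "p": np.nan}
    rho, p = stats.spearmanr(joined["pds"], joined["load"])
    return {"rho": float(rho), "n": n, "p": float(p)}


def compare_groups(
    pds: pd.Series,
    labels: pd.Series,
    comparisons: tuple = DEFAULT_COMPARISONS,
    min_group: int = 3,
    test: str = "ranksum",
) -> pd.DataFrame:
    """Pairwise subgroup comparisons of the PDS distribution.

    Two-sided Mann–Whitney rank-sum test (or Welch t-test when
    ``test="ttest"``) per requested pair, Benjamini–Hochberg adjustment
    across the tested pairs. Pairs with an undersized group are skipped with
    a warning. Group medians are reported alongside.
    """
    groups = {g: pds[labels == g].dropna() for g in SUBGROUP_ORDER}
    rows = []
    for a, b in comparisons:
        xa, xb = groups.get(a, pd.Series(dtype=float)), groups.get(b, pd.Series(dtype=float))
        if len(xa) < min_group or len(xb) < min_group:
            warnings.warn(
                f"skipping {a} vs {b}: group sizes {len(xa)}/{len(xb)} "
                f"below {min_group}"
            )
            continue
        if test == "ranksum":
            stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        elif test == "ttest":
            stat, p = stats.ttest_ind(xa, xb, equal_var=False)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": len(xa),
                "n_b": len(xb),
                "median_a": float(xa.median()),
                "median_b": float(xb.median()),
                "statistic": float(stat),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def rank_gene_contributions(
    gene_pds: pd.DataFrame,
    labels: pd.Series,
    group_a: str = "low",
    group_b: str = "high",
    min_group: int = 3,
) -> pd.DataFrame:
    """Rank pathway genes by how well their single-gene PDS separates two
    load subgroups (default low vs high).

    Per gene: two-sided rank-sum statistic, BH-adjusted p across genes, and
    the median PDS difference (b - a) as the effect size. Genes are ordered
    by adjusted p, then by descending |effect|; equal columns tie exactly.
    """
    idx_a = labels.index[labels == group_a]
    idx_b = labels.index[labels == group_b]
    if len(idx_a) < min_group or len(idx_b) < min_group:
        raise ValueError(
            f"groups {group_a}/{group_b} too small ({len(idx_a)}/{len(idx_b)})"
        )
    rows = []
    for gene in gene_pds.columns:
        xa = gene_pds.loc[idx_a, gene].dropna()
        xb = gene_pds.loc[idx_b, gene].dropna()
        stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append(
            {
                "gene": gene,
                "statistic": float(stat),
                "p": float(p),
                "effect": float(xb.median() - xa.median()),
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out = out.sort_values(
        by=["p_adj", "effect"],
        key=lambda s: s if s.name == "p_adj" else -s.abs(),
        kind="stable",
    )
    out["rank"] = out["p_adj"].rank(method="min").astype(int)
    return out
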