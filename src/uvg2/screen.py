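"""Per-well summarization and per-gene scoring of the high-content screen.

The screen reads out three phenotypes per perturbation and cell line after UV
irradiation: viability (cell number), cell-cycle position (2n / S / 4n DNA
content from integrated nuclear stain intensity), and single-stranded-DNA
exposure (RPA foci per cell). Wells are summarized, compared against
non-targeting (NT) control wells, and folded into an integer score per gene
per cell line; confidence tiers follow the published two-cell-line rules
(siRNA: total >= 10 in both lines is high confidence, in exactly one line is
low; overexpression: score > 2 in both lines is high, > 3 in one is low).

The per-axis point values are configurable; the shipped defaults assign 0/2/4
points per axis over five axes so that a full phenotype clears the >= 10 tier
boundary. They are this package's choice, not a reproduction of the original
supplementary scoring table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

__all__ = [
    "fit_dna_mixture",
    "classify_dna_content",
    "summarize_wells",
    "tukey_vs_control",
    "foci_stats",
    "score_sirna",
    "score_overexpression",
    "DEFAULT_SIRNA_RUBRIC",
    "DEFAULT_OE_RUBRIC",
]

DEFAULT_SIRNA_RUBRIC: dict = {
    # viability: fold change in cell count vs NT after UV (lower is stronger)
    "viability": {"weak": 0.75, "strong": 0.50, "points": (2, 4)},
    # delayed checkpoint entry: 4n fraction shift vs NT at 24 h (negative)
    "entry24": {"weak": -0.10, "strong": -0.20, "points": (2, 4)},
    # retained arrest / delayed exit: 4n fraction shift vs NT at 40 h
    "exit40": {"weak": 0.10, "strong": 0.20, "points": (2, 4)},
    # significant RPA foci increase (fold vs NT, Tukey-adjusted p < alpha)
    "foci_up": {"weak": 1.5, "strong": 2.0, "alpha": 0.05, "points": (2, 4)},
    # significant RPA foci decrease
    "foci_down": {"weak": 1 / 1.5, "strong": 0.5, "alpha": 0.05, "points": (2, 4)},
}

DEFAULT_OE_RUBRIC: dict = {
    # transduced-fraction ratio UV40 / noUV ("> 25% reduction" rule at 0.75)
    "viability": {"weak": 0.75, "strong": 0.50, "points": (2, 3)},
    "entry24": {"weak": -0.10, "strong": -0.20, "points": (1, 2)},
    "exit40": {"weak": 0.10, "strong": 0.20, "points": (1, 2)},
}


# ---------------------------------------------------------------------------
# DNA-content classification
# ---------------------------------------------------------------------------

def _dna_em(x: np.ndarray, mu: float, max_iter: int = 200, tol: float = 1e-7):
    """EM for the constrained mixture w*N(mu, sd) + (1-w)*N(mu+1, sd).

    Returns (mu, sd, w, loglik)."""
    sd = max(min(float(np.std(x)) / 2.0, 0.3), 1e-3)
    w = 0.5
    ll = -np.inf
    for _ in range(max_iter):
        z1 = (x - mu) / sd
        z2 = (x - mu - 1.0) / sd
        logp1 = np.log(w + 1e-300) - 0.5 * z1**2
        logp2 = np.log(1.0 - w + 1e-300) - 0.5 * z2**2
        m = np.maximum(logp1, logp2)
        lse = m + np.log(np.exp(logp1 - m) + np.exp(logp2 - m))
        ll_new = float(np.sum(lse)) - len(x) * np.log(sd * np.sqrt(2 * np.pi))
        r1 = np.exp(logp1 - lse)
        r2 = 1.0 - r1
        mu = float(np.sum(r1 * x + r2 * (x - 1.0)) / len(x))
        var = float(np.sum(r1 * (x - mu) ** 2 + r2 * (x - mu - 1.0) ** 2) / len(x))
        sd = max(np.sqrt(var), 1e-4)
        w = float(np.mean(r1))
        if abs(ll_new - ll) < tol * (abs(ll_new) + 1.0):
            ll = ll_new
            break
        ll = ll_new
    return mu, sd, w, ll


def fit_dna_mixture(log2_intensity: np.ndarray, max_iter: int = 200):
    """Constrained two-normal fit on log2 intensity: the 4n mode is the 2n
    mode plus exactly 1 (doubling of DNA content), shared sd.

    Because the two modes are exactly one log2 unit apart, the fractional
    part of the intensities concentrates at the 2n mode's phase; the circular
    mean of exp(2*pi*i*x) supplies deterministic starting values (one per
    integer offset within the data range), augmented with quantile starts.
    EM is run from every start and the best log-likelihood wins, which keeps
    the fit from collapsing onto a single wide component when one ploidy
    class dominates. All starts are shift-equivariant, so rescaling the
    intensities by a constant leaves phase assignments unchanged.

    Returns (mu_2n, sd, weight_2n).
    """
    x = np.asarray(log2_intensity, dtype=float)
    phase = float(np.angle(np.mean(np.exp(2j * np.pi * x))) / (2 * np.pi)) % 1.0
    lo, hi = float(np.min(x)), float(np.max(x))
    starts = []
    k = np.floor(lo - phase - 0.5)
    while phase + k <= hi + 0.5:
        cand = phase + k
        if lo - 1.25 <= cand <= hi + 0.25:
            starts.append(cand)
        k += 1.0
    starts.append(float(np.quantile(x, 0.25)))
    starts.append(float(np.quantile(x, 0.75)) - 1.0)
    # drop near-duplicate starts; EM from nearby values converges identically
    kept = []
    for s in starts:
        if all(abs(s - k) > 0.15 for k in kept):
            kept.append(s)
    best = None
    for mu0 in kept:
        fit = _dna_em(x, mu0, max_iter=max_iter)
        if best is None or fit[3] > best[3] + 1e-6:
            best = fit
        elif fit[3] > best[3] - 1e-6 and fit[2] > best[2]:
            # likelihood tie (e.g. a single-mode well, where "all 2n at mu"
            # and "all 4n at mu-1" are equivalent): prefer the 2n-dominant
            # labeling, matching an unperturbed interphase population
            best = fit
    mu, sd, w, _ = best
    return mu, sd, w


def classify_dna_content(
    intensities: np.ndarray,
    s_margin: float = 0.15,
    min_cells: int = 200,
) -> dict:
    """Phase fractions (2n / S / 4n) for one well from DNA-stain intensities.

    Cells within ``s_margin`` log2 units of a fitted mode are assigned to
    that mode's phase; cells beyond a mode stay in that phase; cells between
    the modes and outside both margins are S phase. Wells with fewer than
    ``min_cells`` cells are flagged unevaluable (fractions NaN).
    """
    x = np.asarray(intensities, dtype=float)
    if (x <= 0).any():
        raise ValueError("DNA intensities must be > 0")
    if len(x) < min_cells:
        return {
            "frac_2n": np.nan,
            "frac_s": np.nan,
            "frac_4n": np.nan,
            "n_cells": len(x),
            "evaluable": False,
        }
    lx = np.log2(x)
    mu, sd, w = fit_dna_mixture(lx)
    is_2n = lx <= mu + s_margin
    is_4n = lx >= mu + 1.0 - s_margin
    is_s = ~(is_2n | is_4n)
    n = len(lx)
    return {
        "frac_2n": float(is_2n.sum()) / n,
        "frac_s": float(is_s.sum()) / n,
        "frac_4n": float(is_4n.sum()) / n,
        "n_cells": n,
        "evaluable": True,
        "mode_2n_log2": mu,
        "sd_log2": sd,
    }


# ---------------------------------------------------------------------------
# Well summaries
# ---------------------------------------------------------------------------

def summarize_wells(
    cells: pd.DataFrame,
    min_cells: int = 200,
    s_margin: float = 0.15,
) -> pd.DataFrame:
    """Collapse the per-cell table into one row per well.

    Columns: identity (well, perturbation, cell_line, timepoint), cell
    count, phase fractions, mean foci per cell, evaluable flag and — when a
    ``transduced`` column is present — the transduced fraction.
    """
    required = {"well", "perturbation", "cell_line", "timepoint", "dna_intensity", "foci_count"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"per-cell table lacks column(s): {sorted(missing)}")
    rows = []
    for well, grp in cells.groupby("well", sort=True):
        res = classify_dna_content(
            grp["dna_intensity"].to_numpy(), s_margin=s_margin, min_cells=min_cells
        )
        row = {
            "well": well,
            "perturbation": grp["perturbation"].iloc[0],
            "cell_line": grp["cell_line"].iloc[0],
            "timepoint": grp["timepoint"].iloc[0],
            "n_cells": len(grp),
            "frac_2n": res["frac_2n"],
            "frac_s": res["frac_s"],
            "frac_4n": res["frac_4n"],
            "mean_foci": float(grp["foci_count"].mean()),
            "evaluable": res["evaluable"],
        }
        if "transduced" in grp.columns:
            row["transduced_frac"] = float(grp["transduced"].mean())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tukey HSD foci comparison
# ---------------------------------------------------------------------------

def tukey_vs_control(groups: dict, control: str = "NT") -> pd.DataFrame:
    """Pairwise-vs-control adjusted p values from the studentized range.

    ``groups`` maps group name to an array of per-well mean foci counts (the
    analysis unit is the well, not the cell). A one-way layout across all
    groups supplies the pooled error variance; each non-control group is
    compared with the control by the Tukey–Kramer statistic
    q = |m_i - m_c| / sqrt(MSE/2 * (1/n_i + 1/n_c)) referred to the
    studentized range with k groups and the pooled error df. Groups with a
    single well get an undefined (NaN) p.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} missing")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if len(arrays[control]) < 3:
        raise ValueError("need >= 3 control replicate wells")
    k = len(arrays)
    df_err = sum(len(v) - 1 for v in arrays.values())
    sse = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    mse = sse / df_err if df_err > 0 else np.nan
    mc = arrays[control].mean()
    nc = len(arrays[control])
    rows = []
    for g, v in arrays.items():
        if g == control:
            continue
        mg, ng = v.mean(), len(v)
        fold = mg / mc if mc != 0 else np.nan
        if ng < 2 or df_err < 1 or not np.isfinite(mse) or mse <= 0:
            p = 1.0 if (np.isfinite(mse) and mse == 0 and mg == mc) else np.nan
            q = np.nan if not (np.isfinite(mse) and mse == 0 and mg == mc) else 0.0
        else:
            q = abs(mg - mc) / np.sqrt(mse / 2.0 * (1.0 / ng + 1.0 / nc))
            p = float(studentized_range.sf(q, k, df_err))
        rows.append({"group": g, "fold_change": fold, "q": q, "p_adj": min(p, 1.0) if np.isfinite(p) else p})
    return pd.DataFrame(rows).set_index("group")


def foci_stats(well_summaries: pd.DataFrame, control: str = "NT") -> pd.DataFrame:
    """Foci fold change and Tukey-adjusted p per perturbation per timepoint.

    Runs :func:`tukey_vs_control` separately within each (cell_line,
    timepoint) stratum using per-well mean foci.
    """
    rows = []
    for (line, tp), grp in well_summaries.groupby(["cell_line", "timepoint"], sort=True):
        groups = {
            name: sub["mean_foci"].to_numpy()
            for name, sub in grp.groupby("perturbation", sort=True)
        }
        res = tukey_vs_control(groups, control=control)
        for name, row in res.iterrows():
            rows.append(
                {
                    "cell_line": line,
                    "timepoint": tp,
                    "perturbation": name,
                    "foci_fold": row["fold_change"],
                    "foci_p_adj": row["p_adj"],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Phenotype assembly and scoring
# ---------------------------------------------------------------------------

def assemble_phenotypes(
    well_summaries: pd.DataFrame, control: str = "NT"
) -> pd.DataFrame:
    """Per-(gene, cell line) phenotype metrics relative to the NT control.

    Produces, per perturbation and line: cell-count fold vs NT at UV24/UV40,
    the 4n-fraction shifts vs NT at both UV timepoints, foci fold changes
    and adjusted p values, and (when present) transduced fractions at noUV
    and UV40. Control and cells-only wells are not scored.
    """
    foci = foci_stats(well_summaries, control=control)
    rows = []
    skip = {control, "PLK1", "cells-only", "empty-vector"}
    for line, grp in well_summaries.groupby("cell_line", sort=True):
        ref = {}
        for tp, sub in grp[grp["perturbation"] == control].groupby("timepoint"):
            ev = sub[sub["evaluable"]]
            ref[tp] = {
                "n_cells": sub["n_cells"].mean(),
                "frac_4n": ev["frac_4n"].mean() if len(ev) else np.nan,
            }
        for name, sub in grp.groupby("perturbation", sort=True):
            if name in skip:
                continue
            row = {"gene": name, "cell_line": line}
            for tp in ("noUV", "UV24", "UV40"):
                tp_sub = sub[sub["timepoint"] == tp]
                ev = tp_sub[tp_sub["evaluable"]]
                present = len(tp_sub) > 0 and tp in ref
                row[f"has_{tp}"] = present
                if not present:
                    continue
                row[f"cellcount_fold_{tp}"] = (
                    tp_sub["n_cells"].mean() / ref[tp]["n_cells"]
                    if ref[tp]["n_cells"]
                    else np.nan
                )
                row[f"d4n_{tp}"] = (
                    ev["frac_4n"].mean() - ref[tp]["frac_4n"] if len(ev) else np.nan
                )
                row[f"evaluable_{tp}"] = bool(len(ev))
                if "transduced_frac" in tp_sub.columns:
                    row[f"transduced_frac_{tp}"] = tp_sub["transduced_frac"].mean()
                m = foci[
                    (foci["cell_line"] == line)
                    & (foci["timepoint"] == tp)
                    & (foci["perturbation"] == name)
                ]
                if len(m):
                    row[f"foci_fold_{tp}"] = float(m["foci_fold"].iloc[0])
                    row[f"foci_p_{tp}"] = float(m["foci_p_adj"].iloc[0])
            rows.append(row)
    return pd.DataFrame(rows).set_index(["gene", "cell_line"]).sort_index()


def _axis_points(value: float, weak: float, strong: float, points: tuple) -> int:
    """Graded points for one axis; direction inferred from weak vs strong."""
    if not np.isfinite(value):
        return 0
    pw, ps = points
    if strong <= weak:  # lower is stronger (viability, entry24, foci_down)
        if value <= strong:
            return ps
        if value <= weak:
            return pw
    else:  # higher is stronger (exit40, foci_up)
        if value >= strong:
            return ps
        if value >= weak:
            return pw
    return 0


def _tier(total_a: float, total_b: float, mode: str) -> str:
    if mode == "sirna":
        hits = (total_a >= 10) + (total_b >= 10)
        return {2: "high", 1: "low", 0: "none"}[hits]
    # overexpression tier rules
    if total_a > 2 and total_b > 2:
        return "high"
    if max(total_a, total_b) > 3:
        return "low"
    return "none"


def score_sirna(phenotypes: pd.DataFrame, rubric: dict | None = None) -> pd.DataFrame:
    """Score the siRNA screen per gene across both cell lines.

    Five axes per line: viability drop, delayed 4n accumulation at 24 h,
    retained 4n at 40 h, significant foci increase, significant foci
    decrease. Missing timepoints score 0 on their axes and are flagged.
    Tier: high when the total is >= 10 in both lines, low when >= 10 in
    exactly one, else none.
    """
    rub = rubric or DEFAULT_SIRNA_RUBRIC
    lines = sorted(phenotypes.index.get_level_values("cell_line").unique())
    if len(lines) != 2:
        raise ValueError(f"expected exactly 2 cell lines, got {lines}")
    records = []
    for gene in sorted(phenotypes.index.get_level_values("gene").unique()):
        rec = {"gene": gene}
        totals = {}
        flags = []
        for line in lines:
            try:
                row = phenotypes.loc[(gene, line)]
            except KeyError:
                totals[line] = 0
                flags.append(f"{line}:missing")
                continue
            for tp in ("UV24", "UV40"):
                if not row.get(f"has_{tp}", False):
                    flags.append(f"{line}:{tp}-missing")
            folds = [
                row.get(f"cellcount_fold_{tp}", np.nan) for tp in ("UV24", "UV40")
            ]
            folds = [f for f in folds if np.isfinite(f)]
            viability_val = min(folds) if folds else np.nan
            r = rub["viability"]
            s_viab = _axis_points(viability_val, r["weak"], r["strong"], r["points"])
            r = rub["entry24"]
            s_entry = _axis_points(
                row.get("d4n_UV24", np.nan), r["weak"], r["strong"], r["points"]
            )
            r = rub["exit40"]
            s_exit = _axis_points(
                row.get("d4n_UV40", np.nan), r["weak"], r["strong"], r["points"]
            )

            def foci_axis(spec_key):
                r = rub[spec_key]
                best = 0
                for tp in ("UV24", "UV40"):
                    fold = row.get(f"foci_fold_{tp}", np.nan)
                    p = row.get(f"foci_p_{tp}", np.nan)
                    if np.isfinite(p) and p < r["alpha"]:
                        best = max(
                            best, _axis_points(fold, r["weak"], r["strong"], r["points"])
                        )
                return best

            s_up = foci_axis("foci_up")
            s_down = foci_axis("foci_down")
            total = s_viab + s_entry + s_exit + s_up + s_down
            totals[line] = total
            rec.update(
                {
                    f"viability_{line}": s_viab,
                    f"entry24_{line}": s_entry,
                    f"exit40_{line}": s_exit,
                    f"foci_up_{line}": s_up,
                    f"foci_down_{line}": s_down,
                    f"total_{line}": total,
                }
            )
        rec["tier"] = _tier(totals.get(lines[0], 0), totals.get(lines[1], 0), "sirna")
        rec["flags"] = ";".join(flags)
        records.append(rec)
    return pd.DataFrame(records).set_index("gene")


def score_overexpression(
    phenotypes: pd.DataFrame, rubric: dict | None = None
) -> pd.DataFrame:
    """Score the overexpression screen per gene across both cell lines.

    The viability axis flags genes whose transduced fraction after UV (40 h)
    drops below 0.75x the unirradiated control (the published > 25%
    reduction rule); the cell-cycle axes reuse the 4n-shift thresholds.
    Genes with unevaluable wells (below the cell floor) in a line get tier
    "unevaluable". Tier: high when the score is > 2 in both lines, low when
    > 3 in one.
    """
    rub = rubric or DEFAULT_OE_RUBRIC
    lines = sorted(phenotypes.index.get_level_values("cell_line").unique())
    if len(lines) != 2:
        raise ValueError(f"expected exactly 2 cell lines, got {lines}")
    records = []
    for gene in sorted(phenotypes.index.get_level_values("gene").unique()):
        rec = {"gene": gene}
        totals = {}
        unevaluable = False
        for line in lines:
            try:
                row = phenotypes.loc[(gene, line)]
            except KeyError:
                totals[line] = 0
                unevaluable = True
                continue
            if not (
                row.get("evaluable_noUV", True) and row.get("evaluable_UV40", True)
            ):
                unevaluable = True
            tf0 = row.get("transduced_frac_noUV", np.nan)
            tf40 = row.get("transduced_frac_UV40", np.nan)
            ratio = tf40 / tf0 if np.isfinite(tf0) and tf0 > 0 else np.nan
            r = rub["viability"]
            s_viab = _axis_points(ratio, r["weak"], r["strong"], r["points"])
            r = rub["entry24"]
            s_entry = _axis_points(
                row.get("d4n_UV24", np.nan), r["weak"], r["strong"], r["points"]
            )
            r = rub["exit40"]
            s_exit = _axis_points(
                row.get("d4n_UV40", np.nan), r["weak"], r["strong"], r["points"]
            )
            total = s_viab + s_entry + s_exit
            totals[line] = total
            rec.update(
                {
                    f"viability_flag_{line}": bool(np.isfinite(ratio) and ratio < 0.75),
                    f"viability_{line}": s_viab,
                    f"entry24_{line}": s_entry,
                    f"exit40_{line}": s_exit,
                    f"transduced_ratio_{line}": ratio,
                    f"total_{line}": total,
                }
            )
        rec["tier"] = (
            "unevaluable"
            if unevaluable
            else _tier(totals.get(lines[0], 0), totals.get(lines[1], 0), "oe")
        )
        records.append(rec)
    return pd.DataFrame(records).set_index("gene")
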