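"""Differential polysome-loading analysis and candidate selection.

Transcripts differentially loaded onto polysomes during the UV-G2 checkpoint
arrest are found by an empirical-Bayes moderated linear-model test on log2
expression (log2 intensities for microarray, log2 counts-per-million for
RNA-seq), contrasting an arrested condition against asynchronously growing
cells within one gradient fraction.

Per gene the test reports the log2 fold change, a moderated t statistic whose
residual variance is shrunk toward a prior estimated by moment matching of
the log sample variances, and the B statistic: the log posterior odds of
differential expression under a two-component normal model with a prior
proportion ``p`` of truly changed genes.

Candidate selection then applies the published rules: fold change >= 2 and
B > 0; removal of genes behaving identically in the plain G2-phase arrest;
intersection of the microarray and RNA-seq candidate lists; and a
transcriptional / translational classification from the total-mRNA versus
polysome-fraction contrasts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

from .io import ExpressionDataset

__all__ = [
    "log_cpm",
    "moderated_stats",
    "select_differential",
    "subtract_g2",
    "intersect_platforms",
    "classify_regulation",
]


def trigamma(x):
    return polygamma(1, x)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the monotone transform suggested by the large/small-y asymptotics
    (trigamma(x) ~ 1/x + 1/(2x^2)).
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate prior df and prior variance (d0, s0^2) for variance shrinkage.

    Moment matching on z = log(s^2): under the scaled-F model,
    E[z] = log(s0^2) + digamma(d/2) - log(d/2) - digamma(d0/2) + log(d0/2)
    and Var[z] = trigamma(d/2) + trigamma(d0/2). Genes with non-positive
    sample variance are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive sample variances to fit the prior")
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(trigamma(df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    return d0, s0_2


def squeeze_variances(s2: np.ndarray, df: float, d0: float, s0_2: float) -> np.ndarray:
    """Posterior variances s~^2 = (d0*s0^2 + df*s^2) / (d0 + df)."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(d0):
        return np.full_like(s2, s0_2)
    return (d0 * s0_2 + df * s2) / (d0 + df)


def estimate_v0(t: np.ndarray, v_g: np.ndarray, df_total: float, proportion: float) -> float:
    """Method-of-moments estimate of the DE-component coefficient variance.

    Under the two-component model a fraction ``proportion`` of moderated t
    values are inflated by sqrt((v_g + v0)/v_g); matching the mean squared t
    gives v0. Expressed, like v_g, in units of the residual variance.
    """
    t = np.asarray(t, dtype=float)
    vbar = float(np.mean(v_g))
    if np.isfinite(df_total) and df_total > 2:
        null_m2 = df_total / (df_total - 2.0)
    else:
        null_m2 = 1.0
    excess = float(np.mean(t**2)) / null_m2 - 1.0
    v0 = vbar * excess / proportion
    return max(v0, 0.0)


def b_statistic(
    t: np.ndarray,
    v_g: np.ndarray,
    df_total: float,
    proportion: float,
    v0: float,
) -> np.ndarray:
    """Log posterior odds of differential expression.

    B = log(p/(1-p)) + 0.5*log(r) + ((nu+1)/2)*log((t^2+nu)/(t^2*r+nu))
    with r = v_g/(v_g+v0) and nu the total df of the moderated t; in the
    infinite-df (normal) limit the last term becomes t^2*(1-r)/2.
    """
    t = np.asarray(t, dtype=float)
    v_g = np.broadcast_to(np.asarray(v_g, dtype=float), t.shape)
    r = v_g / (v_g + v0)
    lo = np.log(proportion / (1.0 - proportion)) + 0.5 * np.log(r)
    if np.isfinite(df_total):
        nu = df_total
        kernel = ((nu + 1.0) / 2.0) * np.log((t**2 + nu) / (t**2 * r + nu))
    else:
        kernel = t**2 * (1.0 - r) / 2.0
    return lo + kernel


def log_cpm(counts: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    """log2 counts-per-million with a pseudocount, column-wise library sizes."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    return np.log2((counts + pseudocount) / (lib + 2.0 * pseudocount) * 1e6)


def moderated_stats(
    ds: ExpressionDataset,
    contrast: tuple,
    prior_de_proportion: float = 0.01,
) -> pd.DataFrame:
    """Per-gene moderated statistics for ``condition_a - condition_b``.

    ``contrast`` is ``(condition_a, condition_b, fraction)``; e.g.
    ``("UVG2", "AS", "polysome")`` tests differential polysome loading of the
    checkpoint-arrested cells against the asynchronous baseline.

    Returns a DataFrame indexed by gene with columns ``log2fc``, ``t``,
    ``B``, ``sigma`` (ordinary residual sd), ``s2_post``, ``df_residual``,
    ``df_prior`` and ``contrast``.
    """
    cond_a, cond_b, fraction = contrast
    ids_a = ds.samples_for(cond_a, fraction)
    ids_b = ds.samples_for(cond_b, fraction)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError(
            f"contrast {contrast} needs >= 2 replicates per condition "
            f"(got {len(ids_a)} and {len(ids_b)})"
        )
    frame = ds.to_frame()
    values = frame.to_numpy(dtype=float)
    if ds.platform == "rnaseq":
        values = log_cpm(values)
        frame = pd.DataFrame(values, index=frame.index, columns=frame.columns)
    xa = frame[ids_a].to_numpy()
    xb = frame[ids_b].to_numpy()
    n1, n2 = xa.shape[1], xb.shape[1]
    df_resid = n1 + n2 - 2
    if df_resid < 1:
        raise ValueError("zero residual degrees of freedom")
    logfc = xa.mean(axis=1) - xb.mean(axis=1)
    ss = ((xa - xa.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (xb - xb.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid
    d0, s0_2 = fit_variance_prior(s2, df_resid)
    s2_post = squeeze_variances(s2, df_resid, d0, s0_2)
    v_g = 1.0 / n1 + 1.0 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / np.sqrt(s2_post * v_g)
    t = np.where(s2_post > 0, t, 0.0)
    df_total = d0 + df_resid
    v_g_arr = np.full_like(t, v_g)
    v0 = estimate_v0(t, v_g_arr, df_total, prior_de_proportion)
    b = b_statistic(t, v_g_arr, df_total, prior_de_proportion, v0)
    return pd.DataFrame(
        {
            "log2fc": logfc,
            "t": t,
            "B": b,
            "sigma": np.sqrt(s2),
            "s2_post": s2_post,
            "df_residual": float(df_resid),
            "df_prior": d0,
            "s2_prior": s0_2,
            "v0": v0,
            "contrast": f"{cond_a}-{cond_b}:{fraction}",
        },
        index=frame.index,
    )


def select_differential(stats: pd.DataFrame, fc_cutoff: float = 2.0, b_cutoff: float = 0.0) -> set:
    """Genes with |log2FC| >= log2(fc_cutoff) and B > b_cutoff."""
    if fc_cutoff < 1:
        raise ValueError("fc_cutoff must be >= 1 (linear fold scale)")
    if stats.empty:
        return set()
    mask = (stats["log2fc"].abs() >= np.log2(fc_cutoff)) & (stats["B"] > b_cutoff)
    return set(stats.index[mask])


def subtract_g2(
    uvg2_set: set,
    uvg2_stats: pd.DataFrame,
    g2_set: set,
    g2_stats: pd.DataFrame,
    similarity_logfc: float = 1.0,
) -> set:
    """Drop checkpoint candidates that behave the same in plain G2 arrest.

    A gene is removed when it is in both candidate lists and its two log2
    fold changes agree in sign and differ by less than ``similarity_logfc``
    — i.e. the polysome shift is generic to G2 phase rather than specific to
    the UV-G2 checkpoint.
    """
    missing = [g for g in uvg2_set if g not in uvg2_stats.index]
    missing += [g for g in (uvg2_set & g2_set) if g not in g2_stats.index]
    if missing:
        raise ValueError(f"stats missing for listed gene(s): {sorted(missing)[:5]}")
    out = set()
    for g in uvg2_set:
        if g in g2_set:
            fu = uvg2_stats.at[g, "log2fc"]
            fg = g2_stats.at[g, "log2fc"]
            if np.sign(fu) == np.sign(fg) and abs(fu - fg) < similarity_logfc:
                continue
        out.add(g)
    return out


def intersect_platforms(microarray_set: set, rnaseq_set: set) -> tuple[set, float]:
    """Cross-platform high-confidence set and the containment fraction.

    Returns ``(microarray_set & rnaseq_set, |intersection| / |rnaseq_set|)``;
    containment 1.0 reproduces the "completely contained" situation in which
    the intersection equals the RNA-seq list.
    """
    inter = set(microarray_set) & set(rnaseq_set)
    containment = len(inter) / len(rnaseq_set) if rnaseq_set else float("nan")
    return inter, containment


def classify_regulation(
    total_stats: pd.DataFrame,
    polysome_stats: pd.DataFrame,
    fc_cutoff: float = 2.0,
    b_cutoff: float = 0.0,
) -> tuple[pd.Series, dict]:
    """Per-gene transcriptional / translational regulation class.

    A gene passing selection in the polysome contrast but not in the total
    contrast is translational-only; the converse is transcriptional-only;
    passing both is "both"; otherwise "none". The summary reports the two
    directional exclusive fractions (share of polysome-selected genes not
    total-selected, and vice versa) and the Venn counts.
    """
    if set(total_stats.index) != set(polysome_stats.index):
        raise ValueError("total and polysome stats cover different gene universes")
    total_sel = select_differential(total_stats, fc_cutoff, b_cutoff)
    poly_sel = select_differential(polysome_stats, fc_cutoff, b_cutoff)
    classes = {}
    for g in total_stats.index:
        in_t, in_p = g in total_sel, g in poly_sel
        if in_p and not in_t:
            classes[g] = "translational-only"
        elif in_t and not in_p:
            classes[g] = "transcriptional-only"
        elif in_t and in_p:
            classes[g] = "both"
        else:
            classes[g] = "none"
    classes = pd.Series(classes, name="regulation_class").loc[total_stats.index]
    n_both = len(total_sel & poly_sel)
    n_poly_only = len(poly_sel - total_sel)
    n_total_only = len(total_sel - poly_sel)
    summary = {
        "n_polysome_selected": len(poly_sel),
        "n_total_selected": len(total_sel),
        "n_both": n_both,
        "n_translational_only": n_poly_only,
        "n_transcriptional_only": n_total_only,
        "fraction_polysome_not_total": (
            n_poly_only / len(poly_sel) if poly_sel else float("nan")
        ),
        "fraction_total_not_polysome": (
            n_total_only / len(total_sel) if total_sel else float("nan")
        ),
    }
    return classes, summary
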