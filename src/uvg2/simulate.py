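"""Synthetic data generators with planted, recoverable structure.

Three generators emulate the three input classes of the analysis chain:

* :func:`gen_polysome` — paired microarray / RNA-seq expression designs
  (AS / G2 / UVG2 conditions x total / polysome fractions) with planted gene
  classes: transcriptional-only, translational-only (the dominant class in
  the checkpoint response), and G2-generic shifts present in both arrests.
* :func:`gen_screen` — per-cell high-content readouts (integrated DNA-stain
  intensity, RPA foci counts) for siRNA or overexpression wells, driven by
  per-perturbation phenotype archetypes.
* :func:`gen_cohort` — a melanoma-like cohort with a latent dysregulation
  axis t in [0,1] driving pathway-gene expression along a curve, coupled to a
  negative-binomial UV-signature mutation load.

Every generator is a pure function of its spec (the seed lives in the spec),
so identical specs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ExpressionDataset, GeneSetCollection

__all__ = [
    "PolysomeSimSpec",
    "Archetype",
    "ScreenSimSpec",
    "CohortSimSpec",
    "gen_polysome",
    "gen_screen",
    "gen_cohort",
    "default_gene_sets",
    "PATHWAY_SUBSETS",
]

# Known UV-G2 checkpoint pathway members assembled from the screen hits and
# previously established components, grouped into the three scored subsets.
# Used as the default cohort gene panel (43 genes); membership of the real
# supplementary panel is approximated, identifiers are treated as opaque.
PATHWAY_SUBSETS: dict = {
    "checkpoint": [
        "ATR", "CHEK1", "TIMELESS", "BTG2", "CCND1", "CDKN2A", "STAT3",
        "JUN", "SMARCA4", "GDF15", "LZTS1", "SCRIB", "PHLDA3", "FAM129A",
        "SDHA", "CDK1", "PCLAF", "HSPA1A", "LMNA", "CTNNA1",
    ],
    "DDR": [
        "XPC", "DDB1", "DDB2", "BRCA1", "XRCC6", "RAD51", "RAD18", "PARP1",
        "FEN1", "CDKN1A", "LIG1", "NONO", "PIAS4", "USP5", "VCP", "TP53I3",
        "GADD45A", "FBXO32",
    ],
    "MASTL": ["MASTL", "ENSA", "ARPP19", "PPP2R2A", "PPP2R1A"],
}

DEFAULT_PATHWAY_GENES: tuple = tuple(
    g for genes in PATHWAY_SUBSETS.values() for g in genes
)


def default_gene_sets() -> GeneSetCollection:
    """The default pathway panel and its subsets as a GeneSetCollection."""
    sets = {"uvg2_all": list(DEFAULT_PATHWAY_GENES)}
    subsets = {"uvg2_all": None}
    for label, genes in PATHWAY_SUBSETS.items():
        name = f"uvg2_{label}"
        sets[name] = list(genes)
        subsets[name] = label
    return GeneSetCollection(sets=sets, subsets=subsets)


# ---------------------------------------------------------------------------
# Polysome profiling designs
# ---------------------------------------------------------------------------

@dataclass
class PolysomeSimSpec:
    """Planted-effect design for the differential polysome-loading stage.

    The planted classes mirror the structure of the checkpoint response:
    translational-only genes (polysome shift with unchanged total mRNA)
    dominate, with smaller transcriptional-only and G2-generic classes; the
    remainder are null. All planted effects are ``effect_logfc`` log2 units
    upward.
    """

    n_genes: int = 1000
    n_replicates: int = 3
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    noise_sd: float = 0.3
    frac_transcriptional: float = 0.01
    frac_translational: float = 0.05
    frac_g2_generic: float = 0.01
    effect_logfc: float = 2.0
    rnaseq_dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self):
        fracs = (self.frac_transcriptional, self.frac_translational, self.frac_g2_generic)
        if any(f < 0 for f in fracs) or sum(fracs) > 1:
            raise ValueError("class proportions must be >= 0 and sum to <= 1")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per (condition, fraction)")

    @property
    def n_transcriptional(self) -> int:
        return int(round(self.frac_transcriptional * self.n_genes))

    @property
    def n_translational(self) -> int:
        return int(round(self.frac_translational * self.n_genes))

    @property
    def n_g2_generic(self) -> int:
        return int(round(self.frac_g2_generic * self.n_genes))


def _polysome_effects(spec: PolysomeSimSpec) -> tuple[pd.DataFrame, dict]:
    """Per-gene true log2 shifts for each (condition, fraction) cell."""
    classes = np.array(["null"] * spec.n_genes, dtype=object)
    i = 0
    classes[i : i + spec.n_transcriptional] = "transcriptional-only"
    i += spec.n_transcriptional
    classes[i : i + spec.n_translational] = "translational-only"
    i += spec.n_translational
    classes[i : i + spec.n_g2_generic] = "g2-generic"
    genes = [f"G{k:05d}" for k in range(spec.n_genes)]
    e = spec.effect_logfc
    eff = {
        ("AS", "total"): np.zeros(spec.n_genes),
        ("AS", "polysome"): np.zeros(spec.n_genes),
        ("G2", "total"): np.zeros(spec.n_genes),
        ("G2", "polysome"): np.where(classes == "g2-generic", e, 0.0),
        ("UVG2", "total"): np.where(classes == "transcriptional-only", e, 0.0),
        ("UVG2", "polysome"): np.where(
            np.isin(classes, ["transcriptional-only", "translational-only", "g2-generic"]),
            e,
            0.0,
        ),
    }
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "class": classes,
            "logfc_uvg2_polysome": eff[("UVG2", "polysome")],
            "logfc_uvg2_total": eff[("UVG2", "total")],
            "logfc_g2_polysome": eff[("G2", "polysome")],
        }
    ).set_index("gene_id")
    return truth, eff


def gen_polysome(
    spec: PolysomeSimSpec,
) -> tuple[ExpressionDataset, ExpressionDataset, pd.DataFrame]:
    """Generate paired microarray and RNA-seq datasets plus the truth table.

    Both datasets share gene identifiers and design (3 conditions x 2
    fractions x ``n_replicates``). Microarray noise is Gaussian on the log2
    scale; RNA-seq counts are negative binomial around 2**(baseline+effect)
    with gene-wise dispersion ``rnaseq_dispersion``.
    """
    rng = np.random.default_rng(spec.seed)
    truth, eff = _polysome_effects(spec)
    genes = list(truth.index)
    baseline = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, spec.n_genes)

    sample_ids, meta_rows, design = [], [], []
    for cond in ("AS", "G2", "UVG2"):
        for frac in ("total", "polysome"):
            for r in range(1, spec.n_replicates + 1):
                sid = f"{cond}_{frac}_r{r}"
                sample_ids.append(sid)
                meta_rows.append((sid, cond, frac, r))
                design.append((cond, frac))
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "condition", "fraction", "replicate"]
    ).set_index("sample_id")

    mu = np.column_stack([baseline + eff[cell] for cell in design])
    ma_values = mu + rng.normal(0.0, spec.noise_sd, mu.shape)
    microarray = ExpressionDataset(
        gene_ids=genes,
        sample_ids=list(sample_ids),
        values=ma_values,
        sample_meta=meta,
        platform="microarray",
    )

    size = 1.0 / spec.rnaseq_dispersion
    mean_counts = 2.0**mu
    p = size / (size + mean_counts)
    counts = rng.negative_binomial(size, p).astype(float)
    rnaseq = ExpressionDataset(
        gene_ids=genes,
        sample_ids=list(sample_ids),
        values=counts,
        sample_meta=meta.copy(),
        platform="rnaseq",
    )
    return microarray, rnaseq, truth


# ---------------------------------------------------------------------------
# High-content screen
# ---------------------------------------------------------------------------

@dataclass
class Archetype:
    """Phenotype of one perturbation relative to the non-targeting control.

    ``viability`` multiplies post-UV cell counts; ``d4n_24`` / ``d4n_40``
    shift the 4n DNA-content fraction at 24 h and 40 h after irradiation;
    ``foci_mult_24`` / ``foci_mult_40`` multiply the mean RPA foci count.
    ``tv_24`` / ``tv_40`` multiply the transduced fraction post-UV
    (overexpression mode only).
    """

    viability: float = 1.0
    d4n_24: float = 0.0
    d4n_40: float = 0.0
    foci_mult_24: float = 1.0
    foci_mult_40: float = 1.0
    tv_24: float = 1.0
    tv_40: float = 1.0

    def __post_init__(self):
        for name in ("viability", "foci_mult_24", "foci_mult_40", "tv_24", "tv_40"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ScreenSimSpec:
    """Per-cell screen generator settings.

    DNA content is a two-component lognormal mixture over the 2n and 4n
    modes (the 4n mode is exactly twice the 2n mode) with a uniform S-phase
    bridge of weight ``s_fraction`` between them. Foci counts are negative
    binomial. Control wells (non-targeting ``NT`` and toxic ``PLK1``) are
    added when ``include_controls`` is set.
    """

    perturbations: dict = field(default_factory=dict)  # name -> Archetype
    cell_lines: tuple = ("A2058", "MM576")
    wells_per_perturbation: int = 3
    cells_per_well: int = 500
    mode_2n: float = 500.0
    log2_sd: float = 0.08
    s_fraction: float = 0.10
    base_4n: dict = field(
        default_factory=lambda: {"noUV": 0.25, "UV24": 0.55, "UV40": 0.30}
    )
    base_foci: dict = field(
        default_factory=lambda: {"noUV": 1.0, "UV24": 8.0, "UV40": 4.0}
    )
    foci_size: float = 3.0  # negative-binomial size (1/dispersion)
    include_controls: bool = True
    transduction_rate: float | None = None  # set -> overexpression mode
    seed: int = 0

    def __post_init__(self):
        if self.mode_2n <= 0:
            raise ValueError("mode_2n must be > 0")
        for tp, f in self.base_4n.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"base_4n[{tp}] outside [0,1]")
        if not 0.0 <= self.s_fraction < 1.0:
            raise ValueError("s_fraction outside [0,1)")

    @property
    def mode_4n(self) -> float:
        return 2.0 * self.mode_2n


TIMEPOINTS = ("noUV", "UV24", "UV40")


def _archetype_for(name: str, line: str, spec: ScreenSimSpec) -> Archetype:
    """Archetype for a perturbation in a given cell line.

    A perturbation may map to one Archetype (same phenotype in both lines)
    or to a dict keyed by cell line (line-specific phenotypes, e.g. to plant
    a one-line "low confidence" gene).
    """
    if name in ("NT", "cells-only", "empty-vector"):
        return Archetype()
    if name == "PLK1":
        return Archetype(viability=0.2, d4n_24=0.2)
    arch = spec.perturbations[name]
    if isinstance(arch, dict):
        return arch.get(line, Archetype())
    return arch


def gen_screen(spec: ScreenSimSpec) -> pd.DataFrame:
    """Generate the per-cell screen table.

    Returns a DataFrame with columns ``well``, ``perturbation``,
    ``cell_line``, ``timepoint``, ``dna_intensity``, ``foci_count`` and (in
    overexpression mode) ``transduced``.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.perturbations)
    if spec.include_controls:
        names = names + ["NT", "PLK1"]
    rows = []
    log2_m2n = np.log2(spec.mode_2n)
    for line in spec.cell_lines:
        for tp in TIMEPOINTS:
            for name in names:
                arch = _archetype_for(name, line, spec)
                viab = 1.0 if tp == "noUV" else arch.viability
                d4n = {"noUV": 0.0, "UV24": arch.d4n_24, "UV40": arch.d4n_40}[tp]
                fmult = {"noUV": 1.0, "UV24": arch.foci_mult_24, "UV40": arch.foci_mult_40}[tp]
                tv = {"noUV": 1.0, "UV24": arch.tv_24, "UV40": arch.tv_40}[tp]
                f4n = float(np.clip(spec.base_4n[tp] + d4n, 0.0, 1.0 - spec.s_fraction))
                f2n = 1.0 - spec.s_fraction - f4n
                for w in range(1, spec.wells_per_perturbation + 1):
                    n = rng.poisson(spec.cells_per_well * viab)
                    if n == 0:
                        continue
                    phase = rng.choice(
                        3, size=n, p=[f2n, spec.s_fraction, f4n]
                    )  # 0=2n, 1=S, 2=4n
                    log2_int = np.empty(n)
                    is2n, isS, is4n = phase == 0, phase == 1, phase == 2
                    log2_int[is2n] = log2_m2n + rng.normal(0, spec.log2_sd, is2n.sum())
                    log2_int[is4n] = log2_m2n + 1.0 + rng.normal(0, spec.log2_sd, is4n.sum())
                    log2_int[isS] = rng.uniform(log2_m2n, log2_m2n + 1.0, isS.sum())
                    mu = spec.base_foci[tp] * fmult
                    pnb = spec.foci_size / (spec.foci_size + mu)
                    foci = rng.negative_binomial(spec.foci_size, pnb, n)
                    well = f"{line}:{tp}:{name}:w{w}"
                    rec = {
                        "well": well,
                        "perturbation": name,
                        "cell_line": line,
                        "timepoint": tp,
                    }
                    df = pd.DataFrame(
                        {
                            "dna_intensity": 2.0**log2_int,
                            "foci_count": foci.astype(int),
                        }
                    )
                    for k, v in rec.items():
                        df[k] = v
                    if spec.transduction_rate is not None:
                        rate = float(np.clip(spec.transduction_rate * tv, 0.0, 1.0))
                        df["transduced"] = rng.random(n) < rate
                    rows.append(df)
    cols = ["well", "perturbation", "cell_line", "timepoint", "dna_intensity", "foci_count"]
    if spec.transduction_rate is not None:
        cols.append("transduced")
    out = pd.concat(rows, ignore_index=True)[cols]
    return out


# ---------------------------------------------------------------------------
# Melanoma-like cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSimSpec:
    """Latent-axis cohort generator.

    Each sample carries a latent dysregulation t ~ U(0,1). Pathway-gene
    expression follows gene loadings times a (by default quadratic) curve in
    t plus Gaussian noise; the UV-signature mutation load is negative
    binomial with log-mean ``load_intercept + load_slope * t`` (per-Mb
    units), and the samples with the smallest expected load are forced to
    exactly zero to emulate the zero-USM reference subgroup (the lowest-t
    samples when the slope is positive; t-independent when the slope is
    zero, keeping that case a true null). The default slope was
    calibrated once so that the true Spearman correlation between t and load
    is about 0.25 at n = 352.
    """

    n_samples: int = 352
    genes: tuple = DEFAULT_PATHWAY_GENES
    baseline_log2: float = 8.0
    loading_mean: float = 1.0
    loading_sd: float = 0.3
    quad_strength: float = 0.6
    curve: str = "quadratic"  # or "linear"
    noise_sd: float = 0.25
    shared_factor_sd: float = 0.0
    load_intercept: float = float(np.log(12.0))
    load_slope: float = 0.95
    load_size: float = 0.6
    exome_mb: float = 30.0
    zero_fraction: float = 12.0 / 352.0
    seed: int = 0

    def __post_init__(self):
        if self.load_slope < 0:
            raise ValueError("load_slope must be >= 0 (planted positive association)")
        if not 0.0 <= self.zero_fraction < 1.0:
            raise ValueError("zero_fraction outside [0,1)")
        if self.curve not in ("linear", "quadratic"):
            raise ValueError("curve must be 'linear' or 'quadratic'")


def gen_cohort(
    spec: CohortSimSpec,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Generate (expression samples x genes, load per sample, truth table)."""
    rng = np.random.default_rng(spec.seed)
    n, genes = spec.n_samples, list(spec.genes)
    t = rng.uniform(0.0, 1.0, n)
    sample_ids = [f"S{i:04d}" for i in range(n)]

    a = rng.normal(spec.loading_mean, spec.loading_sd, len(genes))
    c = (
        spec.quad_strength * rng.normal(0.0, 1.0, len(genes))
        if spec.curve == "quadratic"
        else np.zeros(len(genes))
    )
    # gene-space curve f_g(t) = a_g t + c_g (t^2 - t); linear mode has c = 0
    signal = np.outer(t, a) + np.outer(t**2 - t, c)
    noise = rng.normal(0.0, spec.noise_sd, signal.shape)
    if spec.shared_factor_sd > 0:
        u = rng.normal(0.0, spec.shared_factor_sd, n)
        w = rng.normal(0.0, 1.0, len(genes))
        noise = noise + np.outer(u, w)
    expr = pd.DataFrame(
        spec.baseline_log2 + signal + noise, index=sample_ids, columns=genes
    )

    mu = np.exp(spec.load_intercept + spec.load_slope * t) * spec.exome_mb
    p = spec.load_size / (spec.load_size + mu)
    counts = rng.negative_binomial(spec.load_size, p, n).astype(float)
    load = counts / spec.exome_mb
    n_zero = int(np.floor(spec.zero_fraction * n))
    if n_zero > 0:
        # zero out the samples with the smallest *expected* load exp(a+b*t):
        # with b > 0 these are exactly the lowest-t samples, making the
        # zero-USM subgroup genuinely reference-like (its low median
        # deregulation is the structure reported for real cohorts); with
        # b = 0 the stable sort of a constant picks samples independently of
        # t, so the null case stays null
        zero_idx = np.argsort(mu, kind="stable")[:n_zero]
        load[zero_idx] = 0.0
    loads = pd.Series(load, index=sample_ids, name="usm_per_mb")
    truth = pd.DataFrame({"t": t, "is_zero_group": loads.to_numpy() == 0.0},
                         index=sample_ids)
    return expr, loads, truth


def with_seed(spec, seed: int):
    """Copy of a sim spec with a different seed."""
    return replace(spec, seed=int(seed))
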