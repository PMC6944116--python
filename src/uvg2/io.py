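"""Readers, writers and validation for expression matrices, gene sets and run configuration.

The canonical on-disk dialect is TSV (first column gene identifiers, header
row of sample identifiers) with a separate sample-metadata table keyed by
sample id. Gene sets use the standard GMT format. Run configuration is a flat
JSON or YAML mapping.

Gene identifiers are opaque, case-sensitive strings; no alias resolution is
attempted. Missing values in expression matrices are not permitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

CONDITIONS = ("AS", "G2", "UVG2")
FRACTIONS = ("total", "polysome")
PLATFORMS = ("microarray", "rnaseq")


class ValidationError(ValueError):
    """Raised when an input table violates the dataset contract."""


@dataclass
class ExpressionDataset:
    """Gene x sample expression matrix with per-sample design metadata.

    ``values`` holds log2 intensities for ``platform="microarray"`` and
    non-negative integer read counts for ``platform="rnaseq"``.
    ``sample_meta`` is indexed by sample id with columns ``condition``
    (AS / G2 / UVG2), ``fraction`` (total / polysome) and ``replicate``
    (positive integer).
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    sample_meta: pd.DataFrame
    platform: str = "microarray"

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValidationError(f"unknown platform {self.platform!r}")
        n_genes, n_samples = len(self.gene_ids), len(self.sample_ids)
        if self.values.shape != (n_genes, n_samples):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{n_genes} genes x {n_samples} samples"
            )
        if len(set(self.gene_ids)) != n_genes:
            dups = pd.Index(self.gene_ids)
            dup = dups[dups.duplicated()].tolist()
            raise ValidationError(f"duplicate gene_ids: {dup[:5]}")
        if len(set(self.sample_ids)) != n_samples:
            raise ValidationError("duplicate sample_ids")
        missing = [s for s in self.sample_ids if s not in self.sample_meta.index]
        if missing:
            raise ValidationError(f"sample_meta missing sample(s): {missing}")
        meta = self.sample_meta.loc[self.sample_ids]
        for col in ("condition", "fraction", "replicate"):
            if col not in meta.columns:
                raise ValidationError(f"sample_meta lacks column {col!r}")
        bad_cond = sorted(set(meta["condition"]) - set(CONDITIONS))
        if bad_cond:
            raise ValidationError(f"unknown condition label(s): {bad_cond}")
        bad_frac = sorted(set(meta["fraction"]) - set(FRACTIONS))
        if bad_frac:
            raise ValidationError(f"unknown fraction label(s): {bad_frac}")
        reps = meta["replicate"]
        if not np.all(reps.astype(float) == reps.astype(float).round()) or (
            reps.astype(float) < 1
        ).any():
            raise ValidationError("replicate must be a positive integer")
        if np.isnan(self.values).any():
            raise ValidationError("expression matrix contains missing values")
        if self.platform == "rnaseq":
            if (self.values < 0).any():
                raise ValidationError("rnaseq counts must be >= 0")
            if not np.allclose(self.values, np.round(self.values)):
                raise ValidationError("rnaseq values must be integers")

    # -- access -----------------------------------------------------------
    @property
    def meta(self) -> pd.DataFrame:
        return self.sample_meta.loc[self.sample_ids]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def samples_for(self, condition: str, fraction: str) -> list:
        m = self.meta
        mask = (m["condition"] == condition) & (m["fraction"] == fraction)
        return list(m.index[mask])

    def n_replicates(self, condition: str, fraction: str) -> int:
        return len(self.samples_for(condition, fraction))

    def equals(self, other: "ExpressionDataset") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and self.platform == other.platform
            and np.allclose(self.values, other.values)
            and self.meta[["condition", "fraction", "replicate"]]
            .astype({"replicate": int})
            .equals(
                other.meta[["condition", "fraction", "replicate"]].astype(
                    {"replicate": int}
                )
            )
        )

    # -- persistence ------------------------------------------------------
    def write(self, path, meta_path, sep: str = "\t") -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep=sep)
        meta = self.meta[["condition", "fraction", "replicate"]].copy()
        meta.index.name = "sample_id"
        meta["platform"] = self.platform
        meta.to_csv(meta_path, sep=sep)


def read_expression(path, meta_path, platform: str | None = None, sep: str = "\t") -> ExpressionDataset:
    """Read a gene x sample matrix plus its sample-metadata table.

    ``platform`` overrides any ``platform`` column present in the metadata;
    when neither is given, microarray is assumed.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    meta = pd.read_csv(meta_path, sep=sep, index_col=0)
    meta.index = meta.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index = df.index.astype(str)
    if platform is None:
        platform = (
            str(meta["platform"].iloc[0]) if "platform" in meta.columns else "microarray"
        )
    return ExpressionDataset(
        gene_ids=list(df.index),
        sample_ids=list(df.columns),
        values=df.to_numpy(dtype=float),
        sample_meta=meta,
        platform=platform,
    )


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named, ordered gene sets with an optional subset label per set.

    The GMT description field carries the subset label (e.g. DDR,
    checkpoint, MASTL); an empty or "na" description means no label.
    """

    sets: dict = field(default_factory=dict)  # name -> ordered list of gene ids
    subsets: dict = field(default_factory=dict)  # name -> label or None

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {name!r} has duplicate members")
        for name in self.sets:
            self.subsets.setdefault(name, None)

    def __len__(self):
        return len(self.sets)

    def __getitem__(self, name):
        return self.sets[name]

    def names(self):
        return list(self.sets)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                desc = self.subsets.get(name) or "na"
                fh.write("\t".join([name, desc, *members]) + "\n")


def read_gene_sets(path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`."""
    sets, subsets = {}, {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                raise ValidationError(f"{path}: empty line at line {lineno}")
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: gene set with no members"
                )
            name, desc, members = parts[0], parts[1], [p for p in parts[2:] if p]
            if not members:
                raise ValidationError(
                    f"{path}: line {lineno}: gene set {name!r} is empty"
                )
            if name in sets:
                raise ValidationError(
                    f"{path}: line {lineno}: duplicate gene set name {name!r}"
                )
            sets[name] = members
            subsets[name] = None if desc.lower() in ("", "na", "none") else desc
    return GeneSetCollection(sets=sets, subsets=subsets)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable thresholds of the analysis chain in one place.

    Defaults follow the published selection rules where stated (fold-change
    cutoff 2, B > 0, mutation-load boundaries 3.6 and 54.6 per Mb) and the
    package's own documented choices elsewhere.
    """

    fc_cutoff: float = 2.0
    b_cutoff: float = 0.0
    g2_similarity_logfc: float = 1.0
    prior_de_proportion: float = 0.01
    load_boundaries: tuple = (3.6, 54.6)
    var_fraction: float = 0.9
    curve_tol: float = 1e-4
    curve_max_iter: int = 50
    curve_span: float = 0.3
    s_phase_margin: float = 0.15
    min_cells_per_well: int = 200
    sirna_rubric: dict = field(default_factory=dict)
    oe_rubric: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        self.load_boundaries = tuple(float(b) for b in self.load_boundaries)
        for name in (
            "fc_cutoff",
            "b_cutoff",
            "g2_similarity_logfc",
            "prior_de_proportion",
            "var_fraction",
            "curve_tol",
            "s_phase_margin",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        if self.fc_cutoff < 1:
            raise ValidationError("fc_cutoff must be >= 1 (linear fold scale)")
        lo, hi = self.load_boundaries
        if not (0 < lo < hi):
            raise ValidationError("load_boundaries must be strictly increasing and positive")
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ValidationError("seed must be a non-negative integer")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        return cls(**data)

    def to_file(self, path) -> None:
        data = asdict(self)
        data["load_boundaries"] = list(self.load_boundaries)
        text = (
            json.dumps(data, indent=2)
            if str(path).endswith(".json")
            else yaml.safe_dump(data)
        )
        Path(path).write_text(text)
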