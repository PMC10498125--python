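"""Readers, writers, and schema validation for every on-disk artifact.

All tabular artifacts are plain TSV. In-memory containers are pandas
DataFrames with fixed column contracts:

* expression matrix  — genes (index) x samples (columns), log2-scale floats
* clinical table     — one row per sample; four survival endpoints plus
                       demographic / stage covariates, any of which may be NA
* segment table      — SEG-convention copy-number segments (1-based inclusive)
* mutation table     — MAF-lite: sample, gene, variant classification
* feature table      — sample-indexed continuous features (immune scores,
                       stemness/HRD indexes, ...)
* genome arm model   — BED-like table of chromosome arms (p/q per chromosome)

Every schema violation raises :class:`SchemaError` naming the offending
record; nothing is silently coerced.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("kifscore")

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "load_config",
    "save_config",
    "MAF_CLASSES",
    "NONSILENT_CLASSES",
    "read_expression",
    "write_expression",
    "validate_expression",
    "read_clinical",
    "write_clinical",
    "validate_clinical",
    "read_segments",
    "write_segments",
    "validate_segments",
    "read_mutations",
    "write_mutations",
    "read_features",
    "write_features",
    "load_arm_model",
    "write_arm_model",
    "validate_arm_model",
    "toy_arm_model",
    "TOY_CHROM_LENGTHS",
]


class SchemaError(ValueError):
    """An on-disk artifact violated its schema."""


# Controlled vocabulary of MAF variant classifications (the three-column
# MAF-lite reader accepts only these tokens).
MAF_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Silent",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Nonstop_Mutation",
        "3'UTR",
        "5'UTR",
        "Intron",
        "RNA",
    }
)

#: Classifications counted toward tumor mutation burden.
NONSILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Nonstop_Mutation",
    }
)

ENDPOINTS = ("OS", "DSS", "DFI", "PFI")

CLINICAL_COLUMNS = (
    ["sample", "cohort"]
    + [f"{e}_{k}" for e in ENDPOINTS for k in ("time", "event")]
    + ["age", "sex", "race", "stage_T", "stage_N", "stage_M", "vital_status"]
)

SEGMENT_COLUMNS = ["sample", "chromosome", "start", "end", "log2_ratio"]
MUTATION_COLUMNS = ["sample", "gene", "variant_classification"]
ARM_COLUMNS = ["chromosome", "start", "end", "arm"]


@dataclasses.dataclass
class PipelineConfig:
    """Every tunable threshold in the pipeline, defaulting to the published values.

    alpha              Wald p-value cutoff for per-gene risk classification.
    tau                weight exponent of the enrichment random walk.
    kernel             per-gene CDF estimator: "gauss" (Gaussian kernel,
                       bandwidth sd/4) or "ecdf" (empirical CDF).
    focal_fraction     a segment shorter than this fraction of its arm is focal.
    arm_call_threshold arm-level gain/loss call boundary on the mean log2 ratio.
    exome_size_mb      denominator for mutations-per-megabase TMB.
    lfc_cut, padj_cut  differential-expression filter thresholds.
    """

    alpha: float = 0.05
    tau: float = 1.0
    kernel: str = "gauss"
    bandwidth_factor: float = 4.0
    pooled_gsva: bool = False
    drop_never_significant: bool = False
    focal_fraction: float = 0.5
    arm_call_threshold: float = 0.25
    arm_indicator_mode: bool = False
    exome_size_mb: float = 38.0
    lfc_cut: float = 1.0
    padj_cut: float = 0.05


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# expression matrix


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise SchemaError(f"duplicate gene identifiers: {dups}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise SchemaError(f"duplicate sample identifiers: {dups}")
    if expr.shape[1] < 2:
        raise SchemaError(
            f"expression matrix has {expr.shape[1]} sample(s); at least 2 are "
            "required to estimate cross-sample distributions"
        )
    numeric = expr.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~expr.isna()
    if bad.any().any():
        gi, sj = np.argwhere(bad.to_numpy())[0]
        raise SchemaError(
            f"non-numeric expression value at gene {expr.index[gi]!r}, "
            f"sample {expr.columns[sj]!r}: {expr.iat[gi, sj]!r}"
        )
    if numeric.isna().any().any():
        gi, sj = np.argwhere(numeric.isna().to_numpy())[0]
        raise SchemaError(
            f"missing expression value at gene {expr.index[gi]!r}, "
            f"sample {expr.columns[sj]!r}"
        )
    out = numeric.astype(float)
    if not np.isfinite(out.to_numpy()).all():
        gi, sj = np.argwhere(~np.isfinite(out.to_numpy()))[0]
        raise SchemaError(
            f"non-finite expression value at gene {out.index[gi]!r}, "
            f"sample {out.columns[sj]!r}"
        )
    out.index.name = "gene"
    return out


def read_expression(path: str | Path, orientation: str = "genes_by_samples") -> pd.DataFrame:
    """Read a TSV expression matrix; first column holds row identifiers."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "samples_by_genes":
        df = df.T
    elif orientation != "genes_by_samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    expr = validate_expression(df)
    logger.info("read expression matrix %s: %d genes x %d samples", path, *expr.shape)
    return expr


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# clinical table


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("sample", "cohort") if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table missing columns: {missing}")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise SchemaError(f"duplicate sample identifiers in clinical table: {dups}")
    df = df.copy()
    for ep in ENDPOINTS:
        tcol, ecol = f"{ep}_time", f"{ep}_event"
        if tcol in df.columns:
            times = pd.to_numeric(df[tcol], errors="coerce")
            if ((times < 0) & df[tcol].notna()).any():
                bad = df.loc[times < 0, "sample"].iloc[0]
                raise SchemaError(f"negative {tcol} for sample {bad!r}")
            df[tcol] = times
        if ecol in df.columns:
            events = pd.to_numeric(df[ecol], errors="coerce")
            ok = events.isin([0, 1]) | df[ecol].isna()
            if not ok.all():
                bad = df.loc[~ok, "sample"].iloc[0]
                raise SchemaError(f"{ecol} not in {{0,1}} for sample {bad!r}")
            df[ecol] = events
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    df = validate_clinical(df)
    logger.info("read clinical table %s: %d samples", path, len(df))
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# copy-number segments (SEG convention: 1-based inclusive coordinates)

_SEG_ALIASES = {
    "Sample": "sample",
    "Chromosome": "chromosome",
    "Start": "start",
    "End": "end",
    "Segment_Mean": "log2_ratio",
}


def validate_segments(df: pd.DataFrame, chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    df = df.rename(columns=_SEG_ALIASES)
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"segment table missing columns: {missing}")
    df = df[SEGMENT_COLUMNS].copy()
    df["start"] = pd.to_numeric(df["start"], errors="raise").astype(int)
    df["end"] = pd.to_numeric(df["end"], errors="raise").astype(int)
    ratios = pd.to_numeric(df["log2_ratio"], errors="coerce")
    if ratios.isna().any() or not np.isfinite(ratios).all():
        row = df.loc[~np.isfinite(ratios.fillna(np.inf))].iloc[0]
        raise SchemaError(
            f"non-numeric log2 ratio in segment {row['sample']}:"
            f"{row['chromosome']}:{row['start']}-{row['end']}"
        )
    df["log2_ratio"] = ratios.astype(float)
    bad = df["start"] >= df["end"]
    if bad.any():
        row = df.loc[bad].iloc[0]
        raise SchemaError(
            f"segment with start >= end: {row['sample']}:"
            f"{row['chromosome']}:{row['start']}-{row['end']}"
        )
    if chrom_lengths is not None:
        unknown = set(df["chromosome"].astype(str)) - set(chrom_lengths)
        if unknown:
            raise SchemaError(f"unknown chromosome name(s): {sorted(unknown)}")
    df["chromosome"] = df["chromosome"].astype(str)
    return df.reset_index(drop=True)


def read_segments(path: str | Path, chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = validate_segments(df, chrom_lengths)
    logger.info("read segment table %s: %d segments", path, len(df))
    return df


def write_segments(df: pd.DataFrame, path: str | Path) -> None:
    df[SEGMENT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MAF-lite mutations


def read_mutations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"mutation table missing columns: {missing}")
    unknown = set(df["variant_classification"]) - MAF_CLASSES
    if unknown:
        raise SchemaError(f"unknown variant classification(s): {sorted(unknown)}")
    logger.info("read mutation table %s: %d records", path, len(df))
    return df[MUTATION_COLUMNS].copy()


def write_mutations(df: pd.DataFrame, path: str | Path) -> None:
    df[MUTATION_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# per-sample continuous feature tables


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise SchemaError("feature table missing 'sample' column")
    if df["sample"].duplicated().any():
        raise SchemaError("duplicate sample identifiers in feature table")
    if df.columns.duplicated().any():
        raise SchemaError("duplicate feature names")
    df = df.set_index("sample")
    values = df.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & df.notna()
    if bad.any().any():
        si, fj = np.argwhere(bad.to_numpy())[0]
        raise SchemaError(
            f"non-numeric feature value at sample {df.index[si]!r}, "
            f"feature {df.columns[fj]!r}"
        )
    logger.info("read feature table %s: %d samples x %d features", path, *values.shape)
    return values.astype(float)


def write_features(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# genome arm model

#: Synthetic toy genome used by the cohort generator: chromosome -> length (bp).
TOY_CHROM_LENGTHS = {"chr1": 200_000_000, "chr2": 150_000_000, "chr3": 120_000_000, "chr4": 100_000_000}

#: Fraction of each toy chromosome assigned to the p arm (centromere position).
_TOY_P_FRACTION = 0.4


def toy_arm_model() -> pd.DataFrame:
    """Arm model of the packaged synthetic toy genome (one p and one q per chromosome)."""
    rows = []
    for chrom, length in TOY_CHROM_LENGTHS.items():
        centromere = int(length * _TOY_P_FRACTION)
        rows.append({"chromosome": chrom, "start": 1, "end": centromere, "arm": "p"})
        rows.append({"chromosome": chrom, "start": centromere + 1, "end": length, "arm": "q"})
    return pd.DataFrame(rows, columns=ARM_COLUMNS)


def validate_arm_model(df: pd.DataFrame, chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    missing = [c for c in ARM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"arm model missing columns: {missing}")
    df = df[ARM_COLUMNS].copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["chromosome"] = df["chromosome"].astype(str)
    for chrom, grp in df.groupby("chromosome"):
        arms = sorted(grp["arm"])
        if arms != ["p", "q"]:
            raise SchemaError(f"chromosome {chrom} must have exactly arms p and q, got {arms}")
        p = grp[grp["arm"] == "p"].iloc[0]
        q = grp[grp["arm"] == "q"].iloc[0]
        # 1-based inclusive intervals overlap iff starts/ends interleave
        if p["start"] <= q["end"] and q["start"] <= p["end"]:
            raise SchemaError(f"overlapping p/q arms on chromosome {chrom}")
        if chrom_lengths is not None:
            declared = chrom_lengths.get(chrom)
            if declared is None:
                raise SchemaError(f"arm model chromosome {chrom} not in declared genome")
            tiled = (p["end"] - p["start"] + 1) + (q["end"] - q["start"] + 1)
            if tiled != declared:
                raise SchemaError(
                    f"arms of {chrom} tile {tiled} bp but chromosome is {declared} bp"
                )
    return df.reset_index(drop=True)


def load_arm_model(path: str | Path, chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = validate_arm_model(df, chrom_lengths)
    logger.info("read arm model %s: %d arms", path, len(df))
    return df


def write_arm_model(df: pd.DataFrame, path: str | Path) -> None:
    df[ARM_COLUMNS].to_csv(path, sep="\t", index=False)
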