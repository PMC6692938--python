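"""Domain containers and TSV readers/writers shared by every pipeline stage.

All tables are tab-separated UTF-8 with a header row. Methylation is carried
as beta values (fraction of methylated cytosines, ``beta = mC/(mC+C)``), so
every non-missing entry must lie in [0, 1]. Readers validate and reject;
they never silently coerce out-of-range betas or unknown categorical codes.
Missing betas are empty cells and propagate as NaN; downstream statistics
use pairwise deletion per probe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("cptmethsig")

ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
GENE_REGION_GROUPS = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")
DIAGNOSES = ("CPC", "aCPP", "CPP")
TP53_STATES = ("wt", "het", "hom", "unknown")
AGE_CLASSES = ("pediatric", "adult", "unknown")

ANNOTATION_COLUMNS = [
    "probe_id", "chr", "pos", "gene", "gene_region", "island_relation",
    "enhancer", "dhs", "cdmr", "rdmr", "snp_proximal", "cross_reactive",
    "is_control",
]
_ANNOTATION_BOOL = ["enhancer", "dhs", "cdmr", "rdmr", "snp_proximal",
                    "cross_reactive", "is_control"]
METADATA_COLUMNS = [
    "sample_id", "diagnosis", "tp53", "age_class", "os_time",
    "death_event", "recurrence_event", "cohort",
]


class SchemaError(ValueError):
    """A table is missing columns or contains values outside its vocabulary."""


class BetaValueError(ValueError):
    """A methylation value falls outside [0, 1]."""


def _parse_bool(series: pd.Series, column: str) -> pd.Series:
    mapping = {"0": False, "1": True, "TRUE": True, "FALSE": False,
               "True": True, "False": False}
    out = series.astype(str).str.strip().map(mapping)
    if out.isna().any():
        bad = series[out.isna()].iloc[0]
        raise SchemaError(f"column {column!r}: unparseable boolean value {bad!r}")
    return out.astype(bool)


@dataclass
class BetaMatrix:
    """CpG probes x samples matrix of methylation fractions in [0, 1].

    ``values.loc[probe, sample]`` is the beta value; NaN marks missing.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise SchemaError(f"duplicate probe id {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise SchemaError(f"duplicate sample id {dup!r}")
        vals = self.values.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise BetaValueError(
                f"beta value {vals[i, j]!r} out of [0,1] at probe "
                f"{idx[i]!r}, sample {cols[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def restrict_probes(self, probes: Iterable[str]) -> "BetaMatrix":
        probes = [p for p in probes if p in self.values.index]
        return BetaMatrix(self.values.loc[probes])

    def restrict_samples(self, samples: Iterable[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[:, list(samples)])


@dataclass
class ExpressionMatrix:
    """Genes x samples log-scale expression with optional per-gene statistics.

    ``gene_stats`` carries the CPC-vs-CPP differential expression summary
    (``log2fc`` and BH-adjusted ``q``) consumed by the methylation/expression
    concordance stage.
    """

    values: pd.DataFrame
    gene_stats: pd.DataFrame | None = None  # index gene, columns log2fc, q

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise SchemaError("duplicate gene symbol in expression matrix")
        if self.gene_stats is not None:
            missing = {"log2fc", "q"} - set(self.gene_stats.columns)
            if missing:
                raise SchemaError(f"gene stats missing columns {sorted(missing)}")

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.values.index)


def read_beta_matrix(path) -> BetaMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "probe_id":
        raise SchemaError(
            f"{path}: first column must be 'probe_id', got {df.columns[0]!r}"
        )
    df = df.set_index("probe_id")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = df.index[bad][0]
            raise SchemaError(f"{path}: non-numeric cell at probe {row!r}, sample {col!r}")
        df[col] = coerced
    return BetaMatrix(df.astype(float))


def write_beta_matrix(matrix: BetaMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6g")


def read_annotation(path) -> pd.DataFrame:
    """Read probe annotation mirroring the Illumina 450K manifest fields.

    Returns a DataFrame indexed by probe_id. ``gene`` and ``gene_region``
    are semicolon-separated parallel lists (possibly empty), as in the
    manifest's UCSC_RefGene columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: annotation missing columns {sorted(missing)}")
    return _validate_annotation(df)


def _validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if df["probe_id"].duplicated().any():
        raise SchemaError("duplicate probe_id in annotation")
    bad = ~df["island_relation"].isin(ISLAND_RELATIONS)
    if bad.any():
        raise SchemaError(
            f"unknown island_relation {df.loc[bad, 'island_relation'].iloc[0]!r}"
        )
    for g, r in zip(df["gene"], df["gene_region"]):
        ng = len([x for x in g.split(";") if x])
        nr = len([x for x in r.split(";") if x])
        if ng != nr:
            raise SchemaError(f"gene/gene_region length mismatch: {g!r} vs {r!r}")
    for col in _ANNOTATION_BOOL:
        if df[col].dtype != bool:
            df[col] = _parse_bool(df[col], col)
    df["pos"] = pd.to_numeric(df["pos"]).astype(int)
    return df.set_index("probe_id", drop=False)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    out = annotation.copy()
    for col in _ANNOTATION_BOOL:
        out[col] = out[col].map({True: "TRUE", False: "FALSE"})
    out.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata (diagnosis, TP53 zygosity, outcomes, cohort)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: metadata missing columns {sorted(missing)}")
    return _validate_metadata(df)


def _validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if df["sample_id"].duplicated().any():
        raise SchemaError("duplicate sample_id in metadata")
    for col, vocab in (("diagnosis", DIAGNOSES), ("tp53", TP53_STATES),
                       ("age_class", AGE_CLASSES)):
        bad = ~df[col].isin(vocab)
        if bad.any():
            raise SchemaError(
                f"unknown {col} value {df.loc[bad, col].iloc[0]!r}"
            )
    df["os_time"] = pd.to_numeric(df["os_time"].replace("", np.nan))
    if (df["os_time"].dropna() < 0).any():
        raise SchemaError("negative os_time")
    for col in ("death_event", "recurrence_event"):
        blank = df[col].astype(str).str.strip() == ""
        parsed = pd.Series(pd.NA, index=df.index, dtype="boolean")
        if (~blank).any():
            parsed[~blank] = _parse_bool(df.loc[~blank, col], col)
        df[col] = parsed
    if (df["os_time"].notna() & df["death_event"].isna()).any():
        raise SchemaError("death_event must be present wherever os_time is present")
    return df.set_index("sample_id", drop=False)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    for col in ("death_event", "recurrence_event"):
        out[col] = out[col].map({True: "TRUE", False: "FALSE", pd.NA: ""})
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_expression(path, stats_path=None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_symbol":
        raise SchemaError(
            f"{path}: first column must be 'gene_symbol', got {df.columns[0]!r}"
        )
    df = df.set_index("gene_symbol").astype(float)
    stats = None
    if stats_path is not None:
        stats = pd.read_csv(stats_path, sep="\t", dtype={0: str})
        missing = {"gene_symbol", "log2fc", "q"} - set(stats.columns)
        if missing:
            raise SchemaError(f"{stats_path}: missing columns {sorted(missing)}")
        stats = stats.set_index("gene_symbol")[["log2fc", "q"]].astype(float)
    return ExpressionMatrix(df, stats)


def write_expression(expr: ExpressionMatrix, path, stats_path=None) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_symbol", float_format="%.6g")
    if stats_path is not None and expr.gene_stats is not None:
        expr.gene_stats.to_csv(stats_path, sep="\t", index_label="gene_symbol",
                               float_format="%.6g")


def split_gene_regions(annotation_row: pd.Series) -> list[tuple[str, str]]:
    """Parallel (gene, region_group) pairs for one annotation record."""
    genes = [g for g in annotation_row["gene"].split(";") if g]
    regions = [r for r in annotation_row["gene_region"].split(";") if r]
    return list(zip(genes, regions))
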