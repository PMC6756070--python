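"""Readers and writers for the pipeline's tabular formats.

Segment tables (relative and allelic) travel as TSV with 1-based inclusive
coordinates; gene annotation as BED (0-based half-open).  Everything is
converted to 0-based half-open on read.  Chromosome labels are normalized
("chr1" == "1"); X/Y rows are dropped with a logged count, since only
autosomes are analysed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_segments",
    "read_allelic",
    "read_bed",
    "read_expression",
    "read_metadata",
    "write_segments",
    "write_allelic",
    "write_bed",
    "write_expression",
    "write_metadata",
    "write_cohort",
    "write_json",
]


class ParseError(ValueError):
    """Malformed input file; message names the file and the problem."""


def _normalize_chrom(series: pd.Series, path: Path) -> pd.Series:
    s = series.astype(str).str.replace("^chr", "", regex=True)
    sex = s.isin(["X", "Y", "x", "y", "MT", "M"])
    if sex.any():
        log.warning("%s: dropped %d non-autosomal rows", path.name, int(sex.sum()))
    s[sex] = np.nan
    out = pd.to_numeric(s, errors="coerce")
    bad = out.isna() & ~sex
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ParseError(f"{path}: unparseable chromosome at line {line}")
    return out


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")


def _check_intervals(df: pd.DataFrame, path: Path, per_sample: bool) -> None:
    if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
        raise ParseError(f"{path}: negative or inverted coordinates")
    keys = ["sample", "chrom", "start", "end"] if per_sample else ["chrom", "start", "end"]
    if df.duplicated(subset=keys).any():
        raise ParseError(f"{path}: duplicate interval rows")


def _read_interval_tsv(path: str | Path, value_cols: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample", "chrom", "start", "end"] + value_cols, path)
    df["chrom"] = _normalize_chrom(df["chrom"], path)
    df = df.dropna(subset=["chrom"]).copy()
    df["chrom"] = df["chrom"].astype(int)
    df["start"] = df["start"].astype(int) - 1  # 1-based inclusive -> 0-based half-open
    df["end"] = df["end"].astype(int)
    _check_intervals(df, path, per_sample=True)
    return df.reset_index(drop=True)


def read_segments(path: str | Path) -> pd.DataFrame:
    """SEG-like relative copy-number segments (sample, chrom, start, end, value)."""
    df = _read_interval_tsv(path, ["value"])
    if not np.isfinite(df["value"]).all():
        raise ParseError(f"{path}: non-finite segment values")
    return df[["sample", "chrom", "start", "end", "value"]]


def read_allelic(path: str | Path) -> pd.DataFrame:
    """Allele-specific segments (sample, chrom, start, end, nA, nB)."""
    df = _read_interval_tsv(path, ["nA", "nB"])
    if (df[["nA", "nB"]] < 0).any().any():
        raise ParseError(f"{path}: negative allele copy numbers")
    df["nA"] = df["nA"].astype(int)
    df["nB"] = df["nB"].astype(int)
    return df[["sample", "chrom", "start", "end", "nA", "nB"]]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Gene annotation BED (chrom, start, end, gene_id, score, strand);
    strand and score are ignored.  The optional 7th column carries the arm."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ParseError(f"{path}: BED needs at least 4 columns")
    names = ["chrom", "start", "end", "gene_id", "score", "strand", "arm"][: df.shape[1]]
    df.columns = names
    df["chrom"] = _normalize_chrom(df["chrom"], path)
    df = df.dropna(subset=["chrom"]).copy()
    df["chrom"] = df["chrom"].astype(int)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
        raise ParseError(f"{path}: negative or inverted coordinates")
    if df["gene_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate gene_id")
    df["symbol"] = df["gene_id"]
    if "arm" not in df:
        df["arm"] = ""
    return df[["gene_id", "symbol", "chrom", "start", "end", "arm"]].reset_index(drop=True)


def read_expression(path: str | Path) -> pd.DataFrame:
    """log2 expression matrix, genes in rows (index column gene_id)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "gene_id":
        raise ParseError(f"{path}: first column must be gene_id")
    if df.index.duplicated().any():
        raise ParseError(f"{path}: duplicate gene_id rows")
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    _require_columns(df.reset_index(), ["sample"], path)
    for col in ("msi", "cms"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col}")
    if "event" in df.columns:
        df["event"] = df["event"].astype(bool)
    return df


def write_segments(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["start"] = out["start"].astype(int) + 1  # back to 1-based inclusive
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


write_allelic = write_segments


def write_bed(genes: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"],
            "end": genes["end"],
            "gene_id": genes["gene_id"],
            "score": 0,
            "strand": "+",
            "arm": genes.get("arm", ""),
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample", float_format="%.6g")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def write_cohort(sim: dict, directory: str | Path) -> dict[str, Path]:
    """Write a simulated cohort in the exact formats the readers consume."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "segments": d / "relative_segments.tsv",
        "allelic": d / "allelic_segments.tsv",
        "genes": d / "genes.bed",
        "expression": d / "expression.tsv",
        "metadata": d / "metadata.tsv",
        "compartment_expression": d / "compartment_expression.tsv",
        "compartment_labels": d / "compartment_labels.tsv",
        "truth": d / "truth.json",
    }
    write_segments(sim["relative_segments"], paths["segments"])
    write_allelic(sim["allelic_segments"], paths["allelic"])
    write_bed(sim["genes"], paths["genes"])
    write_expression(sim["expression"], paths["expression"])
    write_metadata(sim["metadata"], paths["metadata"])
    write_expression(sim["compartment_expression"], paths["compartment_expression"])
    sim["compartment_labels"].rename("compartment").to_frame().to_csv(
        paths["compartment_labels"], sep="\t", index_label="sample"
    )
    truth = sim["truth"]
    write_json(
        {
            "seed": truth.seed,
            "true_hazard_ratio": truth.true_hazard_ratio,
            "gene_truth": truth.gene_truth.reset_index().to_dict(orient="list"),
            "sample_truth": truth.sample_truth.reset_index().to_dict(orient="list"),
            "amplifications": truth.amplifications.to_dict(orient="list"),
        },
        paths["truth"],
    )
    return paths
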