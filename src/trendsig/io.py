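"""Readers/writers for the plain-text formats the pipeline exchanges.

Everything is TSV/CSV/BED/JSON; genomic intervals follow BED convention
(0-based half-open) on disk and in memory.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import InputError, ValidationError

TISSUE_CLASSES = ("NORM", "DTC", "ATC")

# ---------------------------------------------------------------- expression


def read_expression(path) -> pd.DataFrame:
    """Probe x sample log2 matrix from TSV (first column = probe id)."""
    try:
        m = pd.read_csv(path, sep="\t", index_col=0)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise InputError(f"malformed expression matrix {path}: {exc}") from exc
    if m.index.duplicated().any() or m.columns.duplicated().any():
        raise ValidationError("duplicate probe or sample ids in expression matrix")
    if not m.map(lambda v: isinstance(v, (int, float))).all().all():
        raise ValidationError("non-numeric values in expression matrix")
    return m.astype(float)


def write_expression(m: pd.DataFrame, path) -> None:
    m.to_csv(path, sep="\t", index_label="probe_id")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "tissue", "study"}
    if not required <= set(sheet.columns):
        raise InputError(f"sample sheet {path} must have columns {sorted(required)}")
    bad = set(sheet["tissue"]) - set(TISSUE_CLASSES)
    if bad:
        raise ValidationError(f"unknown tissue classes {sorted(bad)}")
    if sheet["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids in sample sheet")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_probe_map(path) -> pd.DataFrame:
    pm = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_id"} <= set(pm.columns):
        raise InputError(f"probe map {path} needs columns probe_id, gene_id")
    if pm["probe_id"].duplicated().any():
        raise ValidationError("probe mapped to more than one gene")
    return pm


def write_probe_map(pm: pd.DataFrame, path) -> None:
    pm.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- network


def read_edge_list(path) -> pd.DataFrame:
    """Two gene columns plus optional confidence score in [0, 1]."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise InputError(f"edge list {path} needs >= 2 columns")
    df = df.iloc[:, :3]
    df.columns = ["gene_a", "gene_b", "score"][: df.shape[1]]
    if "score" not in df.columns:
        df["score"] = 1.0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if pd.isna(row.gene_a) or pd.isna(row.gene_b) or pd.isna(row.score):
            raise InputError(f"edge list {path}: malformed row at line {i}")
    df["score"] = pd.to_numeric(df["score"], errors="raise")
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        raise ValidationError("edge scores must lie in [0, 1]")
    return df.astype({"gene_a": str, "gene_b": str})


def write_edge_list(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------- peaks

_NARROWPEAK_COLS = ["chrom", "start", "end", "name", "score", "strand",
                    "signal", "pvalue", "qvalue", "summit"]


def read_peaks(path) -> pd.DataFrame:
    """BED3/BED6/narrowPeak reader; column count auto-detected."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    if ncol < 3:
        raise InputError(f"{path}: need >= 3 BED columns, found {ncol}")
    df.columns = _NARROWPEAK_COLS[:ncol]
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] >= df["end"]).any():
        raise ValidationError(f"{path}: intervals must satisfy start < end")
    return df


def write_peaks(df: pd.DataFrame, path) -> None:
    cols = [c for c in _NARROWPEAK_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


# --------------------------------------------------------------- DEG tables


def read_deg_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "fdr"}
    if not required <= set(df.columns):
        raise InputError(f"DEG table {path} needs columns {sorted(required)}")
    for i, v in enumerate(df["fdr"], start=2):
        try:
            f = float(v)
        except (TypeError, ValueError):
            raise InputError(f"DEG table {path}: non-numeric FDR at line {i}")
        if not 0 <= f <= 1:
            raise ValidationError(f"DEG table {path}: FDR outside [0,1] at line {i}")
    return df.astype({"gene_id": str, "log2fc": float, "fdr": float})


def write_deg_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- nanostring


def read_nanostring(counts_path, samples_path):
    """Raw count CSV (gene, class, one column per sample) + sample metadata CSV."""
    counts = pd.read_csv(counts_path)
    if not {"gene", "class"} <= set(counts.columns):
        raise InputError(f"{counts_path} needs 'gene' and 'class' columns")
    classes = counts.set_index("gene")["class"]
    bad = set(classes) - {"Endogenous", "Positive", "Negative", "Housekeeping"}
    if bad:
        raise ValidationError(f"unknown code classes {sorted(bad)}")
    mat = counts.set_index("gene").drop(columns="class")
    meta = pd.read_csv(samples_path, dtype=str)
    if not {"sample_id", "tissue"} <= set(meta.columns):
        raise InputError(f"{samples_path} needs sample_id and tissue columns")
    return mat.astype(float), classes, meta


def write_nanostring(mat: pd.DataFrame, classes: pd.Series, meta: pd.DataFrame,
                     counts_path, samples_path) -> None:
    out = mat.copy()
    out.insert(0, "class", classes.loc[out.index].to_numpy())
    out.to_csv(counts_path, index_label="gene")
    meta.to_csv(samples_path, index=False)


# --------------------------------------------------------------------- JSON


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
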