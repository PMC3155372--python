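"""Readers and writers for the on-disk formats used by the pipeline.

Expression matrices, sample metadata and clinical chemistry travel as
tab/comma-delimited tables; gene sets use the Broad-standard GMT dialect.
Readers validate and reject malformed input rather than coercing it;
expression and metadata are joined on exact string sample ids (silent
misjoins are the classic failure of this pipeline shape).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel

VALID_DRUGS = ("V", "E", "T")

METADATA_COLUMNS = ("animal_id", "drug", "dose_code")


class ParseError(ValueError):
    """Malformed input file; the message names the offending row/column."""


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column = gene id).

    Returns a DataFrame indexed by gene id with sample-id columns.
    Raises :class:`ParseError` on duplicate ids or non-numeric cells.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate gene id {dup!r} in {path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"duplicate sample id {dup!r} in {path}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ParseError(
                f"non-numeric cell in column {col!r}, row {bad.index[0]!r} of {path}"
            )
    if not np.isfinite(df.to_numpy()).all():
        raise ParseError(f"non-finite expression value in {path}")
    return df


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata (animal_id, drug in {V,E,T}, dose_code 0-3)."""
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"metadata {path} missing column(s) {missing}")
    if df["animal_id"].duplicated().any():
        dup = df.loc[df["animal_id"].duplicated(), "animal_id"].iloc[0]
        raise ParseError(f"duplicate animal id {dup!r} in {path}")
    bad = set(df["drug"]) - set(VALID_DRUGS)
    if bad:
        raise ParseError(f"unknown drug code(s) {sorted(bad)} in {path}")
    df["dose_code"] = df["dose_code"].astype(int)
    if ((df["drug"] == "V") != (df["dose_code"] == 0)).any():
        raise ParseError(f"vehicle rows must (and only they may) have dose_code 0 in {path}")
    return validate_metadata(df)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    if (meta["dose_code"] < 0).any() or (meta["dose_code"] > 3).any():
        raise ParseError("dose_code outside the ordinal range 0-3")
    return meta.reset_index(drop=True)


def reconcile(expr: pd.DataFrame, meta: pd.DataFrame) -> None:
    """Error unless expression samples and metadata rows match one-to-one."""
    e, m = set(expr.columns), set(meta["animal_id"])
    if e != m:
        raise ParseError(
            f"expression/metadata sample mismatch: "
            f"{sorted(e - m)[:5]} only in expression, {sorted(m - e)[:5]} only in metadata"
        )


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> members..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"GMT line {lineno} of {path} has <3 fields")
            name, _desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"GMT set {name!r} (line {lineno}) is empty")
            if name in sets:
                raise ParseError(f"duplicate GMT set name {name!r} (line {lineno})")
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_clinchem(path) -> pd.DataFrame:
    """Read a clinical chemistry CSV: animal_id rows, analyte columns."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate animal id {dup!r} in {path}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ParseError(f"non-numeric analyte column {col!r} in {path}")
    return df


def read_clinchem_summary(path) -> pd.DataFrame:
    """Read a group-summary clinical chemistry table.

    Expected columns: analyte, group, mean, se, n — one row per
    analyte x group.  This is the form in which published studies report
    clinical chemistry, and it is sufficient for ANOVA and Tukey HSD.
    """
    df = pd.read_csv(path, sep="\t")
    need = {"analyte", "group", "mean", "se", "n"}
    missing = need - set(df.columns)
    if missing:
        raise ParseError(f"summary table {path} missing column(s) {sorted(missing)}")
    if (df["n"] < 2).any():
        raise ParseError("summary rows with n < 2: group variance unrecoverable")
    if (df["se"] < 0).any():
        raise ParseError("negative standard error in summary table")
    return df


def load_config(path) -> dict:
    """Load a flat key-value YAML config; returns {} for an empty file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"config {path} is not a flat key-value mapping")
    return cfg


class RunSummary(BaseModel):
    """Schema of the JSON run summary written next to the report tables."""

    config: dict
    seed: int
    n_genes: int
    n_samples: int
    category_counts: dict[str, int]
    primary_counts: dict[str, int]
    ideal_counts: dict[str, int]
    total_markers: int
    total_ideal: int
    concordance_pct: float | None = None
    ideal_concordance_pct: float | None = None


def write_report(results: dict, directory) -> dict[str, Path]:
    """Write the pipeline result tables under *directory*.

    ``results`` may contain any of the keys ``markers``, ``performance``,
    ``pathways``, ``clinchem``, ``susceptible``, ``correlations``
    (DataFrames) and ``summary`` (a :class:`RunSummary` or plain dict).
    Absent sections are written as headers-only files so a partial run
    still produces a complete, explicit report.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tables = {
        "markers": ["gene", "category", "slope_T", "se_T", "slope_E", "se_E",
                    "p_TV", "p_EV", "p_TE", "q_TV", "q_EV", "q_TE",
                    "dir_T", "dir_E"],
        "performance": ["gene", "category", "contrast", "sensitivity", "specificity"],
        "pathways": ["set", "size", "categorized_genes", "p", "tol_specific", "significant"],
        "clinchem": ["analyte", "F", "df_between", "df_within", "p"],
        "susceptible": ["animal_id", "analyte", "direction", "value"],
        "correlations": [],
    }
    for key, header in tables.items():
        path = directory / f"{key}.tsv"
        obj = results.get(key)
        if obj is None:
            pd.DataFrame(columns=header).to_csv(path, sep="\t", index=False)
        elif key == "correlations":
            obj.to_csv(path, sep="\t")
        else:
            obj.to_csv(path, sep="\t", index=False)
        paths[key] = path

    summary = results.get("summary")
    if summary is not None:
        if isinstance(summary, dict):
            summary = RunSummary(**summary)
        path = directory / "summary.json"
        path.write_text(json.dumps(summary.model_dump(), indent=2, sort_keys=True) + "\n")
        paths["summary"] = path
    return paths


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
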