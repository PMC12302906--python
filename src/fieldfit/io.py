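"""Validating readers and writers for the package's table dialects.

TSV with a header for matrices (genes as rows), CSV for time series, JSON
lines for per-gene fits — chosen for diff-ability at desk scale.  Readers
reject malformed files with the offending row/column named.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import EnvSeries, ExpressionStudy
from .fitcore import GeneModelFit
from .synthdata import ConditionSpec


class FormatError(ValueError):
    """A file does not conform to its column contract."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


# -- condition tables -------------------------------------------------------

CONDITION_COLUMNS = ["condition_id", "light_hours", "light_temp", "dark_temp"]


def write_condition_table(conditions, path) -> None:
    rows = [
        {
            "condition_id": c.condition_id,
            "light_hours": c.light_hours,
            "light_temp": "" if c.light_temp is None else c.light_temp,
            "dark_temp": "" if c.dark_temp is None else c.dark_temp,
        }
        for c in conditions
    ]
    pd.DataFrame(rows, columns=CONDITION_COLUMNS).to_csv(path, index=False)


def read_condition_table(path) -> list[ConditionSpec]:
    df = pd.read_csv(path)
    _require_columns(df, CONDITION_COLUMNS, path)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                ConditionSpec(
                    str(row["condition_id"]),
                    int(row["light_hours"]),
                    None if pd.isna(row["light_temp"]) else float(row["light_temp"]),
                    None if pd.isna(row["dark_temp"]) else float(row["dark_temp"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from exc
    ids = [c.condition_id for c in out]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate condition_id")
    return out


# -- environmental series ---------------------------------------------------

ENV_COLUMNS = ["time_h", "clock_time_h", "temperature_C", "irradiance"]


def write_env_series(env: EnvSeries, path) -> None:
    env.to_frame().to_csv(path, index=False)


def read_env_series(path) -> EnvSeries:
    df = pd.read_csv(path)
    _require_columns(df, ENV_COLUMNS, path)
    for col in ENV_COLUMNS:
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"{path}: column {col!r} contains non-numeric cells")
    t = df["time_h"].to_numpy(dtype=float)
    clock0 = float(df["clock_time_h"].iloc[0] - t[0]) % 24.0
    try:
        return EnvSeries(t, df["temperature_C"].to_numpy(dtype=float),
                         df["irradiance"].to_numpy(dtype=float), clock0=clock0)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# -- expression studies -----------------------------------------------------

META_REQUIRED = ["sample_id", "cultivar", "condition_id", "plate_id",
                 "clock_time_h", "age_days"]


def write_study(study: ExpressionStudy, matrix_path, meta_path) -> None:
    study.matrix.to_csv(matrix_path, sep="\t")
    study.meta.reset_index().to_csv(meta_path, sep="\t", index=False)


def read_study(matrix_path, meta_path) -> ExpressionStudy:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if matrix.index.name != "gene_id":
        raise FormatError(f"{matrix_path}: first column must be 'gene_id'")
    bad = matrix.columns[~matrix.apply(
        lambda c: np.issubdtype(c.dtype, np.number))]
    if len(bad):
        raise FormatError(f"{matrix_path}: non-numeric cells in column {bad[0]!r}")
    meta = pd.read_csv(meta_path, sep="\t")
    _require_columns(meta, META_REQUIRED, meta_path)
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{meta_path}: duplicate sample_id {dup!r}")
    missing = [c for c in matrix.columns if c not in set(meta["sample_id"])]
    if missing:
        raise FormatError(f"{meta_path}: no metadata for sample {missing[0]!r}")
    try:
        return ExpressionStudy(matrix, meta.set_index("sample_id"))
    except ValueError as exc:
        raise FormatError(f"{matrix_path}: {exc}") from exc


# -- cluster, genotype, fit and summary tables ------------------------------

def write_cluster_table(table: pd.DataFrame, path) -> None:
    table[["exemplar_gene_id", "member_gene_id"]].to_csv(path, sep="\t", index=False)


def read_cluster_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["exemplar_gene_id", "member_gene_id"], path)
    if df["member_gene_id"].duplicated().any():
        dup = df.loc[df["member_gene_id"].duplicated(), "member_gene_id"].iloc[0]
        raise FormatError(f"{path}: member gene {dup!r} appears in two clusters")
    return df


def write_genotype_calls(calls: pd.DataFrame, path) -> None:
    calls[["sample_id", "locus_id", "call"]].to_csv(path, sep="\t", index=False)


def read_genotype_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample_id", "locus_id", "call"], path)
    bad = set(df["call"]) - {"A", "B", "unknown", "none"}
    if bad:
        raise FormatError(f"{path}: unknown call categories {sorted(bad)}")
    return df


def write_fits_jsonl(fits, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for fit in fits:
            fh.write(json.dumps(fit.to_dict()) + "\n")


def read_fits_jsonl(path) -> list[GeneModelFit]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            try:
                out.append(GeneModelFit.from_dict(json.loads(line)))
            except (KeyError, ValueError, json.JSONDecodeError) as exc:
                raise FormatError(f"{path}: line {i + 1}: {exc}") from exc
    return out


def write_selection_summaries(summaries, path) -> None:
    rows = [
        {
            "gene_id": s.gene_id, "pool": s.pool, "n": s.n, "rep_count": s.reps,
            "n_temperature": s.tally["temperature"],
            "n_radiation": s.tally["radiation"],
            "n_neither": s.tally["neither"],
            "median_mae": float(np.nanmedian(s.mae)) if s.mae.size else np.nan,
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
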