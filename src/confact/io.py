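"""Readers and writers for omics matrices, survival tables and results.

The canonical dialect is TSV (TCGA FireBrowse-style matrices are
tab-delimited): omics files carry patient IDs in the first column and
feature IDs in the header; survival files carry ``patient_id``, ``time``
(days) and ``event`` (0/1) columns. Ingestion policy: rows or columns with
more than ``na_policy`` (default 20%) missing values are dropped, remaining
missing values are imputed by the feature median, and constant features are
dropped — each action is logged. Written files are deterministic given
identical results (stable ordering, 6-significant-digit floats).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import IOConfig
from .datatypes import OmicsMatrix, RiskResult, SubtypeResult, SurvivalTable
from .errors import ValidationError

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"

__all__ = [
    "read_omics_matrix",
    "write_omics_matrix",
    "read_survival",
    "write_survival",
    "write_results",
]


def read_omics_matrix(path, io_options: IOConfig | None = None, data_type: str | None = None) -> OmicsMatrix:
    """Read a patients × features matrix from delimited text."""
    opts = io_options or IOConfig()
    path = Path(path)
    df = pd.read_csv(path, sep=opts.delimiter, index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ValidationError(f"{path.name}: duplicate patient IDs")
    if df.columns.duplicated().any():
        raise ValidationError(f"{path.name}: duplicate feature IDs")

    df = df.apply(pd.to_numeric, errors="coerce")
    bad_rows = df.isna().mean(axis=1) > opts.na_policy
    if bad_rows.any():
        logger.info("%s: dropping %d patients with >%.0f%% missing values",
                    path.name, int(bad_rows.sum()), 100 * opts.na_policy)
        df = df.loc[~bad_rows]
    bad_cols = df.isna().mean(axis=0) > opts.na_policy
    if bad_cols.any():
        logger.info("%s: dropping %d features with >%.0f%% missing values",
                    path.name, int(bad_cols.sum()), 100 * opts.na_policy)
        df = df.loc[:, ~bad_cols]
    if df.isna().any().any():
        logger.info("%s: imputing %d missing values by feature median",
                    path.name, int(df.isna().sum().sum()))
        df = df.fillna(df.median(axis=0))
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise ValidationError(f"{path.name}: non-numeric values remain in column {col!r}")

    const = df.std(axis=0, ddof=0) == 0
    if const.any():
        logger.info("%s: dropping %d constant features", path.name, int(const.sum()))
        df = df.loc[:, ~const]

    return OmicsMatrix(
        df.to_numpy(dtype=float),
        list(df.index),
        [str(c) for c in df.columns],
        data_type or path.stem,
    )


def write_omics_matrix(m: OmicsMatrix, path, io_options: IOConfig | None = None) -> None:
    opts = io_options or IOConfig()
    m.to_frame().to_csv(path, sep=opts.delimiter, float_format=FLOAT_FMT)


def read_survival(path, io_options: IOConfig | None = None) -> SurvivalTable:
    """Read a survival table (patient_id, time, event)."""
    opts = io_options or IOConfig()
    path = Path(path)
    df = pd.read_csv(path, sep=opts.delimiter)
    needed = {"patient_id", "time", "event"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"{path.name}: expected columns {sorted(needed)}")
    incomplete = df["time"].isna() | df["event"].isna()
    if incomplete.any():
        logger.info("%s: dropping %d patients with missing time/event",
                    path.name, int(incomplete.sum()))
        df = df.loc[~incomplete]
    return SurvivalTable(
        [str(p) for p in df["patient_id"]],
        df["time"].to_numpy(dtype=float),
        df["event"].to_numpy(),
    )


def write_survival(surv: SurvivalTable, path, io_options: IOConfig | None = None) -> None:
    opts = io_options or IOConfig()
    df = pd.DataFrame(
        {"patient_id": surv.patient_ids, "time": surv.time, "event": surv.event}
    )
    df.to_csv(path, sep=opts.delimiter, index=False, float_format=FLOAT_FMT)


def write_results(result, out_dir, io_options: IOConfig | None = None) -> list[Path]:
    """Write a SubtypeResult or RiskResult as deterministic text files."""
    opts = io_options or IOConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if isinstance(result, SubtypeResult):
        ids = result.patient_ids or [str(i) for i in range(len(result.labels))]
        sub = out / "subtypes.tsv"
        pd.DataFrame({"patient_id": ids, "subtype": result.labels}).to_csv(
            sub, sep=opts.delimiter, index=False
        )
        written.append(sub)

        cons = out / "consensus.tsv"
        pd.DataFrame(result.consensus, index=ids, columns=ids).to_csv(
            cons, sep=opts.delimiter, float_format=FLOAT_FMT
        )
        written.append(cons)

        prov = out / "partitions.json"
        payload = {
            "k_final": int(result.k_final),
            "partitions": [
                {"source": p.source, "k": int(p.k), "sse": round(float(p.sse), 6),
                 "labels": [int(v) for v in p.labels]}
                for p in result.partitions
            ],
        }
        prov.write_text(json.dumps(payload, indent=1, sort_keys=True))
        written.append(prov)
    elif isinstance(result, RiskResult):
        risk = out / "risk.tsv"
        pd.DataFrame({"patient_id": result.patient_ids, "risk_score": result.risk}).to_csv(
            risk, sep=opts.delimiter, index=False, float_format=FLOAT_FMT
        )
        written.append(risk)
    else:
        raise ValidationError(f"cannot write result of type {type(result).__name__}")
    return written
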