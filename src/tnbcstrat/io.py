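"""Readers and writers for the external formats the pipeline touches.

Expression matrices come in as plain TSV (genes x samples) or in the GEO
series-matrix dialect, where the numeric table sits between
``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers and
all other ``!``-prefixed header lines are metadata. Gene sets use GMT,
clinical annotation a CSV with a declared column mapping, and per-sample
scores / group labels two-column TSV.

Gene identifiers are symbols, not probes; probe-level arrays must either
arrive pre-collapsed or rely on the duplicate-row rule here (keep the row
with the highest mean, the common Affymetrix collapse convention).
Missing expression values are rejected by default — silent imputation
would corrupt the unit-magnitude normalization downstream — with an
explicit opt-in to drop affected genes instead.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    ScoreVector,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "read_score",
    "write_score",
]


def _strip_series_matrix(text: str) -> str:
    """Extract the numeric table from a GEO series-matrix file."""
    lines = text.splitlines()
    begin = [i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin")]
    end = [i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end")]
    if begin and end:
        body = lines[begin[0] + 1 : end[0]]
    else:
        body = [l for l in lines if not l.startswith("!")]
    return "\n".join(body)


def read_expression(
    path: str | Path,
    dialect: str = "tsv",
    collapse: str = "highest_mean",
    on_missing: str = "error",
) -> ExpressionMatrix:
    """Load a genes x samples expression table at stage ``raw``.

    Parameters
    ----------
    path : path to a TSV or GEO series-matrix file.
    dialect : ``tsv`` or ``series_matrix``.
    collapse : rule for duplicate gene rows: ``highest_mean`` (default)
        keeps the row with the largest mean, ``mean`` averages rows.
    on_missing : ``error`` (default) or ``drop_gene``.
    """
    path = Path(path)
    if dialect not in ("tsv", "series_matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    text = path.read_text()
    if dialect == "series_matrix":
        text = _strip_series_matrix(text)
    header = text.splitlines()[0].split("\t")[1:] if text.strip() else []
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate sample ids {dups[:5]}")
    df = pd.read_csv(_io.StringIO(text), sep="\t", index_col=0, dtype=str)
    if df.size == 0:
        raise ValueError(f"{path}: empty expression table")
    # strict numeric conversion with a cell-naming error
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if num.isna().to_numpy().any():
        if on_missing == "drop_gene":
            num = num.dropna(axis=0)
            if num.size == 0:
                raise ValueError(f"{path}: all genes dropped for missing values")
        else:
            r, c = np.argwhere(num.isna().to_numpy())[0]
            raise ValueError(
                f"{path}: missing value at gene {num.index[r]!r}, sample "
                f"{num.columns[c]!r} (use on_missing='drop_gene' to drop)"
            )
    if num.index.has_duplicates:
        num = _collapse_duplicates(num, collapse)
    return ExpressionMatrix(num, stage="raw")


def _collapse_duplicates(df: pd.DataFrame, rule: str) -> pd.DataFrame:
    if rule == "highest_mean":
        means = df.mean(axis=1).to_numpy()
        order = np.arange(len(df))
        # stable pick of the max-mean row per gene, preserving first-seen order
        pick = (
            pd.DataFrame({"gene": df.index, "mean": means, "pos": order})
            .sort_values(["mean", "pos"], ascending=[False, True], kind="stable")
            .drop_duplicates("gene")
            .sort_values("pos")["pos"]
            .to_numpy()
        )
        return df.iloc[pick]
    if rule == "mean":
        first_pos = pd.Series(np.arange(len(df)), index=df.index).groupby(level=0).min()
        out = df.groupby(level=0, sort=False).mean()
        return out.loc[first_pos.sort_values().index]
    raise ValueError(f"unknown collapse rule {rule!r}")


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB gene TAB gene..."""
    sets: list[GeneSet] = []
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >= 3"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            sets.append(GeneSet(name=name, genes=tuple(genes)))
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in coll:
            desc = coll.descriptions.get(gs.name, "")
            fh.write("\t".join([gs.name, desc, *gs.genes]) + "\n")


_DEFAULT_CLINICAL_COLUMNS = {
    "sample_id": "sample_id",
    "age": "age",
    "tumor_size": "tumor_size",
    "followup_time": "followup_time",
    "event": "event",
}

_TRUE = {"1", "true", "True", "TRUE", 1, True}
_FALSE = {"0", "false", "False", "FALSE", 0, False}


def read_clinical(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> ClinicalTable:
    """Read a clinical CSV with a declared column mapping.

    `columns` maps canonical names (sample_id, age, tumor_size,
    followup_time, event) to the file's column names; canonical names are
    used directly when omitted. Missing cells stay missing, never zero.
    """
    colmap = dict(_DEFAULT_CLINICAL_COLUMNS)
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, dtype=str)
    if colmap["sample_id"] not in raw.columns:
        raise ValueError(f"{path}: missing sample id column {colmap['sample_id']!r}")
    out = pd.DataFrame(index=raw[colmap["sample_id"]].astype(str))
    out.index.name = "sample_id"
    for canon in ("age", "tumor_size", "followup_time"):
        col = colmap[canon]
        out[canon] = (
            pd.to_numeric(raw[col], errors="raise").to_numpy()
            if col in raw.columns
            else np.nan
        )
    evcol = colmap["event"]
    if evcol in raw.columns:
        ev = []
        for v in raw[evcol]:
            if pd.isna(v):
                ev.append(np.nan)
            elif v in _TRUE:
                ev.append(1.0)
            elif v in _FALSE:
                ev.append(0.0)
            else:
                raise ValueError(f"{path}: event flag {v!r} not in {{0,1,true,false}}")
        out["event"] = ev
    else:
        out["event"] = np.nan
    return ClinicalTable(out)


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    clin.data.to_csv(path, index_label="sample_id")


def read_score(path: str | Path, name: str | None = None) -> ScoreVector:
    """Read a two-column TSV (sample_id, score); integers preserved exactly."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] != 2:
        # allow a header row of exactly two named columns
        raise ValueError(f"{path}: expected two columns, got {df.shape[1]}")
    if not _is_number(df.iat[0, 1]):  # header row
        df = df.iloc[1:]
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise ValueError(f"{path}: duplicate sample id {ids[ids.duplicated()].iloc[0]!r}")
    try:
        vals = pd.to_numeric(df.iloc[:, 1])
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric score: {exc}") from exc
    series = pd.Series(vals.to_numpy(), index=ids.to_numpy())
    return ScoreVector(
        name=name or Path(path).stem, values=series, provenance={"path": str(path)}
    )


def _is_number(x: object) -> bool:
    try:
        float(x)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False


def write_score(score: ScoreVector, path: str | Path) -> None:
    score.values.to_csv(path, sep="\t", header=False)
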