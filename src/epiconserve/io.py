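"""Readers and writers for all external tables.

Everything is parsed with pandas into plain DataFrames and validated here,
once, so downstream modules can assume well-formed inputs:

* beta matrix       — CpG rows x sample columns, values in [0, 1], NaN allowed
                      (covers GEO series-matrix beta exports after metadata
                      stripping)
* sample sheet      — sample_id, group, tissue, time, time_unit, condition
* CpG annotation    — (cpg_id, gene) multimap, symbols trimmed + upper-cased
* gene-effect table — DepMap-style cell line x gene matrix, "SYMBOL (id)"
                      column labels reduced to SYMBOL
* drug response     — long (cell_line, drug, target, score) records
* gene list         — one symbol per line

Missing-value markers "", "NA", "NaN", "null" (case-insensitive) all map to
missing. Delimiter auto-detection tries tab then comma; an explicit ``sep``
overrides. Readers never silently drop rows: anything skipped is logged.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__

logger = logging.getLogger("epiconserve")

#: markers treated as missing, compared case-insensitively
NA_MARKERS = ("", "na", "nan", "null")

__all__ = [
    "TableFormatError",
    "read_beta_matrix",
    "read_sample_sheet",
    "read_cpg_annotation",
    "annotation_map",
    "read_gene_effect",
    "read_drug_response",
    "read_gene_list",
    "write_table",
    "validate_beta_matrix",
]


class TableFormatError(ValueError):
    """A table failed structural validation; the message names the offending cell."""


def _detect_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if "\t" in line else ","
    raise TableFormatError(f"{path}: file is empty")


def _read_delimited(path, sep=None, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _detect_sep(path, sep)
    return pd.read_csv(
        path,
        sep=sep,
        comment="#",
        keep_default_na=False,
        na_values=[m for m in NA_MARKERS] + [m.upper() for m in NA_MARKERS] + ["NaN", "Na", "Null"],
        **kwargs,
    )


def validate_beta_matrix(beta: pd.DataFrame, source: str = "beta matrix") -> pd.DataFrame:
    """Validate an in-memory beta matrix (CpG index x sample columns)."""
    if beta.index.has_duplicates:
        dup = beta.index[beta.index.duplicated()][0]
        raise TableFormatError(f"{source}: duplicate CpG id {dup!r}")
    if beta.columns.has_duplicates:
        dup = beta.columns[beta.columns.duplicated()][0]
        raise TableFormatError(f"{source}: duplicate sample id {dup!r}")
    values = beta.to_numpy(dtype=float, copy=False)
    bad = (values < 0.0) | (values > 1.0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise TableFormatError(
            f"{source}: value {values[i, j]!r} out of [0, 1] at "
            f"CpG {beta.index[i]!r}, sample {beta.columns[j]!r}"
        )
    return beta.astype(float)


def read_beta_matrix(path, sep: str | None = None) -> pd.DataFrame:
    """Read a beta-value matrix: first column CpG id, header row of sample ids.

    Returns a float DataFrame indexed by CpG id with one column per sample;
    missing markers become NaN; any value outside [0, 1] is rejected with a
    message naming the cell.
    """
    df = _read_delimited(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = "cpg_id"
    try:
        df = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise TableFormatError(f"{path}: non-numeric beta value ({exc})") from exc
    return validate_beta_matrix(df, source=str(path))


_SHEET_OPTIONAL = ("tissue", "time", "time_unit", "condition")


def read_sample_sheet(path, sep: str | None = None) -> pd.DataFrame:
    """Read a sample sheet with required columns sample_id and group.

    tissue/time/time_unit/condition are optional and filled with NaN when
    absent. Groups of a single sample are kept but flagged in the log, since a
    pairwise difference needs at least two measurements.
    """
    df = _read_delimited(path, sep=sep, dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: sample sheet lacks required column {col!r}")
    if df.empty:
        raise TableFormatError(f"{path}: sample sheet has no rows")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise TableFormatError(f"{path}: duplicate sample_id {dup!r}")
    for col in _SHEET_OPTIONAL:
        if col not in df.columns:
            df[col] = np.nan
    df["time"] = pd.to_numeric(df["time"], errors="coerce")
    if (df["time"].dropna() < 0).any():
        bad = df.loc[df["time"] < 0, "sample_id"].iloc[0]
        raise TableFormatError(f"{path}: negative time for sample {bad!r}")
    small = df.groupby("group")["sample_id"].count()
    for group in small.index[small < 2]:
        logger.warning(
            "sample sheet group %r has a single sample; unusable for PWD (k<2)", group
        )
    return df.reset_index(drop=True)


def read_cpg_annotation(path, sep: str | None = None) -> pd.DataFrame:
    """Read a 2-column (cpg_id, gene) annotation into a multimap DataFrame.

    Gene symbols are trimmed and upper-cased; rows with an empty gene field
    are skipped with a warning; duplicate (cpg, gene) rows collapse to one.
    A CpG may legitimately map to several genes.
    """
    df = _read_delimited(path, sep=sep, dtype=str, header=0)
    if df.shape[1] < 2:
        raise TableFormatError(f"{path}: annotation needs two columns (cpg_id, gene)")
    df = df.iloc[:, :2]
    df.columns = ["cpg_id", "gene"]
    n_in = len(df)
    df["gene"] = df["gene"].astype("string").str.strip().str.upper()
    keep = df["gene"].notna() & (df["gene"] != "")
    n_skipped = int(n_in - keep.sum())
    if n_skipped:
        logger.warning("annotation: skipped %d rows with empty gene field", n_skipped)
    df = df[keep].drop_duplicates().reset_index(drop=True)
    df["cpg_id"] = df["cpg_id"].astype(str)
    df["gene"] = df["gene"].astype(str)
    return df


def annotation_map(annotation: pd.DataFrame) -> Mapping[str, set]:
    """cpg_id -> set of gene symbols, from an annotation DataFrame."""
    return annotation.groupby("cpg_id")["gene"].agg(set).to_dict()


def _strip_depmap_label(label: str) -> str:
    """Reduce a 'SYMBOL (numeric id)' column label to SYMBOL."""
    label = label.strip()
    if label.endswith(")"):
        head, _, _tail = label.rpartition(" (")
        if head:
            return head.strip().upper()
    return label.upper()


def read_gene_effect(
    path,
    sep: str | None = None,
    cell_lines: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read a DepMap-style gene-effect matrix (cell line rows x gene columns).

    Column labels like "SOX10 (6663)" are reduced to the bare symbol. When
    ``cell_lines`` is given the table is restricted to those rows; absent
    lines are warned about, and no overlap at all is an error.
    """
    df = _read_delimited(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "cell_line"
    df.columns = [_strip_depmap_label(str(c)) for c in df.columns]
    dupes = pd.Index(df.columns)[pd.Index(df.columns).duplicated()]
    if len(dupes):
        raise TableFormatError(f"{path}: duplicated gene column {dupes[0]!r}")
    df = df.apply(pd.to_numeric, errors="coerce")
    if cell_lines is not None:
        wanted = [str(c) for c in cell_lines]
        present = [c for c in wanted if c in df.index]
        missing = sorted(set(wanted) - set(present))
        if not present:
            raise TableFormatError(
                f"{path}: none of the {len(wanted)} requested cell lines are present"
            )
        if missing:
            logger.warning(
                "gene effect: %d requested cell lines absent (%s); %d retained",
                len(missing), ", ".join(missing), len(present),
            )
        df = df.loc[present]
    return df


_DRUG_COLUMNS = ("cell_line", "drug", "target", "score")


def read_drug_response(path, sep: str | None = None) -> pd.DataFrame:
    """Read a long-format drug-response table (cell_line, drug, target, score).

    Scores are sensitivity z-scores with negative = more sensitive. Duplicate
    (cell_line, drug, target) rows are collapsed by their mean with a warning.
    """
    df = _read_delimited(path, sep=sep, dtype=str)
    missing = [c for c in _DRUG_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: drug table lacks required columns {missing}")
    df = df.loc[:, list(_DRUG_COLUMNS)].copy()
    df["target"] = df["target"].astype("string").str.strip().str.upper().astype(str)
    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    key = ["cell_line", "drug", "target"]
    if df.duplicated(key).any():
        n_dup = int(df.duplicated(key).sum())
        logger.warning("drug response: %d duplicate (cell_line, drug) rows collapsed by mean", n_dup)
        df = df.groupby(key, as_index=False, sort=False)["score"].mean()
    return df.reset_index(drop=True)


def read_gene_list(path) -> list[str]:
    """Read a plain gene list (one symbol per line), normalized like the annotation."""
    path = Path(path)
    genes: list[str] = []
    seen = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        g = line.strip().upper()
        if not g or g.startswith("#"):
            continue
        if g not in seen:
            seen.add(g)
            genes.append(g)
    return genes


def write_table(df: pd.DataFrame, path, params: Mapping | None = None, index: bool = True) -> None:
    """Write a result table as TSV with a leading comment line.

    The comment records the tool version and the parameters of the run so any
    output file is self-describing. Floats are written with repr precision so
    a write/read round trip is bit-identical.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = " ".join(f"{k}={v}" for k, v in (params or {}).items())
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=index, na_rep="NA")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# epiconserve {__version__}" + (f" {meta}" if meta else "") + "\n")
        fh.write(buf.getvalue())
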