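"""Conservation of a drug's target gene versus that drug's sensitivity.

Per cell line, conservation of a gene is the PWD between the line's replicate
methylation samples (k = number of replicates, usually 2). Across a panel of
lines, the Pearson correlation between target-gene PWD and drug sensitivity
score is computed per (drug, target) pair. Both axes are oriented
negative-is-more: more negative PWD z-score = more conserved, more negative
sensitivity score = more sensitive — so a *positive* r means conservation
tracks sensitivity. z-scoring leaves Pearson r unchanged; it is kept because
plots and reports use the z scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pwd import grouped_gene_pwd
from .stats import pearson

logger = logging.getLogger("epiconserve")

__all__ = ["zscore", "per_cellline_gene_pwd", "conservation_drug_correlation"]


def zscore(values) -> np.ndarray:
    """(x - mean) / sd with the sample (n-1) standard deviation.

    A constant vector (or n < 2) has no z-score: all-NaN is returned rather
    than zeros, so downstream code cannot mistake "undefined" for "average".
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("zscore expects a 1-d vector")
    if x.size < 2:
        return np.full(x.shape, np.nan)
    sd = np.nanstd(x, ddof=1)
    if sd == 0 or np.isnan(sd):
        return np.full(x.shape, np.nan)
    return (x - np.nanmean(x)) / sd


def per_cellline_gene_pwd(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    annotation: pd.DataFrame,
    genes=None,
) -> pd.DataFrame:
    """Gene PWD per cell line from replicate samples.

    ``sheet.group`` names the cell line; every line needs >=2 replicate
    samples in the beta matrix (lines with fewer are dropped with a warning).
    Returns a cell line x gene DataFrame of PWDs; a line lacking computable
    CpGs for a gene gets NaN there.
    """
    rows = {}
    for line, sub in sheet.groupby("group"):
        cols = [s for s in sub["sample_id"] if s in beta.columns]
        if len(cols) < 2:
            logger.warning("cell line %r has <2 replicate samples; skipped", line)
            continue
        single = sheet[sheet["group"] == line]
        tbl = grouped_gene_pwd(beta, annotation, single)
        rows[str(line)] = tbl["gene_pwd"]
    if not rows:
        raise ValueError("no cell line with at least two replicate samples")
    out = pd.DataFrame(rows).T.rename_axis("cell_line")
    if genes is not None:
        keep = [g for g in genes if g in out.columns]
        out = out[keep]
    return out


@dataclass(frozen=True)
class DrugGeneCorrelation:
    drug: str
    target: str
    pearson_r: float
    p: float
    n: int


def conservation_drug_correlation(
    pwd_by_line: pd.DataFrame,
    drugs: pd.DataFrame,
    min_lines: int = 3,
) -> pd.DataFrame:
    """Pearson r between target-gene PWD and sensitivity, per (drug, target).

    ``pwd_by_line`` is the cell line x gene PWD matrix; ``drugs`` the long
    (cell_line, drug, target, score) table. Each (drug, target) pair gives
    one row — a drug with two annotated targets contributes two rows. Pairs
    with fewer than ``min_lines`` cell lines carrying both values are skipped
    with a warning. p-values are two-sided and uncorrected. Output columns:
    drug, target, pearson_r, p, n (sorted by drug then target).
    """
    records = []
    for (drug, target), sub in drugs.groupby(["drug", "target"], sort=True):
        if target not in pwd_by_line.columns:
            logger.warning("target gene %r has no conservation data; (%s, %s) skipped", target, drug, target)
            continue
        merged = sub.set_index("cell_line")["score"].to_frame().join(
            pwd_by_line[target].rename("pwd"), how="inner"
        ).dropna()
        if len(merged) < min_lines:
            logger.warning(
                "(%s, %s): only %d cell lines with both values (<%d); skipped",
                drug, target, len(merged), min_lines,
            )
            continue
        res = pearson(merged["pwd"].to_numpy(), merged["score"].to_numpy())
        records.append(
            {"drug": drug, "target": target, "pearson_r": res.r, "p": res.p, "n": res.n}
        )
    return pd.DataFrame.from_records(
        records, columns=["drug", "target", "pearson_r", "p", "n"]
    )
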