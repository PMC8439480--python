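"""Essentiality calls and conservation-as-classifier diagnostics.

A gene is called essential when its mean gene-effect score (log-fold
proliferation change after single-gene disruption, averaged over the selected
cell lines) is strictly below a cutoff, −0.4 by default. Conservation is then
evaluated as a classifier of essentiality: a gene is predicted essential when
its PWD is strictly below a threshold, and the 2x2 confusion table yields
sensitivity, specificity, PPV and NPV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import WelchResult, round_percent, welch_t_test

DEFAULT_EFFECT_THRESHOLD = -0.4
DEFAULT_PWD_THRESHOLDS = (0.05, 0.10, 0.15)

__all__ = [
    "ConfusionTable",
    "DiagnosticsRow",
    "call_essential",
    "classification_metrics",
    "confusion_at_threshold",
    "threshold_diagnostics",
    "diagnostics_frame",
    "compare_classes",
    "DEFAULT_EFFECT_THRESHOLD",
    "DEFAULT_PWD_THRESHOLDS",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 gene counts for predicted-essential (PWD < threshold) vs essential."""

    tp: int
    fp: int
    fn: int
    tn: int
    pwd_threshold: float

    @property
    def n_essential(self) -> int:
        return self.tp + self.fn

    @property
    def n_non_essential(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class DiagnosticsRow:
    """Sensitivity/specificity/PPV/NPV with their defining fractions.

    Each metric is a proportion in [0, 1], or NaN when its denominator is
    zero (undefined, never coerced to 0). ``*_percent`` round half-up to one
    decimal for table output.
    """

    pwd_threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    fractions: dict

    def percent(self, metric: str) -> float:
        return round_percent(getattr(self, metric))


def call_essential(
    effects: pd.DataFrame,
    cell_lines: Sequence[str] | None = None,
    threshold: float = DEFAULT_EFFECT_THRESHOLD,
) -> pd.DataFrame:
    """Call essential genes from a cell line x gene effect matrix.

    Per gene, the mean over non-missing scores of the selected lines;
    essential = (mean_effect < threshold), strict, so a gene at exactly the
    cutoff is not essential. Genes with no score in any selected line are
    omitted. Returns a DataFrame indexed by gene with columns mean_effect,
    essential.
    """
    if cell_lines is not None:
        lines = [str(c) for c in cell_lines if str(c) in effects.index]
        if not lines:
            raise ValueError("no selected cell line present in the gene-effect table")
        effects = effects.loc[lines]
    if effects.shape[0] == 0:
        raise ValueError("empty cell-line selection")
    mean_effect = effects.mean(axis=0, skipna=True).dropna()
    out = pd.DataFrame(
        {"mean_effect": mean_effect, "essential": mean_effect < threshold}
    )
    out.attrs["threshold"] = threshold
    return out.rename_axis("gene")


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(ct: ConfusionTable) -> DiagnosticsRow:
    """Derive the four diagnostic proportions from a confusion table.

    sensitivity = tp/(tp+fn), specificity = tn/(fp+tn), ppv = tp/(tp+fp),
    npv = tn/(tn+fn). A zero PPV/NPV denominator yields NaN (undefined).
    """
    if ct.n_essential <= 0 or ct.n_non_essential <= 0:
        raise ValueError("confusion table needs at least one gene in each class")
    fractions = {
        "sensitivity": (ct.tp, ct.tp + ct.fn),
        "specificity": (ct.tn, ct.fp + ct.tn),
        "ppv": (ct.tp, ct.tp + ct.fp),
        "npv": (ct.tn, ct.tn + ct.fn),
    }
    return DiagnosticsRow(
        pwd_threshold=ct.pwd_threshold,
        sensitivity=_ratio(*fractions["sensitivity"]),
        specificity=_ratio(*fractions["specificity"]),
        ppv=_ratio(*fractions["ppv"]),
        npv=_ratio(*fractions["npv"]),
        fractions=fractions,
    )


def _aligned(pwd_table: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    joined = pwd_table[["gene_pwd"]].join(calls[["essential"]], how="inner")
    if joined.empty:
        raise ValueError("no gene has both a PWD and an essentiality call")
    return joined


def confusion_at_threshold(
    pwd_table: pd.DataFrame, calls: pd.DataFrame, threshold: float
) -> ConfusionTable:
    """Confusion table for predicted-essential = (gene_pwd < threshold), strict.

    Evaluation is restricted to genes present in both tables.
    """
    joined = _aligned(pwd_table, calls)
    predicted = joined["gene_pwd"] < threshold
    truth = joined["essential"].astype(bool)
    return ConfusionTable(
        tp=int((predicted & truth).sum()),
        fp=int((predicted & ~truth).sum()),
        fn=int((~predicted & truth).sum()),
        tn=int((~predicted & ~truth).sum()),
        pwd_threshold=float(threshold),
    )


def threshold_diagnostics(
    pwd_table: pd.DataFrame,
    calls: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_PWD_THRESHOLDS,
) -> list[DiagnosticsRow]:
    """DiagnosticsRow per PWD threshold over the gene intersection."""
    return [
        classification_metrics(confusion_at_threshold(pwd_table, calls, t))
        for t in thresholds
    ]


def diagnostics_frame(rows: Sequence[DiagnosticsRow]) -> pd.DataFrame:
    """Tabulate diagnostics rows: one row per threshold, fractions + percents."""
    records = []
    for row in rows:
        rec: dict = {"pwd_threshold": row.pwd_threshold}
        for metric in ("sensitivity", "specificity", "ppv", "npv"):
            num, den = row.fractions[metric]
            rec[f"{metric}_fraction"] = f"{num}/{den}"
            rec[f"{metric}_percent"] = row.percent(metric)
        records.append(rec)
    return pd.DataFrame.from_records(records)


def compare_classes(pwd_table: pd.DataFrame, calls: pd.DataFrame) -> WelchResult:
    """Welch's t-test of gene PWD: essential vs non-essential genes.

    Two-sided; both classes need at least two genes. Under purifying
    selection the essential class is expected to have the smaller mean PWD
    (negative t with essential as the first group).
    """
    joined = _aligned(pwd_table, calls)
    ess = joined.loc[joined["essential"].astype(bool), "gene_pwd"].to_numpy()
    non = joined.loc[~joined["essential"].astype(bool), "gene_pwd"].to_numpy()
    if ess.size < 2 or non.size < 2:
        raise ValueError(
            f"need >=2 genes per class, got {ess.size} essential / {non.size} non-essential"
        )
    return welch_t_test(ess, non)
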