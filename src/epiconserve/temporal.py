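"""Conservation over time: drift accumulation, post-demethylation recovery, aging.

Three designs share one machinery:

* clonal drift — replicate cultures split from one founder, measured at
  successive passages; mean gene PWD across replicates rises with time.
* demethylation recovery — after a demethylating shock (e.g. 5-azacitidine)
  the PWD between mock-treated and treated cultures first jumps, then falls
  back as purifying selection removes cells with disrupted epigenomes; a
  negative Pearson trend of mean PWD against time is the recovery signal.
* aging — the same trend machinery with time = donor age.

Series are built per gene class (essential / non-essential / all) over the
gene intersection common to all time points, so composition changes cannot
masquerade as trends.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pwd import gene_pwd
from .stats import TrendResult, pearson

CLASS_LABELS = ("essential", "non_essential", "all")

__all__ = ["build_time_series", "trend_test", "recovery_analysis", "CLASS_LABELS"]


def _class_masks(genes: pd.Index, calls: pd.DataFrame | None) -> dict[str, pd.Index]:
    masks = {"all": genes}
    if calls is not None:
        flagged = calls.reindex(genes)["essential"].astype("boolean")
        masks["essential"] = genes[flagged.fillna(False).to_numpy(dtype=bool)]
        masks["non_essential"] = genes[(~flagged.fillna(True)).to_numpy(dtype=bool)]
    return masks


def build_time_series(
    tables: Sequence[tuple[float, pd.DataFrame]],
    calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean gene PWD per time point and gene class.

    ``tables`` is a list of (time, GenePWDTable); the mean at each time point
    is taken over the genes shared by *all* time points. Returns a tidy frame
    (time, class_label, mean_gene_pwd, n_genes) sorted by class then time.
    """
    if len(tables) < 2:
        raise ValueError("need at least two time points")
    times = [t for t, _ in tables]
    if len(set(times)) != len(times):
        raise ValueError("duplicate time points")
    common = tables[0][1].index
    for _, tbl in tables[1:]:
        common = common.intersection(tbl.index)
    if len(common) == 0:
        raise ValueError("no gene is shared by all time points")
    masks = _class_masks(common, calls)
    records = []
    for label, genes in masks.items():
        for t, tbl in sorted(tables, key=lambda pair: pair[0]):
            if len(genes) == 0:
                continue
            values = tbl.loc[genes, "gene_pwd"].to_numpy(dtype=float)
            records.append(
                {
                    "time": float(t),
                    "class_label": label,
                    "mean_gene_pwd": float(np.mean(values)),
                    "n_genes": int(len(genes)),
                }
            )
    return pd.DataFrame.from_records(records)


def trend_test(series: pd.DataFrame, class_label: str = "all") -> TrendResult:
    """Pearson correlation of mean gene PWD against time for one class.

    Positive r indicates accumulating drift, negative r indicates recovery
    toward the reference configuration. A constant series has undefined r
    (NaN); fewer than three points yields an r without a p-value.
    """
    sub = series[series["class_label"] == class_label].sort_values("time")
    if sub.empty:
        raise ValueError(f"no rows for class {class_label!r}")
    return pearson(sub["time"].to_numpy(), sub["mean_gene_pwd"].to_numpy())


def recovery_analysis(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    annotation: pd.DataFrame,
    calls: pd.DataFrame | None = None,
    control_label: str = "control",
) -> tuple[pd.DataFrame, dict[str, TrendResult]]:
    """Control-vs-treated PWD over post-shock time, per gene class.

    The sample sheet must pair, per group (cell line) and time point, one
    control sample (condition == ``control_label``) with one treated sample.
    For each such pair the gene PWD is the k=2 statistic |beta_ctrl −
    beta_treated| averaged over a gene's CpGs; several cell lines at a time
    point are averaged with equal weight. Returns the tidy time series and a
    per-class trend test; recovery shows as a significantly negative trend.
    """
    sheet = sheet.dropna(subset=["time"])
    tables: list[tuple[float, pd.DataFrame]] = []
    for time, at_time in sheet.groupby("time"):
        per_line = []
        for group, pair in at_time.groupby("group"):
            is_ctrl = pair["condition"].astype(str) == control_label
            ctrl = pair.loc[is_ctrl, "sample_id"].tolist()
            trt = pair.loc[~is_ctrl, "sample_id"].tolist()
            if len(ctrl) != 1 or len(trt) != 1:
                raise ValueError(
                    f"group {group!r} at time {time} needs exactly one control and "
                    f"one treated sample, got {len(ctrl)}/{len(trt)}"
                )
            if ctrl[0] not in beta.columns or trt[0] not in beta.columns:
                raise ValueError(f"samples for group {group!r} at time {time} missing from beta matrix")
            per_line.append(gene_pwd(beta, annotation, samples=[ctrl[0], trt[0]]))
        stacked = pd.concat(per_line)
        avg = stacked.groupby(level=0).agg(
            gene_pwd=("gene_pwd", "mean"), n_cpgs=("n_cpgs", "max"),
            n_groups=("gene_pwd", "size"),
        )
        tables.append((float(time), avg))
    if len(tables) == 0:
        raise ValueError("no usable time point")
    if len(tables) == 1:
        series = build_single_point_series(tables[0], calls)
        return series, {label: TrendResult(float("nan"), float("nan"), 1) for label in series["class_label"].unique()}
    series = build_time_series(tables, calls)
    trends = {
        label: trend_test(series, label)
        for label in series["class_label"].unique()
    }
    return series, trends


def build_single_point_series(table: tuple[float, pd.DataFrame], calls) -> pd.DataFrame:
    """Degenerate one-time-point series (trend not assessable)."""
    t, tbl = table
    masks = _class_masks(tbl.index, calls)
    records = [
        {
            "time": float(t),
            "class_label": label,
            "mean_gene_pwd": float(tbl.loc[genes, "gene_pwd"].mean()),
            "n_genes": int(len(genes)),
        }
        for label, genes in masks.items()
        if len(genes)
    ]
    return pd.DataFrame.from_records(records)
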