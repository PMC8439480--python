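"""The pairwise-difference (PWD) conservation statistic.

For a CpG with k methylation proportions A_1..A_k the PWD is

    PWD = (1 / C(k, 2)) * sum_{i<j} |A_i - A_j|,        C(k, 2) = k(k-1)/2,

a number in [0, 1]; low PWD between measurements separated in time means the
site's methylation has been conserved. A gene's conservation is the unweighted
mean of the PWDs of all CpG sites annotated to it. With a grouped design
(e.g. several crypts per individual) the gene PWD is computed within each
group and then averaged across groups with equal weights, so that
between-group (e.g. inter-individual) differences never enter the statistic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PWDValue",
    "cpg_pwd",
    "pwd_per_cpg",
    "gene_pwd",
    "grouped_gene_pwd",
    "pwd_histogram",
]


@dataclass(frozen=True)
class PWDValue:
    value: float
    n_pairs: int
    n_samples: int


def cpg_pwd(values, allow_missing: bool = True) -> PWDValue:
    """Mean absolute difference over all unique pairs of measurements.

    Missing entries are removed first when ``allow_missing`` (the default);
    fewer than two usable measurements is an error, since at least one pair
    is needed.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("cpg_pwd expects a 1-d vector of proportions")
    missing = np.isnan(x)
    if missing.any():
        if not allow_missing:
            raise ValueError("missing measurement with allow_missing=False")
        x = x[~missing]
    k = x.size
    if k < 2:
        raise ValueError(f"insufficient measurements: need k>=2 non-missing, got {k}")
    # sum_{i<j} |x_i - x_j| via the sorted-values identity, O(k log k)
    xs = np.sort(x)
    ranks = np.arange(1, k + 1)
    total = float(np.sum((2 * ranks - k - 1) * xs))
    n_pairs = k * (k - 1) // 2
    return PWDValue(total / n_pairs, n_pairs, k)


def pwd_per_cpg(beta: pd.DataFrame, samples=None, min_k: int = 2) -> pd.Series:
    """Per-CpG PWD over a sample subset, vectorized over CpGs.

    NaNs are dropped per CpG (a pair is only counted when both measurements
    are present); CpGs with fewer than ``min_k`` usable values get NaN.
    """
    if samples is not None:
        samples = list(samples)
        if len(samples) == 0:
            raise ValueError("empty sample subset")
        missing = [s for s in samples if s not in beta.columns]
        if missing:
            raise KeyError(f"samples not in beta matrix: {missing}")
        beta = beta[samples]
    if beta.shape[1] < 2:
        raise ValueError("need at least two samples to compute a PWD")
    values = beta.to_numpy(dtype=float)
    n_cpgs, k = values.shape
    total = np.zeros(n_cpgs)
    pairs = np.zeros(n_cpgs, dtype=np.int64)
    for i, j in itertools.combinations(range(k), 2):
        diff = np.abs(values[:, i] - values[:, j])
        ok = ~np.isnan(diff)
        total[ok] += diff[ok]
        pairs += ok
    n_valid = np.sum(~np.isnan(values), axis=1)
    out = np.full(n_cpgs, np.nan)
    usable = (n_valid >= max(min_k, 2)) & (pairs > 0)
    out[usable] = total[usable] / pairs[usable]
    return pd.Series(out, index=beta.index, name="pwd")


def gene_pwd(beta: pd.DataFrame, annotation: pd.DataFrame, samples=None) -> pd.DataFrame:
    """Per-gene conservation: unweighted mean CpG PWD over annotated CpGs.

    ``annotation`` is the (cpg_id, gene) multimap; a CpG annotated to several
    genes contributes to each of them. Genes with no CpG that yields a
    computable PWD are omitted. Returns a DataFrame indexed by gene with
    columns gene_pwd, n_cpgs, n_groups (1 here; see grouped_gene_pwd).
    """
    site = pwd_per_cpg(beta, samples=samples)
    merged = annotation.merge(
        site.rename("pwd"), left_on="cpg_id", right_index=True, how="inner"
    ).dropna(subset=["pwd"])
    if merged.empty:
        return pd.DataFrame(columns=["gene_pwd", "n_cpgs", "n_groups"]).rename_axis("gene")
    out = merged.groupby("gene")["pwd"].agg(gene_pwd="mean", n_cpgs="size")
    out["n_cpgs"] = out["n_cpgs"].astype(int)
    out["n_groups"] = 1
    return out.rename_axis("gene")


def grouped_gene_pwd(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    sheet: pd.DataFrame,
    strategy: str = "within_group_mean",
) -> pd.DataFrame:
    """Gene PWD under a grouped design (replicates within individuals/lines).

    strategy "within_group_mean" (default): gene PWD within each group with
    >=2 samples present in the matrix, then an equal-weight mean across
    groups, so a group of 4 crypts counts the same as a group of 2. A group
    where a gene has no computable CpG simply does not contribute to that
    gene's average (n_groups records how many did). strategy "pooled" treats
    every listed sample as one big group, for sensitivity analysis.
    """
    usable: list[tuple[str, list[str]]] = []
    for group, sub in sheet.groupby("group"):
        cols = [s for s in sub["sample_id"] if s in beta.columns]
        if len(cols) >= 2:
            usable.append((str(group), cols))
    if not usable:
        raise ValueError("no group with at least two samples present in the beta matrix")

    if strategy == "pooled":
        cols = sorted({s for _, group_cols in usable for s in group_cols})
        return gene_pwd(beta, annotation, samples=cols)
    if strategy != "within_group_mean":
        raise ValueError(f"unknown strategy {strategy!r}")

    per_group = []
    for group, cols in usable:
        tbl = gene_pwd(beta, annotation, samples=cols)
        if not tbl.empty:
            per_group.append(tbl[["gene_pwd", "n_cpgs"]])
    if not per_group:
        raise ValueError("no gene had a computable PWD in any group")
    stacked = pd.concat(per_group)
    out = stacked.groupby(level=0).agg(
        gene_pwd=("gene_pwd", "mean"),
        n_cpgs=("n_cpgs", "max"),
        n_groups=("gene_pwd", "size"),
    )
    out["n_cpgs"] = out["n_cpgs"].astype(int)
    out["n_groups"] = out["n_groups"].astype(int)
    return out.rename_axis("gene")


def pwd_histogram(table: pd.DataFrame, bin_width: float = 0.01):
    """Bin gene PWDs over [0, 1] with right-open bins (last bin closed at 1).

    Returns (edges, counts, modal_bin_index). The gene-PWD distribution is
    typically "r-shaped": a mode at or near zero with a long right tail.
    """
    if not (0.0 < bin_width <= 1.0):
        raise ValueError(f"bin_width must be in (0, 1], got {bin_width}")
    if table.empty:
        raise ValueError("empty gene PWD table")
    values = table["gene_pwd"].to_numpy(dtype=float)
    n_bins = int(np.ceil(round(1.0 / bin_width, 9)))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    edges[-1] = 1.0
    counts, _ = np.histogram(values, bins=edges)  # numpy closes the final bin
    return edges, counts, int(np.argmax(counts))
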