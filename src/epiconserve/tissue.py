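"""Differential conservation between two tissues.

A gene is called preferentially conserved in tissue A when its gene PWD is
below the conservation cutoff in A *and* above the drift cutoff in B (and
symmetrically for B). Defaults are conserved_below = 0.05 and
drifted_above = 0.1, the same cutoffs used for the essentiality diagnostics.
Gene-family tagging by symbol prefix (e.g. HOXA/HOXB for the homeobox
clusters) supports inspection of family-level patterns without any external
pathway database.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

DEFAULT_CONSERVED_BELOW = 0.05
DEFAULT_DRIFTED_ABOVE = 0.1

__all__ = [
    "differential_conservation",
    "annotate_gene_family",
    "DEFAULT_CONSERVED_BELOW",
    "DEFAULT_DRIFTED_ABOVE",
]


def differential_conservation(
    pwd_a: pd.DataFrame,
    pwd_b: pd.DataFrame,
    conserved_below: float = DEFAULT_CONSERVED_BELOW,
    drifted_above: float = DEFAULT_DRIFTED_ABOVE,
    labels: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Call tissue-specific conservation over the gene intersection.

    Returns one row per shared gene: pwd_a, pwd_b and call in
    {conserved_in_a, conserved_in_b, none}. The rule is antisymmetric:
    swapping the inputs swaps the directional calls exactly.
    """
    if not conserved_below < drifted_above:
        raise ValueError(
            f"conserved_below ({conserved_below}) must be < drifted_above ({drifted_above})"
        )
    la, lb = labels
    joined = pwd_a[["gene_pwd"]].join(
        pwd_b[["gene_pwd"]], how="inner", lsuffix="_x", rsuffix="_y"
    )
    if joined.empty:
        raise ValueError("the two tables share no gene")
    a = joined["gene_pwd_x"]
    b = joined["gene_pwd_y"]
    in_a = (a < conserved_below) & (b > drifted_above)
    in_b = (b < conserved_below) & (a > drifted_above)
    call = pd.Series("none", index=joined.index, dtype=object)
    call[in_a] = f"conserved_in_{la}"
    call[in_b] = f"conserved_in_{lb}"
    out = pd.DataFrame(
        {f"pwd_{la}": a, f"pwd_{lb}": b, "call": call}
    ).rename_axis("gene")
    out.attrs["thresholds"] = {
        "conserved_below": conserved_below,
        "drifted_above": drifted_above,
    }
    return out


def annotate_gene_family(
    calls: pd.DataFrame, family_patterns: Sequence[str]
) -> pd.DataFrame:
    """Flag calls whose gene symbol starts with any of the given prefixes.

    Adds a ``family`` column holding the first matching prefix (empty string
    when none matches). Matching is case-insensitive on the upper-cased
    symbol.
    """
    out = calls.copy()
    prefixes = [p.strip().upper() for p in family_patterns if p.strip()]

    def tag(gene: str) -> str:
        g = str(gene).upper()
        for p in prefixes:
            if g.startswith(p):
                return p
        return ""

    out["family"] = [tag(g) for g in out.index]
    return out
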