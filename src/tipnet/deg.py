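"""Pairwise differential expression between disease stages.

A gene is called differentially expressed when its FPKM fold change (later
stage over earlier stage) is >= 1.5 or <= 0.67 AND its Benjamini-Hochberg
adjusted p-value is < 0.05; both boundaries are inclusive on the fold change
and strict on the adjusted p. The location test is Welch's t on
log2(FPKM + 1) — a deliberately simple, self-contained stand-in for a
count-model likelihood, which is out of scope here; fold changes are plain
FPKM mean ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, log_transform

__all__ = ["differential_expression", "bh_adjust"]

FC_EPS = 1e-9  # denominator guard for fold changes


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    fc_up: float = 1.5,
    fc_down: float = 0.67,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """DEG table for the contrast ``group_b`` vs ``group_a`` (b over a).

    Returns one row per gene: means, fold change (with a tiny epsilon guard
    in the denominator), log2 fold change, Welch-t p-value on
    log2(FPKM + pseudocount), BH-adjusted p, the DEG call and its direction.
    Genes constant in both groups are flagged (``degenerate``) with p = 1.
    """
    for g in (group_a, group_b):
        if expr.stages is None or g not in set(expr.stage_order):
            raise ValueError(f"unknown stage label: {g!r}")
    a = expr.subset_stage(group_a)
    b = expr.subset_stage(group_b)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    fold_change = (mean_b + FC_EPS) / (mean_a + FC_EPS)

    logx = log_transform(expr, pseudocount)
    la, lb = logx[a.columns].to_numpy(), logx[b.columns].to_numpy()
    degenerate = (np.ptp(la, axis=1) == 0) & (np.ptp(lb, axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(lb, la, axis=1, equal_var=False).pvalue
    p = np.where(degenerate | ~np.isfinite(p), 1.0, p)

    adj_p = bh_adjust(p)
    # inclusive boundaries, with a relative tolerance absorbing both float
    # representation (6.7/10 != 0.67 in binary) and the epsilon guard
    rtol = 1e-9
    up = fold_change >= fc_up * (1 - rtol)
    down = fold_change <= fc_down * (1 + rtol)
    is_deg = (up | down) & (adj_p < alpha)
    direction = np.select(
        [is_deg & up, is_deg & down],
        ["up", "down"],
        default="none",
    )
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fold_change,
            "log2_fc": np.log2(fold_change),
            "p_value": p,
            "adj_p": adj_p,
            "is_deg": is_deg,
            "direction": direction,
            "degenerate": degenerate,
        },
        index=expr.gene_ids,
    )
    out.attrs["contrast"] = f"{group_b}/{group_a}"
    return out
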