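"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (explicit loops, exact rational
arithmetic) and never share code with the implementations they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from tipnet.expression import ExpressionMatrix


# ---------------------------------------------------------------- oracles


def oracle_bh(p: list[float]) -> list[float]:
    """Step-up Benjamini-Hochberg, written as the textbook procedure."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def oracle_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap."""
    n = a.shape[0]
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            t[i, j] = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
    return t


def oracle_composite_index(x: np.ndarray, group_mask: np.ndarray):
    """Pairwise-loop CI for one stage block (genes x samples)."""
    g = np.flatnonzero(group_mask)
    o = np.flatnonzero(~group_mask)
    sd_d = float(np.mean([x[i].std(ddof=1) for i in g]))

    def absr(i, j):
        xi, xj = x[i], x[j]
        if xi.std() == 0 or xj.std() == 0:
            return 0.0
        return abs(float(np.corrcoef(xi, xj)[0, 1]))

    pcc_d = float(np.mean([absr(g[i], g[j]) for i in range(len(g))
                           for j in range(i + 1, len(g))]))
    pcc_o = float(np.mean([absr(i, j) for i in g for j in o]))
    ci = sd_d * pcc_d / pcc_o if pcc_o > 0 else float("inf")
    return sd_d, pcc_d, pcc_o, ci


def oracle_hypergeom_tail(k: int, U: int, s: int, q: int) -> Fraction:
    """Exact rational upper-tail P[X >= k]."""
    total = Fraction(0)
    for i in range(k, min(s, q) + 1):
        total += Fraction(comb(s, i) * comb(U - s, q - i), comb(U, q))
    return total


# ---------------------------------------------------------------- fixtures


def make_expression(values: np.ndarray, stages: list[str],
                    stage_order: list[str]) -> ExpressionMatrix:
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        stages=pd.Series(stages, index=samples),
        stage_order=stage_order,
    )


@pytest.fixture(scope="session")
def small_study():
    """One small planted study reused by read-only tests."""
    from tipnet.simulate import SimulationConfig, simulate_study

    cfg = SimulationConfig(
        n_genes=150,
        module_sizes=[40, 30],
        module_trait_loadings=[0.7, -0.6],
        dnb_size=20,
        seed=7,
    )
    return simulate_study(cfg)
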