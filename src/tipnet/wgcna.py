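"""Weighted gene coexpression network analysis, single-block.

Implements the standard unsigned pipeline: soft-threshold selection by
scale-free topology fit, adjacency ``a_ij = |cor(x_i, x_j)|^beta``,
topological overlap smoothing (TOM), average-linkage clustering of the TOM
dissimilarity with a simplified tree-style dynamic cut, module eigengenes
(first principal component per module), eigengene-similarity module merging,
size-ordered colour naming, module membership (MM), gene significance (GS)
against a clinical trait, module-trait correlation, and hub-gene selection
(|MM| > 0.8 and GS > 0.2 by default).

Expression matrices are genes x samples; correlations are computed across
samples on the values as given (the caller decides raw FPKM vs log).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "SoftThresholdScan",
    "ModulePartition",
    "correlation_matrix",
    "adjacency",
    "soft_threshold_scan",
    "tom_similarity",
    "cluster_modules",
    "module_eigengenes",
    "merge_close_modules",
    "assign_colors",
    "module_membership",
    "gene_significance",
    "module_trait_correlation",
    "select_hub_genes",
]

# conventional module palette, largest module first; grey is reserved for
# unassigned genes
COLOR_PALETTE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]


def correlation_matrix(values: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows; rows with zero variance get
    correlation 0 to every other row (with a warning) and 1 to themselves."""
    values = np.asarray(values, dtype=float)
    sd = values.std(axis=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance gene(s); their correlations "
            "are set to 0",
            stacklevel=2,
        )
        values = values.copy()
        values[zero_var] = 0.0
        sd = values.std(axis=1)
        sd[zero_var] = 1.0
    centered = values - values.mean(axis=1, keepdims=True)
    c = (centered / sd[:, None]) @ (centered / sd[:, None]).T / values.shape[1]
    c = np.nan_to_num(c, nan=0.0)
    np.clip(c, -1.0, 1.0, out=c)
    c[zero_var, :] = 0.0
    c[:, zero_var] = 0.0
    np.fill_diagonal(c, 1.0)
    return c


def adjacency(values: np.ndarray, power: float) -> np.ndarray:
    """Unsigned weighted adjacency ``|cor|^beta`` with unit diagonal."""
    if power < 1:
        raise ValueError("soft-threshold power must be >= 1")
    a = np.abs(correlation_matrix(values)) ** power
    np.fill_diagonal(a, 1.0)
    return a


@dataclass
class SoftThresholdScan:
    powers: list[float]
    fit_r2: list[float]
    mean_connectivity: list[float]
    chosen_power: float


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index for a connectivity vector.

    Bins k into ``n_bins`` equal-width bins (the referenced convention),
    regresses log10(frequency) on log10(mean k) over occupied bins, and
    returns R^2 signed by the negated slope, so that a decreasing degree
    distribution scores positively. Returns NaN when the fit is undefined
    (fewer than 3 occupied bins, or constant k).
    """
    k = np.asarray(k, dtype=float)
    if np.ptp(k) == 0:
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        freq = mask.mean()
        if mean_k > 0 and freq > 0:
            log_k.append(np.log10(mean_k))
            log_p.append(np.log10(freq))
    if len(log_k) < 3 or np.ptp(log_k) == 0:
        return float("nan")
    slope, _, r, _, _ = stats.linregress(log_k, log_p)
    return float(r**2 * np.sign(-slope))


def soft_threshold_scan(
    values: np.ndarray,
    powers=None,
    fit_threshold: float = 0.85,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Scan candidate powers for approximate scale-free topology.

    The chosen power is the smallest one whose signed fit R^2 reaches
    ``fit_threshold``; if none does, the power with the best fit. Powers with
    an undefined fit are skipped (flagged NaN).
    """
    if powers is None:
        powers = list(range(1, 21))
    c = np.abs(correlation_matrix(values))
    np.fill_diagonal(c, 0.0)
    fit_r2, mean_k = [], []
    for beta in powers:
        a = c**beta
        k = a.sum(axis=1)
        fit_r2.append(_scale_free_fit(k, n_bins))
        mean_k.append(float(k.mean()))
    arr = np.array(fit_r2)
    ok = np.where(np.nan_to_num(arr, nan=-np.inf) >= fit_threshold)[0]
    if ok.size:
        chosen = powers[int(ok[0])]
    elif np.isfinite(arr).any():
        chosen = powers[int(np.nanargmax(arr))]
    else:
        warnings.warn("scale-free fit undefined at every power", stacklevel=2)
        chosen = powers[0]
    return SoftThresholdScan(list(powers), fit_r2, mean_k, float(chosen))


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency with unit diagonal.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, with
    l_ij = sum_u a_iu a_uj over u not in {i, j} and k the connectivity
    excluding the diagonal; TOM_ii = 1.
    """
    a = np.asarray(adj, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
        raise ValueError("adjacency must be square symmetric")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    l = a0 @ a0  # (i,j) entry includes no u==i or u==j terms since diag 0
    k = a0.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a0) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def _static_cut(Z: np.ndarray, n: int, height: float) -> np.ndarray:
    return fcluster(Z, t=height, criterion="distance")


def cluster_modules(
    dissimilarity: np.ndarray,
    min_module_size: int = 30,
    cut_height_fraction: float = 0.99,
    max_cluster_fraction: float = 0.4,
) -> np.ndarray:
    """Average-linkage clustering with a simplified tree-style dynamic cut.

    The dendrogram is cut at ``cut_height_fraction`` of its maximum merge
    height. Any resulting cluster holding more than ``max_cluster_fraction``
    of the genes is considered oversized and is re-cut recursively within its
    own subtree, at the same height fraction of the subtree's own maximum
    merge — TOM dissimilarities saturate near 1 between unrelated gene
    groups, so a single static cut can leave distinct modules fused just
    below it; the descent resolves them without touching tight clusters,
    which re-merge at low heights and stop the recursion. Clusters below
    ``min_module_size`` are pooled into label 0 (grey); surviving modules are
    relabelled 1..K by decreasing size, ties broken by the smallest member
    index.
    """
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    if n < min_module_size:
        warnings.warn("fewer genes than min_module_size; all genes unassigned",
                      stacklevel=2)
        return np.zeros(n, dtype=int)

    max_size = max_cluster_fraction * n

    def cut_block(idx: np.ndarray, depth: int = 0) -> list[np.ndarray]:
        if idx.size < 2 or depth > 20:
            return [idx]
        sub = d[np.ix_(idx, idx)]
        Z = linkage(squareform(sub, checks=False), method="average")
        hmax = Z[:, 2].max()
        if hmax <= 0:
            return [idx]
        raw = _static_cut(Z, idx.size, cut_height_fraction * hmax)
        groups = [idx[raw == c] for c in np.unique(raw)]
        if len(groups) == 1:
            # plateau at the top: cut just below the final merge instead
            raw = _static_cut(Z, idx.size, np.nextafter(hmax, 0.0))
            groups = [idx[raw == c] for c in np.unique(raw)]
            if len(groups) == 1:
                return groups
        out = []
        for g in groups:
            if g.size > max_size and g.size < idx.size:
                out.extend(cut_block(g, depth + 1))
            else:
                out.append(g)
        return out

    blocks = cut_block(np.arange(n))
    labels = np.zeros(n, dtype=int)
    kept = [b for b in blocks if b.size >= min_module_size]
    kept.sort(key=lambda b: (-b.size, int(b.min())))
    for lab, b in enumerate(kept, start=1):
        labels[b] = lab
    return labels


def module_eigengenes(
    values: np.ndarray, labels: np.ndarray
) -> tuple[pd.DataFrame, dict[int, float]]:
    """First principal component of each module's gene-standardised profile.

    Returns (eigengenes, variance_explained): eigengenes is modules x samples
    with unit sample variance (ddof=1), sign-oriented so each eigengene
    correlates non-negatively with the module's mean expression profile.
    Label 0 (grey) is skipped.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    rows, ve = {}, {}
    for m in sorted(set(labels) - {0}):
        block = values[labels == m]
        sd = block.std(axis=1, keepdims=True)
        if (sd == 0).any():
            raise ValueError(f"module {m} contains zero-variance gene(s)")
        z = (block - block.mean(axis=1, keepdims=True)) / sd
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        mean_profile = block.mean(axis=0)
        if mean_profile.std() > 0 and np.corrcoef(eig, mean_profile)[0, 1] < 0:
            eig = -eig
        eig = (eig - eig.mean()) / eig.std(ddof=1)
        rows[m] = eig
        ve[m] = float(s[0] ** 2 / (s**2).sum())
    eigengenes = pd.DataFrame.from_dict(rows, orient="index")
    return eigengenes, ve


def merge_close_modules(
    values: np.ndarray, labels: np.ndarray, cut_height: float = 0.25
) -> np.ndarray:
    """Merge modules whose eigengene dissimilarity (1 - cor) is below
    ``cut_height``, closest pair first, recomputing eigengenes after each
    merge."""
    labels = np.asarray(labels).copy()
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            return labels
        eig, _ = module_eigengenes(values, labels)
        E = eig.loc[mods].to_numpy()
        cor = np.corrcoef(E)
        diss = 1 - cor
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= cut_height:
            return labels
        keep, drop = mods[min(i, j)], mods[max(i, j)]
        labels[labels == drop] = keep


def assign_colors(labels: np.ndarray) -> np.ndarray:
    """Name modules by decreasing size along the conventional palette;
    unassigned genes are grey. Size ties break on the smallest member index;
    modules beyond the palette get numbered names (``module21``, ...)."""
    labels = np.asarray(labels)
    mods = sorted(set(labels) - {0})
    order = sorted(
        mods, key=lambda m: (-(labels == m).sum(), int(np.flatnonzero(labels == m)[0]))
    )
    name = {0: "grey"}
    for rank, m in enumerate(order):
        name[m] = (
            COLOR_PALETTE[rank] if rank < len(COLOR_PALETTE) else f"module{rank + 1}"
        )
    return np.array([name[l] for l in labels])


def _cor_rows_vs_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xz = (x - x.mean(axis=1, keepdims=True))
    yz = (y - y.mean(axis=1, keepdims=True))
    xs = xz.std(axis=1)
    ys = yz.std(axis=1)
    xs[xs == 0] = np.nan
    ys[ys == 0] = np.nan
    c = (xz / xs[:, None]) @ (yz / ys[:, None]).T / x.shape[1]
    return np.clip(c, -1.0, 1.0)


def module_membership(values: np.ndarray, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """MM: correlation of every gene with every module eigengene
    (genes x modules)."""
    mm = _cor_rows_vs_rows(np.asarray(values, float), eigengenes.to_numpy())
    return pd.DataFrame(mm, columns=eigengenes.index)


def gene_significance(
    values: np.ndarray, trait: np.ndarray, signed: bool = False
) -> np.ndarray:
    """GS: correlation of each gene with a numeric trait; absolute value by
    default (signed available)."""
    trait = np.asarray(trait, dtype=float)
    if trait.std() == 0:
        raise ValueError("trait has zero variance")
    gs = _cor_rows_vs_rows(np.asarray(values, float), trait[None, :])[:, 0]
    return gs if signed else np.abs(gs)


def _cor_test_p(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(np.asarray(r, dtype=float), -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return 2 * stats.t.sf(np.abs(t), df=n - 2)


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r and two-sided p (via the t transform with n-2 df) between
    every module eigengene and every trait column. Undefined correlations
    (constant trait or eigengene) are reported as NaN."""
    n = eigengenes.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    records = []
    for m in eigengenes.index:
        e = eigengenes.loc[m].to_numpy(dtype=float)
        for tr in traits.columns:
            t = traits[tr].to_numpy(dtype=float)
            if e.std() == 0 or t.std() == 0:
                records.append((m, tr, np.nan, np.nan))
                continue
            r = float(np.corrcoef(e, t)[0, 1])
            records.append((m, tr, r, float(_cor_test_p(np.array([r]), n)[0])))
    return pd.DataFrame(records, columns=["module", "trait", "r", "p"])


def select_hub_genes(
    mm: pd.DataFrame,
    gs: np.ndarray,
    labels: np.ndarray,
    mm_threshold: float = 0.8,
    gs_threshold: float = 0.2,
    modules=None,
) -> np.ndarray:
    """Boolean hub mask: genes in the selected modules with |MM to their own
    module| strictly above ``mm_threshold`` and GS strictly above
    ``gs_threshold``."""
    labels = np.asarray(labels)
    gs = np.asarray(gs, dtype=float)
    if modules is None:
        modules = sorted(set(labels) - {0})
    hub = np.zeros(labels.size, dtype=bool)
    for m in modules:
        in_mod = labels == m
        if m not in mm.columns:
            continue
        own = np.abs(mm[m].to_numpy())
        hub |= in_mod & (own > mm_threshold) & (gs > gs_threshold)
    return hub


@dataclass
class ModulePartition:
    """Bundle of a fitted coexpression network partition."""

    labels: np.ndarray
    colors: np.ndarray
    eigengenes: pd.DataFrame
    variance_explained: dict[int, float]
    mm: pd.DataFrame
    gs: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
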