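"""Gene-list integration: set overlaps and over-representation analysis.

The overlap report mirrors the Venn-diagram step that intersects the
differential, coexpression-hub and DNB gene lists and pools the overlapping
genes into the final candidate list. Over-representation analysis (ORA)
scores a query list against a GMT collection with the hypergeometric upper
tail; a set passes when the overlap is at least ``min_overlap`` (default 3),
p < ``p_cutoff`` (default 0.01) and the enrichment factor — observed over
expected overlap, ``(k/q)/(s/U)`` — is at least ``min_enrichment``
(default 1.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd
from scipy.stats import hypergeom

from .deg import bh_adjust

__all__ = [
    "OverlapReport",
    "GeneSetCollection",
    "overlap_report",
    "ora",
    "read_gmt",
]


@dataclass
class OverlapReport:
    sets: dict[str, set[str]]
    intersections: dict[tuple[str, ...], list[str]]
    union_of_overlaps: list[str]

    def sizes(self) -> dict[str, int]:
        out = {name: len(s) for name, s in self.sets.items()}
        out.update({" & ".join(k): len(v) for k, v in self.intersections.items()})
        return out

    def as_dict(self) -> dict:
        return {
            "sets": {k: sorted(v) for k, v in self.sets.items()},
            "intersections": {
                " & ".join(k): v for k, v in self.intersections.items()
            },
            "union_of_overlaps": self.union_of_overlaps,
        }


def overlap_report(sets: dict[str, set[str]]) -> OverlapReport:
    """All pairwise and higher-order intersections of named gene sets, with
    sorted member lists; ``union_of_overlaps`` pools every gene appearing in
    at least one pairwise intersection."""
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least 2 named sets")
    if len(set(names)) != len(names):
        raise ValueError("duplicate set names")
    intersections: dict[tuple[str, ...], list[str]] = {}
    pooled: set[str] = set()
    for k in range(2, len(names) + 1):
        for combo in combinations(names, k):
            inter = set.intersection(*(set(sets[n]) for n in combo))
            intersections[combo] = sorted(inter)
            if k == 2:
                pooled |= inter
    return OverlapReport(
        sets={n: set(sets[n]) for n in names},
        intersections=intersections,
        union_of_overlaps=sorted(pooled),
    )


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if any(not name for name in self.sets):
            raise ValueError("empty gene-set name")
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()


def ora(
    query: set[str],
    collection: GeneSetCollection,
    min_overlap: int = 3,
    p_cutoff: float = 0.01,
    min_enrichment: float = 1.5,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each collection set.

    p = P[X >= k] for X ~ Hypergeom(U, s, q) with U the universe size, s the
    set size (restricted to the universe), q the query size and k the
    overlap. Query genes outside the universe are an error.
    """
    U = len(collection.universe)
    outside = set(query) - collection.universe
    if outside:
        raise ValueError(
            f"query gene(s) outside the universe: {sorted(outside)[:10]}"
        )
    q = len(query)
    rows = []
    for name, members in collection.sets.items():
        s_set = set(members) & collection.universe
        s = len(s_set)
        k = len(s_set & set(query))
        p = float(hypergeom.sf(k - 1, U, s, q)) if s and q else 1.0
        expected = q * s / U if U else 0.0
        ef = (k / expected) if expected else 0.0
        rows.append((name, s, k, ef, p))
    out = pd.DataFrame(
        rows, columns=["set", "set_size", "overlap_count", "enrichment_factor", "p_value"]
    )
    out["adj_p"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    out["passes"] = (
        (out["overlap_count"] >= min_overlap)
        & (out["p_value"] < p_cutoff)
        & (out["enrichment_factor"] >= min_enrichment)
    )
    return out.sort_values(["p_value", "set"]).reset_index(drop=True)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name <tab> description <tab> member ...).

    Duplicate members within a set are de-duplicated with a warning; a line
    with fewer than 3 fields is an error reported with its line number.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
        name, desc, *members = fields
        members = [m for m in members if m]
        if len(set(members)) < len(members):
            warnings.warn(
                f"{path}: line {lineno}: duplicate members in set {name!r}",
                stacklevel=2,
            )
        sets[name] = set(members)
        descriptions[name] = desc
    if not sets:
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
    return GeneSetCollection(sets=sets, descriptions=descriptions)
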