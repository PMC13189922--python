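"""Gene-set over-representation analysis (ORA).

Query lists (top-N called genes, or diametral gene sets) are tested against
GMT collections with the one-sided Fisher exact test, BH-adjusted within
each collection.  The curated-pathway overlap report mirrors the "n (o/t) %"
accounting of pathway tables: called genes intersected with each set, split
by direction, with the percentage of the set covered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, StatsError
from .rounding import percent
from .stats import FeatureCalls, bh_adjust, fisher_exact

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "select_top_n",
    "enrich",
    "pathway_overlap_report",
    "synthetic_pathway_collection",
    "PATHWAY_SET_SIZES",
]

#: Curated-pathway set sizes used for the synthetic overlap-report fixture.
PATHWAY_SET_SIZES = {
    "Focal_Adhesion": 201,
    "Fibrosis": 67,
    "Syndactyly": 113,
    "Wound_Healing": 176,
    "EMT": 90,
    "p53_Signaling": 179,
    "Squamous_Cell_Carcinoma": 214,
}


@dataclass
class GeneSetCollection:
    """Named gene sets: name -> (description, member symbols)."""

    sets: dict = field(default_factory=dict)  # name -> frozenset
    descriptions: dict = field(default_factory=dict)

    def add(self, name: str, description: str, members) -> None:
        members = frozenset(members)
        if name in self.sets:
            raise ParseError(f"duplicate gene-set name {name!r}")
        if not members:
            raise ParseError(f"gene set {name!r} has no members")
        self.sets[name] = members
        self.descriptions[name] = description

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name TAB description TAB gene TAB gene ...

    Duplicate genes within a line are deduplicated; a line without genes is
    a parse error reported with its line number.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected name, description, >=1 gene")
            name, description = parts[0], parts[1]
            genes = [g for g in parts[2:] if g]
            if not genes:
                raise ParseError(f"{path}: line {lineno}: gene set {name!r} has no genes")
            coll.add(name, description, genes)
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in coll.sets:
            genes = "\t".join(sorted(coll.sets[name]))
            fh.write(f"{name}\t{coll.descriptions.get(name, '')}\t{genes}\n")


def select_top_n(table: pd.DataFrame, calls: FeatureCalls, n: int = 100) -> tuple[list, list]:
    """Top-``n`` called features per direction for enrichment queries.

    Ranking among called features: ascending p, ties by descending |logFC|,
    then lexicographic feature id.  Returns (top up, top down), each best-p
    first and shorter than ``n`` when fewer features are called.
    """
    if n < 1:
        raise StatsError("n must be >= 1")
    sub = table.set_index("feature_id")

    def top(features) -> list:
        ranked = sorted(
            features,
            key=lambda f: (sub.at[f, "p_value"], -abs(sub.at[f, "logFC"]), str(f)),
        )
        return ranked[:n]

    return top(calls.up), top(calls.down)


def enrich(query, collection: GeneSetCollection, universe) -> pd.DataFrame:
    """One-sided Fisher enrichment of ``query`` against every set.

    Set members are intersected with the universe (all tested features);
    query genes outside the universe are dropped with a warning.  BH
    adjustment is applied across the collection; rows are sorted by p.
    """
    universe = set(universe)
    query = list(dict.fromkeys(query))
    outside = [g for g in query if g not in universe]
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the universe were dropped")
    query_set = frozenset(g for g in query if g in universe)
    if not query_set:
        raise StatsError("query is empty after intersecting with the universe")

    N = len(universe)
    n = len(query_set)
    rows = []
    for name, members in collection.sets.items():
        in_universe = members & universe
        K = len(in_universe)
        overlap = sorted(query_set & in_universe)
        k = len(overlap)
        if K == 0:
            odds, p = float("nan"), 1.0
        else:
            odds, p = fisher_exact(k, K, n, N)
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "odds_ratio": odds,
                "p_value": p,
                "overlap_genes": ",".join(overlap),
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out = out.sort_values(["p_value", "set_name"], kind="stable").reset_index(drop=True)
    return out[
        [
            "set_name",
            "overlap",
            "set_size",
            "query_size",
            "universe_size",
            "odds_ratio",
            "p_value",
            "q_value",
            "overlap_genes",
        ]
    ]


def pathway_overlap_report(calls: FeatureCalls, pathway_sets: GeneSetCollection) -> pd.DataFrame:
    """Curated-pathway coverage of the called genes, split by direction.

    For each set: overlap genes among up- and down-calls, "k/K" accounting
    and the percentage of the set covered (half-up, one decimal).
    """
    rows = []
    for name, members in pathway_sets.sets.items():
        up = sorted(members & calls.up)
        down = sorted(members & calls.down)
        k = len(up) + len(down)
        K = len(members)
        rows.append(
            {
                "pathway": name,
                "up_genes": ",".join(up),
                "down_genes": ",".join(down),
                "n_overlap": k,
                "set_size": K,
                "overlap": f"{k}/{K}",
                "percent": percent(k, K, 1) if K else 0.0,
            }
        )
    return pd.DataFrame(rows)


def synthetic_pathway_collection(universe, seed: int = 0, sizes: dict | None = None) -> GeneSetCollection:
    """Synthetic stand-in for the curated pathway lists.

    Set sizes follow the curated collections the overlap report mirrors, but
    membership is drawn at random from ``universe`` — the real lists are
    versioned external resources and are not bundled.
    """
    sizes = dict(sizes or PATHWAY_SET_SIZES)
    universe = list(dict.fromkeys(universe))
    rng = np.random.default_rng(seed)
    coll = GeneSetCollection()
    for name, size in sizes.items():
        take = min(size, len(universe))
        idx = rng.choice(len(universe), size=take, replace=False)
        coll.add(name, "synthetic membership; size mirrors the curated list", [universe[i] for i in idx])
    return coll
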