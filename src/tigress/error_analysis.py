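"""Topology of false positives on the gold-standard network.

A predicted pair absent from the directed gold standard ("spurious") is
characterized by the shortest-path distance between its endpoints on the
*undirected* gold graph: a reversed true edge sits at distance 1, a pair
sharing a regulator or a target at distance 2, and so on.  The running
proportion of each distance bin among the first r spurious predictions is
compared with a null band from the hypergeometric distribution (sampling r
of the N_S spurious edges without replacement).  Distance-2 pairs are
further classified into the three witnessed motifs: siblings (common
regulator), couple (common target) and grandparent/grandchild (two-step
directed chain); one pair may show several patterns at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import GoldStandard, RankedEdgeList

__all__ = [
    "DistanceProfile",
    "Distance2Patterns",
    "DISTANCE_BINS",
    "undirected_distances",
    "hypergeometric_band",
    "classify_distance2",
    "fp_profile_report",
    "plot_distance_profile",
]

DISTANCE_BINS = ("1", "2", "3", "4", ">4", "unreachable")


def _bin_of(dist: float, merge_unreachable: bool) -> str:
    if np.isinf(dist):
        return ">4" if merge_unreachable else "unreachable"
    return str(int(dist)) if dist <= 4 else ">4"


@dataclass
class DistanceProfile:
    """Distances of queried pairs on the undirected gold graph, binned."""

    distances: list[float]          # per pair, inf when no connecting path
    bins: list[str]                 # per pair, one of DISTANCE_BINS
    p_hat: dict[str, float]         # overall proportion per bin
    N_S: int

    def counts(self) -> dict[str, int]:
        return {b: self.bins.count(b) for b in DISTANCE_BINS}


@dataclass
class Distance2Patterns:
    """Motif flags of one distance-2 pair, each certified by witness nodes."""

    sibling: list[str] = field(default_factory=list)            # u with u->t and u->g
    couple: list[str] = field(default_factory=list)             # u with t->u and g->u
    grandparent_grandchild: list[str] = field(default_factory=list)  # u with t->u->g or g->u->t

    @property
    def flags(self) -> set[str]:
        out = set()
        if self.sibling:
            out.add("sibling")
        if self.couple:
            out.add("couple")
        if self.grandparent_grandchild:
            out.add("grandparent_grandchild")
        return out


def _undirected_graph(gold: GoldStandard) -> nx.Graph:
    G = nx.Graph()
    G.add_edges_from(gold.positive_edges)
    return G


def undirected_distances(
    gold: GoldStandard,
    pairs: list[tuple[str, str]],
    merge_unreachable: bool = False,
) -> DistanceProfile:
    """Shortest-path distance of each pair on the undirected positive graph.

    Distances are binned {1, 2, 3, 4, >4}; pairs with no connecting path
    (or an endpoint absent from the graph) go to a separate "unreachable"
    bin by default, or are merged into ">4" with ``merge_unreachable``.
    """
    if not gold.positive_edges:
        raise ValueError("gold standard has no positive edges")
    G = _undirected_graph(gold)
    bfs_cache: dict[str, dict[str, int]] = {}
    distances: list[float] = []
    for a, b in pairs:
        if a not in G or b not in G:
            distances.append(np.inf)
            continue
        if a not in bfs_cache:
            bfs_cache[a] = nx.single_source_shortest_path_length(G, a)
        distances.append(float(bfs_cache[a].get(b, np.inf)))
    bins = [_bin_of(d, merge_unreachable) for d in distances]
    N_S = len(pairs)
    p_hat = {b: (bins.count(b) / N_S if N_S else 0.0) for b in DISTANCE_BINS}
    return DistanceProfile(distances=distances, bins=bins, p_hat=p_hat, N_S=N_S)


def hypergeometric_band(
    p_hat_x: float, N_S: int, r: int, level: float = 0.95
) -> tuple[float, float]:
    """Null band for the proportion of a distance bin among the first r FPs.

    If the r spurious edges seen so far were an exchangeable sample (without
    replacement) of all N_S spurious edges, of which round(p_hat_x * N_S)
    fall in bin x, the count in the first r draws is hypergeometric.  The
    band is [q_lo / r, q_hi / r] with q the (1-level)/2 and 1-(1-level)/2
    quantiles.  With r = N_S the band collapses to p_hat_x (up to rounding);
    with p_hat_x = 0 it is (0, 0).
    """
    if not 0.0 <= p_hat_x <= 1.0:
        raise ValueError("proportion must be in [0, 1]")
    if not 1 <= r <= N_S:
        raise ValueError(f"rank r={r} must be in [1, N_S={N_S}]")
    K = int(round(p_hat_x * N_S))
    a = (1.0 - level) / 2.0
    dist = hypergeom(N_S, K, r)
    lo = float(dist.ppf(a))
    hi = float(dist.ppf(1.0 - a))
    return lo / r, hi / r


def classify_distance2(
    edge: tuple[str, str], gold: GoldStandard
) -> Distance2Patterns:
    """Motif flags of a distance-2 pair, with their witness nodes.

    sibling: some u regulates both t and g; couple: t and g regulate a
    common u; grandparent/grandchild: a directed two-step chain t->u->g or
    g->u->t.  Every distance-2 pair carries at least one flag, and may
    carry several.
    """
    t, g = edge
    profile = undirected_distances(gold, [(t, g)])
    if profile.distances[0] != 2:
        raise ValueError(
            f"({t}, {g}) is at undirected distance {profile.distances[0]}, not 2"
        )
    parents_t = {u for (u, v) in gold.positive_edges if v == t}
    parents_g = {u for (u, v) in gold.positive_edges if v == g}
    children_t = {v for (u, v) in gold.positive_edges if u == t}
    children_g = {v for (u, v) in gold.positive_edges if u == g}
    return Distance2Patterns(
        sibling=sorted(parents_t & parents_g),
        couple=sorted(children_t & children_g),
        grandparent_grandchild=sorted((children_t & parents_g) | (children_g & parents_t)),
    )


def fp_profile_report(
    ranked: RankedEdgeList,
    gold: GoldStandard,
    max_rank: int | None = None,
    level: float = 0.95,
    merge_unreachable: bool = False,
) -> pd.DataFrame:
    """Running distance profile of the spurious predictions, with null bands.

    One row per spurious edge within the top ``max_rank`` predictions, in
    discovery order.  Columns: the prediction rank, the pair, its distance
    bin, the running proportion of each bin among the first r spurious
    edges with its hypergeometric null band, and cumulative distance-2
    motif counts.  The machine-readable form of the distance-distribution
    and motif figures.
    """
    rows = ranked.rows if max_rank is None else ranked.rows[:max_rank]
    spurious = [
        (rank, (t, g))
        for rank, (t, g, _) in enumerate(rows, start=1)
        if (t, g) not in gold.positive_edges
    ]
    if not spurious:
        return pd.DataFrame(
            columns=["rank", "regulator", "target", "distance_bin"]
        )
    pairs = [pair for _, pair in spurious]
    profile = undirected_distances(gold, pairs, merge_unreachable=merge_unreachable)
    N_S = profile.N_S

    records = []
    running = {b: 0 for b in DISTANCE_BINS}
    motifs = {"sibling": 0, "couple": 0, "grandparent_grandchild": 0}
    for r, ((rank, (t, g)), b) in enumerate(zip(spurious, profile.bins), start=1):
        running[b] += 1
        if b == "2":
            for flag in classify_distance2((t, g), gold).flags:
                motifs[flag] += 1
        rec = {
            "rank": rank,
            "regulator": t,
            "target": g,
            "distance_bin": b,
            "n_spurious": r,
        }
        for x in DISTANCE_BINS:
            lo, hi = hypergeometric_band(profile.p_hat[x], N_S, r, level=level)
            rec[f"prop_{x}"] = running[x] / r
            rec[f"band_lo_{x}"] = lo
            rec[f"band_hi_{x}"] = hi
        rec.update({f"n_{k}": v for k, v in motifs.items()})
        records.append(rec)
    return pd.DataFrame.from_records(records)


def plot_distance_profile(report: pd.DataFrame, ax=None):
    """Plot running distance-bin proportions with their null bands."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    if report.empty:
        ax.set_title("no spurious edges")
        return ax
    r = report["n_spurious"]
    for x in DISTANCE_BINS:
        col = f"prop_{x}"
        if col not in report or report[col].iloc[-1] == 0 and x in (">4", "unreachable"):
            continue
        (line,) = ax.plot(r, report[col], label=f"distance {x}")
        ax.fill_between(
            r, report[f"band_lo_{x}"], report[f"band_hi_{x}"],
            alpha=0.15, color=line.get_color(),
        )
    ax.set_xlabel("number of spurious predictions r")
    ax.set_ylabel("proportion among first r spurious edges")
    ax.legend(fontsize=8)
    return ax
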