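"""Weighted Number of Links (WNL) scoring on a thresholded interaction network.

The WNL of a panel gene is the sum of the combined interaction scores of its
edges to *other panel genes* that survive the confidence threshold tau
(inclusive, score >= tau).  Genes whose WNL is exactly zero — no retained
interaction at all — are "orphans" and form their own output class; everything
with WNL > 0 is "linked" and enters the clustering.

Because every retained undirected edge is credited to both endpoints, the WNL
table obeys the conservation identity

    sum_g WNL(g) = 2 * sum_{retained edges} score,

which the test suite checks against a brute-force all-pairs oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import networkx as nx
import pandas as pd

from .io import normalize_symbol

__all__ = [
    "OrphanPartition",
    "compute_wnl",
    "expand_candidates",
    "partition_orphans",
    "threshold_network",
]


def _check_tau(tau: float) -> float:
    tau = float(tau)
    if not 0.0 < tau <= 1.0:
        raise ValueError(f"tau must lie in (0, 1], got {tau}")
    return tau


def threshold_network(net: nx.Graph, tau: float) -> nx.Graph:
    """Subnetwork keeping exactly the edges with score >= tau; nodes unchanged."""
    tau = _check_tau(tau)
    sub = nx.Graph()
    sub.add_nodes_from(net.nodes)
    sub.add_edges_from(
        (u, v, {"score": d["score"]})
        for u, v, d in net.edges(data=True)
        if d["score"] >= tau
    )
    return sub


def compute_wnl(
    net: nx.Graph, panel: Iterable[str], tau: float = 0.9
) -> pd.Series:
    """Per-gene WNL over panel-internal edges with score >= tau.

    Edges to genes outside the panel contribute nothing: associations are
    computed between each gene and the curated gene set only.  Panel genes
    absent from the network get WNL = 0.

    Returns a float Series indexed by sorted panel symbols.
    """
    tau = _check_tau(tau)
    panel_set = {normalize_symbol(g) for g in panel}
    if not panel_set:
        raise ValueError("empty gene panel")
    wnl = dict.fromkeys(sorted(panel_set), 0.0)
    for u, v, d in net.edges(data=True):
        s = float(d["score"])
        if s >= tau and u in wnl and v in wnl:
            wnl[u] += s
            wnl[v] += s
    return pd.Series(wnl, name="wnl")


@dataclass(frozen=True)
class OrphanPartition:
    """Exact split of the panel on WNL == 0 (orphans) vs WNL > 0 (linked)."""

    orphans: frozenset[str]
    linked: frozenset[str]


def partition_orphans(wnl: pd.Series) -> OrphanPartition:
    """Split a WNL table into orphans (WNL == 0) and linked genes (WNL > 0).

    The test is exact — WNL is a sum of retained scores and is zero only
    when that sum is empty — so no epsilon is involved.
    """
    orphans = frozenset(wnl.index[wnl == 0.0])
    linked = frozenset(wnl.index[wnl > 0.0])
    return OrphanPartition(orphans=orphans, linked=linked)


def expand_candidates(
    net: nx.Graph,
    seeds: Iterable[str],
    tau: float = 0.9,
    rounds: int | None = None,
    accept: Callable[[str], bool] | None = None,
) -> frozenset[str]:
    """Grow a seed set by repeated high-confidence neighbour expansion.

    Each round adds every network neighbour reachable from the current set
    by an edge with score >= tau that passes the ``accept`` predicate (the
    hook where an external curation/literature filter plugs in; default
    accept-all).  ``rounds=None`` iterates to closure, which is reached in
    at most ``len(net)`` rounds; ``rounds=0`` returns the seeds unchanged.
    """
    tau = _check_tau(tau)
    current = {normalize_symbol(g) for g in seeds}
    if accept is None:
        accept = lambda _g: True  # noqa: E731 - trivial default hook
    limit = net.number_of_nodes() if rounds is None else int(rounds)
    if limit < 0:
        raise ValueError("rounds must be non-negative")
    for _ in range(limit):
        frontier: set[str] = set()
        for g in current:
            if g not in net:
                continue
            for h, d in net[g].items():
                if d["score"] >= tau and h not in current and accept(h):
                    frontier.add(h)
        if not frontier:
            break
        current |= frontier
    return frozenset(current)
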