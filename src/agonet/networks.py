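"""Directed agonistic networks and from-scratch centrality parameters.

Two network flavors are built per pen from the same decisive events:

* ``IR`` (initiator-receiver): one edge from each attack's initiator to its
  receiver -- who starts fights with whom.
* ``WL`` (winner-loser): one edge from each decisive fight's winner to its
  loser -- who dominates whom.

Multiple interactions of a dyad in the same direction collapse to a single
unweighted edge; the node set is always the full pen roster, so animals with
no interactions stay in the graph as isolated nodes with zero centralities.

Centralities follow the directed conventions of classical social-network
analysis:

* standardized degree = raw degree / (n - 1);
* closeness with the Wasserman-Faust correction for disconnected digraphs:
  for the ingoing direction of node ``v``, with ``R`` the set of nodes that
  reach ``v`` and ``s`` the sum of their geodesic distances to ``v``,
  ``closeness = (|R| / s) * (|R| / (n - 1))`` (0 when ``R`` is empty);
* betweenness by Brandes' accumulation over ordered node pairs with
  fractional geodesic counting, endpoints excluded, normalized by
  ``(n - 1)(n - 2)``.

All three are implemented here directly (breadth-first geodesics on
adjacency sets); general-purpose graph libraries are used only as
independent cross-checks in the test suite.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .events import InteractionEvent, PenRoster, ValidationError

__all__ = [
    "AgonisticNetwork",
    "build_network",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "isolated_fraction",
    "centrality_table",
    "edge_list",
]

Flavor = Literal["IR", "WL"]


@dataclass(frozen=True)
class AgonisticNetwork:
    """Directed simple graph over a full pen roster."""

    flavor: Flavor
    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        nodeset = set(self.nodes)
        for u, v in self.edges:
            if u == v:
                raise ValidationError(f"self-loop at {u!r}")
            if u not in nodeset or v not in nodeset:
                raise ValidationError(f"edge ({u!r}, {v!r}) leaves the node set")

    @property
    def n(self) -> int:
        return len(self.nodes)

    def successors(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {v: set() for v in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
        return adj

    def predecessors(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {v: set() for v in self.nodes}
        for u, v in self.edges:
            adj[v].add(u)
        return adj


def build_network(
    events: Iterable[InteractionEvent], roster: PenRoster, flavor: Flavor
) -> AgonisticNetwork:
    """Aggregate decisive events of one pen into a directed simple graph."""
    if flavor not in ("IR", "WL"):
        raise ValidationError(f"unknown network flavor {flavor!r}")
    edges: set[tuple[str, str]] = set()
    for e in events:
        if not e.decisive:
            raise ValidationError("build_network expects decisive events only")
        u, v = (e.initiator, e.receiver) if flavor == "IR" else (e.winner, e.loser)
        if u not in roster or v not in roster:
            raise ValidationError(
                f"participant {u!r}/{v!r} not in roster of pen {roster.pen_id!r}"
            )
        edges.add((u, v))
    return AgonisticNetwork(flavor, tuple(roster.animals), frozenset(edges))


def _bfs_distances(adj: dict[str, set[str]], source: str) -> dict[str, int]:
    """Unweighted geodesic distances from ``source`` along ``adj``."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def degree_centrality(net: AgonisticNetwork) -> pd.DataFrame:
    """Raw and standardized in/out-degree per node.

    On the WL flavor, out-degree counts distinct pen mates beaten and
    in-degree distinct pen mates lost to; on IR, attacked vs. attacked-by.
    """
    if net.n < 2:
        raise ValidationError("degree centrality needs n >= 2")
    indeg = {v: 0 for v in net.nodes}
    outdeg = {v: 0 for v in net.nodes}
    for u, v in net.edges:
        outdeg[u] += 1
        indeg[v] += 1
    denom = net.n - 1
    return pd.DataFrame(
        {
            "animal": list(net.nodes),
            "in_degree_raw": [indeg[v] for v in net.nodes],
            "out_degree_raw": [outdeg[v] for v in net.nodes],
            "in_degree_std": [indeg[v] / denom for v in net.nodes],
            "out_degree_std": [outdeg[v] / denom for v in net.nodes],
        }
    ).set_index("animal")


def closeness_centrality(
    net: AgonisticNetwork, direction: Literal["in", "out"]
) -> dict[str, float]:
    """Wasserman-Faust closeness per node, for ingoing or outgoing paths.

    ``in``: based on distances *to* the node from everything that reaches it;
    ``out``: distances *from* the node, i.e. the same on reversed edges.
    """
    if net.n < 2:
        raise ValidationError("closeness centrality needs n >= 2")
    if direction not in ("in", "out"):
        raise ValidationError(f"direction must be 'in' or 'out', got {direction!r}")
    # Distances to v over incoming paths are distances from v in the reversed
    # graph; for the outgoing variant BFS runs on the original edges.
    adj = net.predecessors() if direction == "in" else net.successors()
    out: dict[str, float] = {}
    for v in net.nodes:
        dist = _bfs_distances(adj, v)
        reach = len(dist) - 1
        if reach == 0:
            out[v] = 0.0
            continue
        s = sum(dist.values())
        out[v] = (reach / s) * (reach / (net.n - 1))
    return out


def betweenness_centrality(net: AgonisticNetwork) -> dict[str, float]:
    """Directed shortest-path betweenness, endpoints excluded.

    Brandes' dependency accumulation: for each source, one BFS records
    geodesic counts ``sigma`` and predecessor lists, then dependencies are
    accumulated in reverse BFS order.  Normalized by ``(n - 1)(n - 2)``.
    """
    if net.n < 2:
        raise ValidationError("betweenness centrality needs n >= 2")
    adj = net.successors()
    bc = {v: 0.0 for v in net.nodes}
    for s in net.nodes:
        sigma = {v: 0.0 for v in net.nodes}
        sigma[s] = 1.0
        dist = {s: 0}
        preds: dict[str, list[str]] = {v: [] for v in net.nodes}
        order: list[str] = []
        queue = deque([s])
        while queue:
            u = queue.popleft()
            order.append(u)
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    queue.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
                    preds[w].append(u)
        delta = {v: 0.0 for v in net.nodes}
        for w in reversed(order):
            for u in preds[w]:
                delta[u] += sigma[u] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    if net.n > 2:
        norm = (net.n - 1) * (net.n - 2)
        for v in bc:
            bc[v] /= norm
    return bc


def isolated_fraction(net: AgonisticNetwork) -> float:
    """Fraction of rostered animals with no interaction at all."""
    connected = {u for e in net.edges for u in e}
    return 1.0 - len(connected) / net.n


def centrality_table(net: AgonisticNetwork) -> pd.DataFrame:
    """All five centrality parameters per node, indexed by animal.

    Columns: in/out-degree (raw and standardized), ingoing/outgoing
    closeness, betweenness.
    """
    frame = degree_centrality(net)
    frame["closeness_in"] = pd.Series(closeness_centrality(net, "in"))
    frame["closeness_out"] = pd.Series(closeness_centrality(net, "out"))
    frame["betweenness"] = pd.Series(betweenness_centrality(net))
    return frame


def edge_list(net: AgonisticNetwork, pen_id: str) -> pd.DataFrame:
    """Edge-list export (pen_id, flavor, source, target), sorted for determinism."""
    rows = sorted(net.edges)
    return pd.DataFrame(
        {
            "pen_id": pen_id,
            "flavor": net.flavor,
            "source": [u for u, _ in rows],
            "target": [v for _, v in rows],
        }
    )
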