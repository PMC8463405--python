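"""Network property suite: components, paths, clustering, communities, key nodes.

All metrics treat the graph as simple and unsigned within a scope (whole
network, co-occurrence subnetwork, co-exclusion subnetwork).  Path metrics
are computed on the maximum component.  Two modularity scores are reported:
Q under the connected-component partition, and Q under a seeded Louvain
partition (the "LC modularity").
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = [
    "MetricsReport",
    "maximum_component",
    "diameter",
    "average_path_length",
    "transitivity",
    "modularity",
    "louvain_lc_modularity",
    "assortativity_nominal",
    "key_nodes",
    "report",
    "metrics_table",
]

SCOPES = ("all", "co_occurrence", "co_exclusion")


@dataclass
class MetricsReport:
    """Per-network property vector for one scope."""

    scope: str
    n_nodes: int
    n_edges: int
    max_component_size: int
    diameter: int
    avg_path_length: float
    transitivity: float
    modularity: float
    lc_modularity: float
    n_key_nodes: int
    key_nodes: list[str] = field(default_factory=list)
    assortativity: dict[str, float] = field(default_factory=dict)
    degrees: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["assortativity"] = {k: v for k, v in self.assortativity.items()}
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def maximum_component(g: nx.Graph) -> nx.Graph:
    """The largest connected component (ties broken by smallest sorted node
    id set); the empty graph maps to itself."""
    if g.number_of_nodes() == 0:
        return g.copy()
    comps = [sorted(c, key=str) for c in nx.connected_components(g)]
    largest = max(len(c) for c in comps)
    # ties broken by the lexicographically smallest sorted node id set
    best = min((c for c in comps if len(c) == largest), key=lambda c: tuple(map(str, c)))
    return g.subgraph(best).copy()


def diameter(g: nx.Graph) -> int:
    """Longest shortest path (edge count) of a connected graph."""
    if g.number_of_nodes() == 0:
        return 0
    if not nx.is_connected(g):
        raise ValidationError(
            "diameter is defined on a connected graph; pass maximum_component(g)"
        )
    return int(nx.diameter(g))


def average_path_length(g: nx.Graph) -> float:
    """Mean shortest-path edge count over unordered node pairs (connected g)."""
    if g.number_of_nodes() <= 1:
        return 0.0
    if not nx.is_connected(g):
        raise ValidationError(
            "average path length is defined on a connected graph; "
            "pass maximum_component(g)"
        )
    return float(nx.average_shortest_path_length(g))


def transitivity(g: nx.Graph) -> float:
    """Global clustering: 3 x triangles / connected triples (0 if no triples)."""
    return float(nx.transitivity(g))


def modularity(g: nx.Graph, partition: list[set]) -> float:
    """Newman–Girvan Q = sum_c [e_c/m - (d_c/2m)^2] for a node partition."""
    if g.number_of_edges() == 0:
        warnings.warn("modularity undefined on an edgeless graph; returning NaN")
        return float("nan")
    covered = set().union(*partition) if partition else set()
    if covered != set(g.nodes):
        raise ValidationError("partition must cover every node exactly")
    return float(nx.community.modularity(g, partition))


def louvain_lc_modularity(
    g: nx.Graph, seed: int = 0, within_community: bool = False
) -> tuple[list[set], float]:
    """Seeded Louvain communities and the modularity of that partition.

    With ``within_community=True`` the score is instead the unweighted mean,
    over Louvain communities with at least one internal edge, of each
    community subgraph's modularity under its own Louvain partition.
    """
    if g.number_of_nodes() == 0:
        return [], float("nan")
    part = [set(c) for c in nx.community.louvain_communities(g, seed=seed)]
    if g.number_of_edges() == 0:
        return part, float("nan")
    if not within_community:
        return part, float(nx.community.modularity(g, part))
    inner = []
    for comm in part:
        sub = g.subgraph(comm)
        if sub.number_of_edges() == 0:
            continue
        sub_part = [set(c) for c in nx.community.louvain_communities(sub, seed=seed)]
        inner.append(float(nx.community.modularity(sub, sub_part)))
    return part, (float(np.mean(inner)) if inner else float("nan"))


def assortativity_nominal(g: nx.Graph, labels: dict[str, str],
                          attr_name: str = "label") -> float:
    """Newman's nominal assortativity for a categorical node attribute."""
    missing = [n for n in g.nodes if n not in labels]
    if missing:
        raise ValidationError(f"nodes without a label: {missing[:5]}")
    present = {labels[n] for n in g.nodes}
    if len(present) < 2 or g.number_of_edges() == 0:
        warnings.warn("assortativity undefined (single label or no edges); NaN")
        return float("nan")
    h = g.copy()
    nx.set_node_attributes(h, {n: labels[n] for n in h.nodes}, attr_name)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = nx.attribute_assortativity_coefficient(h, attr_name)
    return float(r)


def key_nodes(g: nx.Graph, percentile: float = 75.0) -> list[str]:
    """Articulation points with betweenness at or above the given percentile
    of betweenness over all nodes, sorted by descending betweenness."""
    if g.number_of_nodes() == 0:
        return []
    bc = nx.betweenness_centrality(g, normalized=False)
    cut = float(np.percentile(list(bc.values()), percentile))
    aps = set(nx.articulation_points(g))
    keys = [n for n in aps if bc[n] >= cut]
    return sorted(keys, key=lambda n: (-bc[n], str(n)))


def _scope_report(g: nx.Graph, scope: str, seed: int,
                  assort_attrs: tuple[str, ...]) -> MetricsReport:
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return MetricsReport(scope, 0, 0, 0, 0, 0.0, 0.0, float("nan"),
                             float("nan"), 0)
    mc = maximum_component(g)
    comp_part = [set(c) for c in nx.connected_components(g)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        q_comp = modularity(g, comp_part) if m else float("nan")
    _, q_lc = louvain_lc_modularity(g, seed=seed)
    assort = {}
    for attr in assort_attrs:
        labels = nx.get_node_attributes(g, attr)
        if len(labels) == n:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assort[attr] = assortativity_nominal(g, labels, attr)
    keys = key_nodes(g)
    return MetricsReport(
        scope=scope,
        n_nodes=n,
        n_edges=m,
        max_component_size=mc.number_of_nodes(),
        diameter=diameter(mc),
        avg_path_length=average_path_length(mc),
        transitivity=transitivity(g),
        modularity=q_comp,
        lc_modularity=q_lc,
        n_key_nodes=len(keys),
        key_nodes=keys,
        assortativity=assort,
        degrees={str(v): int(d) for v, d in g.degree()},
    )


def report(net, seed: int = 0,
           assort_attrs: tuple[str, ...] = ("group",)) -> list[MetricsReport]:
    """Three reports: whole signed graph, positive subgraph, negative subgraph."""
    return [_scope_report(net.to_networkx(scope), scope, seed, assort_attrs)
            for scope in SCOPES]


def metrics_table(reports: list[MetricsReport]) -> pd.DataFrame:
    """Property-by-scope summary table (one column per scope)."""
    rows = ("n_nodes", "n_edges", "max_component_size", "diameter",
            "avg_path_length", "transitivity", "modularity", "lc_modularity",
            "n_key_nodes")
    data = {rep.scope: [getattr(rep, r) for r in rows] for rep in reports}
    return pd.DataFrame(data, index=list(rows))
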