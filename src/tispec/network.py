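"""Confidence-weighted protein-interaction topology.

Edges carry an integrated confidence score s in (0, 1] (input scores on
the 0-1000 integer scale are divided by 1000).  The score plays a dual
role: measures that reward strong connectivity (strength, eigenvector
centrality, weighted k-shell) use s directly as the weight, while
shortest-path measures (betweenness, closeness) use the complement
1 - s as the edge length, so shortest paths are least-uncertainty paths.
Scores are clamped to <= 0.999 so path lengths stay strictly positive
(a no-op for integer inputs capped at 999).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from tispec.stats import bonferroni, mann_whitney

SCORE_CLAMP = 0.999


@dataclass
class WeightedNetwork:
    """Undirected graph whose edges hold ``score`` (s) and ``w_sp`` (1-s)."""

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(edges: list[tuple[str, str, float]]) -> WeightedNetwork:
    """Build a network from (node, node, score-in-(0,1]) triples; duplicate
    unordered pairs collapse to one edge, self-loops are dropped."""
    g = nx.Graph()
    for u, v, s in edges:
        if u == v:
            warnings.warn(f"self-loop on {u} dropped")
            continue
        s = min(float(s), SCORE_CLAMP)
        g.add_edge(u, v, score=s, w_sp=1.0 - s)
    return WeightedNetwork(g)


def load_edges(
    path, *, min_score: int | None = None, sep: str | None = None
) -> WeightedNetwork:
    """Read a STRING-style detailed links table into a weighted network.

    The file is whitespace- or tab-separated with a header row naming at
    least ``protein1``, ``protein2`` and ``combined_score`` (integer
    0-1000).  Bidirectional duplicate rows collapse to one undirected
    edge; self-loops are dropped with a warning.

    Parameters
    ----------
    min_score
        Optional threshold on the raw 0-1000 combined score; edges below
        it are skipped.  Default keeps every edge.
    """
    df = pd.read_csv(path, sep=sep or r"\s+", engine="python")
    required = {"protein1", "protein2", "combined_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"edge table missing columns: {sorted(missing)}")
    g = nx.Graph()
    for i, row in enumerate(df.itertuples(index=False)):
        raw = int(row.combined_score)
        if raw < 0 or raw > 1000:
            raise ValueError(
                f"line {i + 2}: combined_score {raw} outside 0-1000"
            )
        if min_score is not None and raw < min_score:
            continue
        u, v = str(row.protein1), str(row.protein2)
        if u == v:
            warnings.warn(f"line {i + 2}: self-loop on {u} dropped")
            continue
        s = min(raw / 1000.0, SCORE_CLAMP)
        g.add_edge(u, v, score=s, w_sp=1.0 - s)
    return WeightedNetwork(g)


def largest_component(net: WeightedNetwork) -> WeightedNetwork:
    """Node-induced subgraph of the largest connected component; size ties
    broken by smallest lexicographic node id."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    comps = list(nx.connected_components(net.graph))
    # largest first; equal sizes fall back to the smallest lexicographic id
    best = sorted(comps, key=lambda c: (-len(c), min(map(str, c))))[0]
    return WeightedNetwork(net.graph.subgraph(best).copy())


def diameter_unweighted(net: WeightedNetwork) -> int:
    """Maximum unweighted shortest-path length over node pairs; requires a
    connected graph (run on the largest component)."""
    if not nx.is_connected(net.graph):
        raise ValueError("graph is disconnected; extract the largest component")
    return nx.diameter(net.graph)


def _eigenvector_power(g: nx.Graph, tol: float, max_iter: int) -> dict:
    """Principal eigenvector of the score-weighted adjacency by power
    iteration, unit L2 norm, nonnegative orientation."""
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight="score")
    # +I keeps the principal eigenvector but makes the matrix primitive,
    # so iteration cannot oscillate on bipartite-like graphs
    a = a + np.eye(len(nodes))
    x = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
    for _ in range(max_iter):
        y = a @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            break
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    else:
        residual = float(np.linalg.norm(a @ x / np.linalg.norm(a @ x) - x))
        warnings.warn(
            f"eigenvector power iteration did not converge in {max_iter} "
            f"iterations (residual {residual:.2e})"
        )
    if x.sum() < 0:
        x = -x
    x = np.clip(x, 0.0, None)
    return dict(zip(nodes, x))


def centralities(
    net: WeightedNetwork,
    *,
    eig_tol: float = 1e-10,
    eig_max_iter: int = 10_000,
    normalized_betweenness: bool = False,
) -> pd.DataFrame:
    """All five per-node centralities under the dual weighting convention.

    Returns a DataFrame indexed by node with columns ``strength``
    (sum of incident scores), ``eigenvector``, ``betweenness``
    (least-uncertainty shortest paths, raw unordered-pair counts, tied
    paths splitting credit), ``closeness`` ((n-1)/sum of distances) and
    ``k_shell`` (weighted shell index).
    """
    g = net.graph
    if not nx.is_connected(g):
        raise ValueError("graph is disconnected; extract the largest component")
    strength = dict(g.degree(weight="score"))
    eig = _eigenvector_power(g, eig_tol, eig_max_iter)
    btw = nx.betweenness_centrality(
        g, weight="w_sp", normalized=normalized_betweenness
    )
    clo = nx.closeness_centrality(g, distance="w_sp")
    shell = weighted_kshell(net)
    nodes = list(g.nodes)
    return pd.DataFrame(
        {
            "strength": [strength[n] for n in nodes],
            "eigenvector": [eig[n] for n in nodes],
            "betweenness": [btw[n] for n in nodes],
            "closeness": [clo[n] for n in nodes],
            "k_shell": [shell[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def _weighted_degree(g: nx.Graph) -> dict:
    """Geometric blend of connectivity and confidence: round(sqrt(k * sum s)),
    half-up rounding."""
    out = {}
    for n in g.nodes:
        k = g.degree(n)
        s = sum(d["score"] for _, _, d in g.edges(n, data=True))
        out[n] = int(np.floor(np.sqrt(k * s) + 0.5))
    return out


def weighted_kshell(net: WeightedNetwork) -> dict:
    """Weighted k-shell decomposition (shell index per node).

    Each node's weighted degree blends its connectivity and the summed
    confidence of its edges, k' = round(sqrt(degree * strength)).  At
    shell level l (starting from the minimum k'), all nodes with current
    k' <= l are removed, k' is recomputed after each removal wave and the
    cascade repeats within the level; survivors move to level l+1.  With
    unit scores this reduces exactly to the classic unweighted k-core.
    """
    g = net.graph.copy()
    if g.number_of_nodes() == 0:
        return {}
    shells: dict = {}
    kw = _weighted_degree(g)
    level = min(kw.values())
    while g.number_of_nodes() > 0:
        removed_any = True
        while removed_any:
            kw = _weighted_degree(g)
            wave = [n for n in g.nodes if kw[n] <= level]
            removed_any = bool(wave)
            for n in wave:
                shells[n] = level
            g.remove_nodes_from(wave)
        level += 1
    return shells


@dataclass
class GroupTopologyRow:
    group: str
    n: int
    median: float
    iqr: tuple[float, float]
    p: float | None
    p_adjusted: float | None


def group_topology_compare(
    table: pd.DataFrame,
    groups: dict[str, set],
    score: str,
    *,
    reference: str,
    id_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Median (IQR) of a centrality per gene group with two-tailed
    Mann-Whitney tests against a designated reference group, Bonferroni
    over the emitted family.

    Parameters
    ----------
    table
        Per-node centralities (output of :func:`centralities`).
    id_map
        Optional node-id -> gene-id mapping when the network uses protein
        identifiers.
    reference
        Name of the group in ``groups`` every other group is tested against.
    """
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not in groups")
    if id_map:
        gene_of = pd.Series(id_map)
        nodes = table.index.to_series().map(gene_of)
    else:
        nodes = table.index.to_series()
    values = table[score]

    def group_values(members: set) -> np.ndarray:
        mask = nodes.isin(members).to_numpy()
        return values.to_numpy()[mask]

    ref_vals = group_values(groups[reference])
    rows = []
    pvals = []
    for name, members in groups.items():
        vals = group_values(members)
        if vals.size == 0:
            rows.append(
                dict(group=name, n=0, median=np.nan, q1=np.nan, q3=np.nan,
                     p=np.nan)
            )
            continue
        q1, q3 = np.percentile(vals, [25, 75])
        if name == reference:
            p = np.nan
        else:
            _, p = mann_whitney(vals, ref_vals)
            pvals.append(p)
        rows.append(
            dict(group=name, n=vals.size, median=float(np.median(vals)),
                 q1=float(q1), q3=float(q3), p=p)
        )
    df = pd.DataFrame(rows)
    m = len(pvals)
    adj = dict(zip([r["group"] for r in rows if not np.isnan(r["p"])],
                   bonferroni(pvals, m=m) if m else []))
    df["p_adj"] = df["group"].map(adj)
    return df
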