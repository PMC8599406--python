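"""Protein-protein interaction networks and per-protein centrality variables.

Two undirected graphs are built from STRING-format edge lists — one for
functional (direct or indirect) and one for physical interactions — keeping
edges whose combined score is at least 0.400 (raw integer score >= 400).
Four centrality metrics per protein per network feed the feature table as the
"network_centrality" variable group: degree (neighbour count), closeness
(inverse average shortest distance within the protein's component),
betweenness (shortest-path mediation over unordered pairs) and eigenvector
centrality (principal eigenvector of the adjacency matrix).
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .feature_table import CONTINUOUS, FeatureTable

METRICS = ("degree", "closeness", "betweenness", "eigenvector")


class NetworkError(ValueError):
    """Raised for malformed edge lists or invalid centrality requests."""


@dataclass
class InteractionNetwork:
    """Undirected simple graph of protein interactions above a score threshold."""

    graph: nx.Graph
    kind: str = "functional"
    score_threshold: float = 0.400

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def load_string_edges(
    path,
    min_score: float = 0.400,
    id_prefix_strip: str | None = None,
    kind: str = "functional",
) -> InteractionNetwork:
    """Parse a STRING ``protein.links`` file into an :class:`InteractionNetwork`.

    Rows are whitespace-separated ``protein1 protein2 combined_score`` with
    integer scores 0-999 (score/1000 is the probability-like combined score).
    Edges with score/1000 >= ``min_score`` are retained (inclusive);
    reciprocal duplicates collapse to one undirected edge; an optional taxon
    prefix (e.g. ``4896.``) is stripped from identifiers.  A leading header
    line is skipped.  Self-loops are discarded.
    """
    g = nx.Graph()
    raw_threshold = min_score * 1000.0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if lineno == 1 and not _is_int(fields[-1]):
                continue  # header
            if len(fields) != 3 or not _is_int(fields[2]):
                raise NetworkError(f"{path}: malformed row at line {lineno}: {line.rstrip()!r}")
            a, b, score = fields[0], fields[1], int(fields[2])
            if id_prefix_strip:
                a = a.removeprefix(id_prefix_strip)
                b = b.removeprefix(id_prefix_strip)
            if a == b:
                continue
            if score >= raw_threshold:
                g.add_edge(a, b)
    return InteractionNetwork(g, kind=kind, score_threshold=min_score)


def _is_int(s: str) -> bool:
    try:
        int(s)
    except ValueError:
        return False
    return True


# ---------------------------------------------------------------------------
# centrality metrics


def compute_centrality(net: InteractionNetwork, metric: str) -> dict:
    """Map node -> centrality for one of degree/closeness/betweenness/eigenvector.

    Definitions (unweighted graph):

    - degree: number of direct neighbours, unnormalized.
    - closeness(v): (r-1) / sum of shortest distances to the r-1 other nodes
      of v's connected component (0 for an isolated node).
    - betweenness(v): sum over unordered pairs s,t (both != v) of the fraction
      of shortest s-t paths passing through v.
    - eigenvector: principal eigenvector of the whole-graph adjacency matrix,
      non-negative, scaled so its maximum entry is 1.
    """
    if metric not in METRICS:
        raise NetworkError(f"unknown centrality metric {metric!r}; choose from {METRICS}")
    g = net.graph
    nodes = list(g.nodes)
    if not nodes:
        if metric == "eigenvector":
            raise NetworkError("eigenvector centrality undefined for an empty network")
        return {}
    if metric == "degree":
        return {n: float(d) for n, d in g.degree()}
    if metric == "eigenvector":
        return _eigenvector_centrality(g, nodes)
    # closeness and betweenness go through igraph's C shortest-path machinery;
    # the definitions above match its unnormalized undirected conventions.
    h = _to_igraph(g, nodes)
    if metric == "betweenness":
        vals = h.betweenness(directed=False)
        return {n: float(v) for n, v in zip(nodes, vals)}
    # closeness via the full distance matrix: robust to disconnected graphs
    dist = np.asarray(h.distances(), dtype=float)
    finite = np.isfinite(dist)
    r = finite.sum(axis=1)  # component size, self included
    total = np.where(finite, dist, 0.0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        clo = np.where(total > 0, (r - 1) / total, 0.0)
    return {n: float(c) for n, c in zip(nodes, clo)}


def _to_igraph(g: nx.Graph, nodes: list) -> ig.Graph:
    index = {n: i for i, n in enumerate(nodes)}
    return ig.Graph(n=len(nodes), edges=[(index[u], index[v]) for u, v in g.edges])


def _eigenvector_centrality(
    g: nx.Graph, nodes: list, tol: float = 1e-12, max_iter: int = 5000
) -> dict:
    """Power iteration from the all-ones vector, max-entry normalised to 1.

    Iterates on A + I rather than A: the spectral shift leaves eigenvectors
    unchanged but makes the leading eigenvalue strictly dominant on bipartite
    graphs (where +/- lambda_max would otherwise cycle).
    """
    a = nx.to_scipy_sparse_array(g, nodelist=nodes, dtype=float, format="csr")
    x = np.ones(len(nodes))
    for _ in range(max_iter):
        y = x + a @ x
        y /= y.max()
        if np.abs(y - x).max() < tol:
            x = y
            break
        x = y
    return {n: float(v) for n, v in zip(nodes, x)}


# ---------------------------------------------------------------------------
# feature-table integration

CENTRALITY_GROUP = "network_centrality"


def centrality_profile(
    functional: InteractionNetwork,
    physical: InteractionNetwork,
    gene_ids,
) -> pd.DataFrame:
    """Per-gene table of the 8 centrality variables plus network presence flags.

    Genes absent from a network get 0 for its four metrics and a False flag —
    absence of interaction evidence is treated as informative rather than
    missing; the flags let users audit that convention.
    """
    gene_ids = list(gene_ids)
    out = pd.DataFrame(index=pd.Index(gene_ids, name="gene"))
    any_match = {}
    for net, label in ((functional, "functional"), (physical, "physical")):
        present = [g for g in gene_ids if net.graph.has_node(g)]
        any_match[label] = len(present)
        for metric in METRICS:
            name = f"{label}_{metric}" if metric != "eigenvector" else f"{label}_eigencentrality"
            if net.graph.number_of_nodes() == 0:
                out[name] = 0.0
                continue
            cent = compute_centrality(net, metric)
            out[name] = [cent.get(g, 0.0) for g in gene_ids]
        out[f"in_{label}"] = [g in net.graph for g in gene_ids]
    if any_match["functional"] == 0 and any_match["physical"] == 0:
        raise NetworkError(
            "no genes match either network; likely an identifier scheme mismatch "
            "(check taxon prefixes)"
        )
    return out


def add_centrality_features(
    table: FeatureTable,
    functional: InteractionNetwork,
    physical: InteractionNetwork,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Append the 8 centrality variables to ``table`` under group "network_centrality".

    Returns the augmented table and the full profile (including presence
    flags, which are not added as predictors).
    """
    profile = centrality_profile(functional, physical, table.gene_ids)
    out = table.copy()
    metric_cols = [c for c in profile.columns if not c.startswith("in_")]
    for c in metric_cols:
        out.values[c] = profile[c].to_numpy(dtype=float)
        out.variable_group[c] = CENTRALITY_GROUP
        out.variable_kind[c] = CONTINUOUS
    out.validate()
    return out, profile
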