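"""Bibliometric networks over the primary studies of a meta-analysis.

Networks are built from binary incidence matrices: co-authorship from the
product Author x Paper times Paper x Author (edge weight = number of
jointly authored papers) and bibliographic coupling from Paper x CitedPaper
times CitedPaper x Paper (edge weight = number of shared cited
references).  Country-level coupling aggregates the paper-level network
over affiliation countries.  Weights are integer counts end-to-end; any
scaling is the renderer's concern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import BibRecord, ConfigurationError

log = logging.getLogger("evimap")


@dataclass
class IncidenceMatrix:
    """Binary papers x entities matrix (entities: authors, countries or refs)."""

    rows: list[str]
    cols: list[str]
    values: np.ndarray
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.rows, columns=self.cols)


@dataclass
class WeightedNetwork:
    """Symmetric integer-weighted graph with per-node attributes.

    The diagonal of the defining matrix product (papers per author,
    references per paper, within-country coupling) is stored in
    ``node_attrs`` rather than as self-loops.
    """

    labels: list[str]
    weights: np.ndarray
    kind: str
    node_attrs: dict[str, dict] = field(default_factory=dict)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for i, lab in enumerate(self.labels):
            g.add_node(lab, **{k: v.get(lab) for k, v in self.node_attrs.items()})
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                w = int(self.weights[i, j])
                if w > 0:
                    g.add_edge(self.labels[i], self.labels[j], weight=w)
        return g

    def edge_list(self) -> pd.DataFrame:
        rows = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                w = int(self.weights[i, j])
                if w > 0:
                    rows.append({"from": self.labels[i], "to": self.labels[j], "weight": w})
        return pd.DataFrame(rows, columns=["from", "to", "weight"])


def build_incidence(records: list[BibRecord], mode: str) -> IncidenceMatrix:
    """Binary paper x entity incidence; entities in first-appearance order."""
    getters = {
        "author": lambda r: r.authors,
        "country": lambda r: r.countries,
        "reference": lambda r: r.references,
    }
    if mode not in getters:
        raise ConfigurationError(f"unknown incidence mode {mode!r}")
    get = getters[mode]
    cols: list[str] = []
    for r in records:
        for ent in get(r):
            if ent not in cols:
                cols.append(ent)
    if not cols:
        raise ConfigurationError(f"no usable entities for mode {mode!r}")
    rows = [r.paper_id for r in records]
    values = np.zeros((len(rows), len(cols)), dtype=int)
    index = {c: i for i, c in enumerate(cols)}
    for i, r in enumerate(records):
        for ent in get(r):
            values[i, index[ent]] = 1
    return IncidenceMatrix(rows=rows, cols=cols, values=values, mode=mode)


def coauthorship_network(m: IncidenceMatrix) -> WeightedNetwork:
    """Co-authorship weights from the Author x Paper · Paper x Author product."""
    if m.mode != "author":
        raise ConfigurationError("coauthorship_network needs an author-mode incidence")
    prod = m.values.T @ m.values  # authors x authors
    papers_per_author = {a: int(prod[i, i]) for i, a in enumerate(m.cols)}
    weights = prod.copy()
    np.fill_diagonal(weights, 0)
    return WeightedNetwork(
        labels=list(m.cols),
        weights=weights,
        kind="coauthorship",
        node_attrs={"papers": papers_per_author},
    )


def coupling_network(c: IncidenceMatrix) -> WeightedNetwork:
    """Paper-level bibliographic coupling from Paper x CitedPaper · its transpose."""
    if c.mode != "reference":
        raise ConfigurationError("coupling_network needs a reference-mode incidence")
    prod = c.values @ c.values.T  # papers x papers
    refs_per_paper = {p: int(prod[i, i]) for i, p in enumerate(c.rows)}
    weights = prod.copy()
    np.fill_diagonal(weights, 0)
    return WeightedNetwork(
        labels=list(c.rows),
        weights=weights,
        kind="coupling_paper",
        node_attrs={"n_references": refs_per_paper},
    )


def aggregate_country_coupling(
    paper_net: WeightedNetwork,
    records: list[BibRecord],
    first_country_only: bool = False,
) -> WeightedNetwork:
    """Country-level coupling: sum paper-pair coupling over country pairs.

    Two countries are coupled when the cumulative bibliographies of their
    papers share cited references; the weight sums the shared-reference
    counts over all cross-country paper pairs.  A multi-country paper
    contributes to every listed country unless ``first_country_only``.
    Within-country coupling is kept as a node attribute, not an edge.
    """
    if paper_net.kind != "coupling_paper":
        raise ConfigurationError("expects a paper-level coupling network")
    countries_of: dict[str, list[str]] = {}
    skipped = 0
    for r in records:
        cs = r.countries[:1] if first_country_only else list(r.countries)
        if not cs:
            skipped += 1
            continue
        countries_of[r.paper_id] = cs
    if skipped:
        log.warning("%d papers without country excluded from country coupling", skipped)
    labels: list[str] = []
    for r in records:
        for c in countries_of.get(r.paper_id, []):
            if c not in labels:
                labels.append(c)
    idx = {c: i for i, c in enumerate(labels)}
    n = len(labels)
    weights = np.zeros((n, n), dtype=int)
    self_coupling = {c: 0 for c in labels}
    papers = paper_net.labels
    for a in range(len(papers)):
        for b in range(a + 1, len(papers)):
            w = int(paper_net.weights[a, b])
            if w == 0:
                continue
            for cx in countries_of.get(papers[a], []):
                for cy in countries_of.get(papers[b], []):
                    if cx == cy:
                        self_coupling[cx] += w
                    else:
                        weights[idx[cx], idx[cy]] += w
                        weights[idx[cy], idx[cx]] += w
    return WeightedNetwork(
        labels=labels,
        weights=weights,
        kind="coupling_country",
        node_attrs={"self_coupling": self_coupling},
    )


def degree_centrality(net: WeightedNetwork, weighted: bool = False) -> dict[str, float]:
    """Unweighted: neighbor count / (n-1).  Weighted: strength (sum of weights)."""
    n = len(net.labels)
    if weighted:
        return {lab: float(net.weights[i].sum()) for i, lab in enumerate(net.labels)}
    if n <= 1:
        return {lab: 0.0 for lab in net.labels}
    return {
        lab: float((net.weights[i] > 0).sum()) / (n - 1)
        for i, lab in enumerate(net.labels)
    }


def author_clusters(
    net: WeightedNetwork, method: str = "components", seed: int = 0
) -> tuple[dict[str, int], dict]:
    """Partition a co-authorship network into clusters (research groups).

    ``components`` (default) uses connected components — deterministic and
    parameter-free; ``louvain`` uses modularity communities with a fixed
    seed.  Cluster ids are assigned by decreasing size, ties broken by the
    lexicographically smallest member label.  Returns (label -> cluster id,
    summary with n_clusters / mean_size / max_size / method / seed).
    """
    g = net.to_graph()
    if method == "components":
        groups = [sorted(c) for c in nx.connected_components(g)]
    elif method == "louvain":
        groups = [
            sorted(c)
            for c in nx.community.louvain_communities(g, weight="weight", seed=seed)
        ]
    else:
        raise ConfigurationError(f"unknown clustering method {method!r}")
    groups.sort(key=lambda c: (-len(c), c[0]))
    partition = {lab: i for i, group in enumerate(groups) for lab in group}
    sizes = [len(g_) for g_ in groups]
    summary = {
        "n_clusters": len(groups),
        "mean_size": float(np.mean(sizes)) if sizes else 0.0,
        "max_size": max(sizes) if sizes else 0,
        "method": method,
        "seed": seed if method == "louvain" else None,
    }
    return partition, summary


def chord_data(net: WeightedNetwork) -> tuple[pd.DataFrame, dict[str, float]]:
    """Chord-diagram inputs: edge list by descending weight + node strengths.

    Node totals are the row sums of the weight matrix; a chord renderer
    shows them as shares of the circle's perimeter.
    """
    edges = net.edge_list().sort_values(
        ["weight", "from", "to"], ascending=[False, True, True]
    ).reset_index(drop=True)
    totals = degree_centrality(net, weighted=True)
    return edges, totals


def to_graphml(net: WeightedNetwork, path) -> None:
    g = net.to_graph()
    for node, data in g.nodes(data=True):
        for k in list(data):
            if data[k] is None:
                del data[k]
    nx.write_graphml(g, path)
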