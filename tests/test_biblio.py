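"""Bibliometric networks: incidence products vs brute-force set counting."""

import numpy as np
import pytest

from evimap.biblio import (
    aggregate_country_coupling,
    author_clusters,
    build_incidence,
    chord_data,
    coauthorship_network,
    coupling_network,
    degree_centrality,
)
from evimap.datamodel import BibRecord, ConfigurationError


def _records(papers: dict[str, dict]) -> list[BibRecord]:
    return [
        BibRecord(pid, authors=spec.get("authors", ["x y"]),
                  countries=spec.get("countries", []),
                  references=spec.get("refs", []))
        for pid, spec in papers.items()
    ]


class TestIncidence:
    def test_direct_construction(self):
        recs = _records({"P1": {"authors": ["a", "b"]}, "P2": {"authors": ["b"]}})
        m = build_incidence(recs, "author")
        assert m.cols == ["a", "b"]
        assert m.values.tolist() == [[1, 1], [0, 1]]

    def test_duplicate_entity_binarized(self):
        recs = [BibRecord("P1", authors=["a", "a", "b"])]
        m = build_incidence(recs, "author")
        assert m.values.max() == 1

    def test_empty_mode_rejected(self):
        recs = _records({"P1": {}, "P2": {}})
        with pytest.raises(ConfigurationError, match="reference"):
            build_incidence(recs, "reference")


class TestCoauthorship:
    def test_pair_counting_oracle(self):
        recs = _records({
            "P1": {"authors": ["A", "B", "C"]},
            "P2": {"authors": ["B", "C"]},
            "P3": {"authors": ["C"]},
        })
        net = coauthorship_network(build_incidence(recs, "author"))
        w = net.to_graph()
        assert w["A"]["B"]["weight"] == 1
        assert w["A"]["C"]["weight"] == 1
        assert w["B"]["C"]["weight"] == 2
        assert net.node_attrs["papers"] == {"A": 1, "B": 2, "C": 3}

    def test_single_author_corpus_edgeless(self):
        recs = _records({f"P{i}": {"authors": ["solo x"]} for i in range(3)})
        net = coauthorship_network(build_incidence(recs, "author"))
        assert net.weights.sum() == 0
        assert net.node_attrs["papers"]["solo x"] == 3

    def test_intersection_bound(self, rng):
        recs = _random_corpus(rng, 15)
        net = coauthorship_network(build_incidence(recs, "author"))
        papers = net.node_attrs["papers"]
        for i, a in enumerate(net.labels):
            for j, b in enumerate(net.labels):
                if i < j:
                    assert net.weights[i, j] <= min(papers[a], papers[b])


class TestCoupling:
    def test_shared_reference_oracle(self):
        recs = _records({
            "P1": {"refs": ["r1", "r2", "r3"]},
            "P2": {"refs": ["r2", "r3"]},
            "P3": {"refs": ["r4"]},
        })
        net = coupling_network(build_incidence(recs, "reference"))
        g = net.to_graph()
        assert g["P1"]["P2"]["weight"] == 2
        assert not g.has_edge("P1", "P3")
        assert net.node_attrs["n_references"]["P1"] == 3

    def test_identical_lists_full_overlap(self):
        recs = _records({"P1": {"refs": ["r1", "r2"]}, "P2": {"refs": ["r1", "r2"]}})
        net = coupling_network(build_incidence(recs, "reference"))
        assert net.to_graph()["P1"]["P2"]["weight"] == 2

    def test_disjoint_lists_zero(self):
        recs = _records({"P1": {"refs": ["r1"]}, "P2": {"refs": ["r2"]}})
        net = coupling_network(build_incidence(recs, "reference"))
        assert net.weights.sum() == 0


class TestCountryCoupling:
    def test_enumeration_oracle(self):
        recs = _records({
            "P1": {"refs": ["r1", "r2"], "countries": ["US"]},
            "P2": {"refs": ["r1", "r2"], "countries": ["GB"]},
            "P3": {"refs": ["r9"], "countries": ["GB"]},
        })
        paper_net = coupling_network(build_incidence(recs, "reference"))
        net = aggregate_country_coupling(paper_net, recs)
        g = net.to_graph()
        assert g["US"]["GB"]["weight"] == 2

    def test_single_country_self_coupling(self):
        recs = _records({
            "P1": {"refs": ["r1"], "countries": ["US"]},
            "P2": {"refs": ["r1"], "countries": ["US"]},
        })
        paper_net = coupling_network(build_incidence(recs, "reference"))
        net = aggregate_country_coupling(paper_net, recs)
        assert net.weights.sum() == 0
        assert net.node_attrs["self_coupling"]["US"] == 1

    def test_symmetry_and_mass_conservation(self, rng):
        recs = _random_corpus(rng, 12, single_country=True)
        paper_net = coupling_network(build_incidence(recs, "reference"))
        net = aggregate_country_coupling(paper_net, recs)
        assert np.array_equal(net.weights, net.weights.T)
        total = net.weights[np.triu_indices(len(net.labels), 1)].sum() + sum(
            net.node_attrs["self_coupling"].values()
        )
        n = len(paper_net.labels)
        paper_total = paper_net.weights[np.triu_indices(n, 1)].sum()
        assert total == paper_total


class TestCentralityClustersChord:
    def test_triangle_centrality(self):
        recs = _records({"P1": {"authors": ["a", "b", "c"]}})
        net = coauthorship_network(build_incidence(recs, "author"))
        assert degree_centrality(net) == {"a": 1.0, "b": 1.0, "c": 1.0}
        assert degree_centrality(net, weighted=True) == {"a": 2.0, "b": 2.0, "c": 2.0}

    def test_star_centrality(self):
        recs = _records({
            "P1": {"authors": ["hub", "l1"]},
            "P2": {"authors": ["hub", "l2"]},
            "P3": {"authors": ["hub", "l3"]},
        })
        net = coauthorship_network(build_incidence(recs, "author"))
        cent = degree_centrality(net)
        assert cent["hub"] == 1.0
        assert cent["l1"] == pytest.approx(1 / 3)

    def test_components_match_flood_fill(self, rng):
        recs = _random_corpus(rng, 20)
        net = coauthorship_network(build_incidence(recs, "author"))
        partition, summary = author_clusters(net, method="components")
        oracle = _flood_fill(net)
        mine = {}
        for lab, cid in partition.items():
            mine.setdefault(cid, set()).add(lab)
        assert sorted(map(sorted, mine.values())) == sorted(map(sorted, oracle))
        assert summary["n_clusters"] == len(oracle)

    def test_two_triangles(self):
        recs = _records({
            "P1": {"authors": ["a", "b", "c"]},
            "P2": {"authors": ["d", "e", "f"]},
        })
        net = coauthorship_network(build_incidence(recs, "author"))
        _, summary = author_clusters(net)
        assert summary == {"n_clusters": 2, "mean_size": 3.0, "max_size": 3,
                           "method": "components", "seed": None}

    def test_edgeless_network_singletons(self):
        recs = _records({f"P{i}": {"authors": [f"a{i}"]} for i in range(5)})
        net = coauthorship_network(build_incidence(recs, "author"))
        _, summary = author_clusters(net)
        assert summary["n_clusters"] == 5

    def test_louvain_deterministic_with_seed(self):
        recs = _records({
            "P1": {"authors": ["a", "b", "c"]},
            "P2": {"authors": ["c", "d"]},
            "P3": {"authors": ["d", "e", "f"]},
        })
        net = coauthorship_network(build_incidence(recs, "author"))
        p1, _ = author_clusters(net, method="louvain", seed=7)
        p2, _ = author_clusters(net, method="louvain", seed=7)
        assert p1 == p2

    def test_chord_totals_equal_row_sums(self):
        recs = _records({
            "P1": {"refs": ["r1", "r2"], "countries": ["US"]},
            "P2": {"refs": ["r1", "r2"], "countries": ["GB"]},
            "P3": {"refs": ["r1"], "countries": ["DE"]},
        })
        net = aggregate_country_coupling(
            coupling_network(build_incidence(recs, "reference")), recs
        )
        edges, totals = chord_data(net)
        for i, lab in enumerate(net.labels):
            assert totals[lab] == net.weights[i].sum()
        assert list(edges["weight"]) == sorted(edges["weight"], reverse=True)


def _random_corpus(rng, n_papers, single_country=False):
    authors = [f"au{i}" for i in range(12)]
    refs = [f"r{i}" for i in range(15)]
    countries = ["US", "GB", "DE"]
    recs = []
    for p in range(n_papers):
        k = int(rng.integers(1, 5))
        recs.append(
            BibRecord(
                f"P{p}",
                authors=[str(a) for a in rng.choice(authors, size=k, replace=False)],
                countries=[str(rng.choice(countries))] if single_country else [],
                references=[str(r) for r in
                            rng.choice(refs, size=int(rng.integers(0, 6)), replace=False)],
            )
        )
    return recs


def _flood_fill(net):
    adj = {lab: set() for lab in net.labels}
    n = len(net.labels)
    for i in range(n):
        for j in range(n):
            if i != j and net.weights[i, j] > 0:
                adj[net.labels[i]].add(net.labels[j])
    seen, groups = set(), []
    for lab in net.labels:
        if lab in seen:
            continue
        stack, comp = [lab], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        groups.append(comp)
    return groups
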