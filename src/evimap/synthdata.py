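"""Seeded synthetic evidence bases with known ground truth.

Generates everything the toolkit consumes — effect tables with raw
two-group outcomes, species trees, clustered bibliographies and altmetric
fixtures — so every pipeline can be exercised and validated without any
external download.  One integer seed drives one named pseudo-random
stream per generator, so adding a generator never perturbs the fixtures
of another.

The generative model mirrors the statistical structure the summaries
assume: study-level true effects ``theta_s ~ Normal(mu_cell, tau2)``;
per-effect raw outcomes drawn as control ~ Normal(0, 1) and treatment ~
Normal(theta_s, 1), so Hedges' g recovers ``theta_s`` in expectation;
authors partitioned into disjoint clusters with papers authored within
exactly one cluster (true co-authorship components equal the declared
clusters); cited references reused within clusters at a configurable
rate; log-normal attention scores and Poisson policy/patent counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import BibRecord, Dataset, EffectRecord, RawOutcome
from .meta import hedges_g
from .phylo import grafen_lengths, parse_newick, brownian_corr

_STREAMS = {"effects": 1, "tree": 2, "biblio": 3, "altmetrics": 4}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic evidence base.

    Defaults describe a mid-sized meta-analysis: 30 studies contributing
    1–3 effects each, group sizes of 20–40 per arm, a global mean effect
    of 0.5 on the standardized scale with no between-study heterogeneity,
    three research groups and a modest shared-reference rate.
    """

    seed: int = 0
    n_studies: int = 30
    effects_per_study: tuple[int, int] = (1, 3)
    group_size: tuple[int, int] = (20, 40)
    true_mu: float = 0.5
    tau2: float = 0.0
    rho_true: float = 0.0
    moderators: dict[str, list[str]] = field(
        default_factory=lambda: {
            "intervention": ["CM", "PSM", "SSM"],
            "outcome": ["QoL", "AQLQ"],
        }
    )
    cell_means: dict[str, dict[str, float]] = field(default_factory=dict)
    n_species: int = 0
    tree_signal: str = "none"  # {none, brownian}
    species_sigma: float = 0.3
    n_author_clusters: int = 3
    authors_per_cluster: tuple[int, int] = (4, 8)
    authors_per_paper: tuple[int, int] = (2, 4)
    refs_pool_size: int = 40
    refs_per_paper: tuple[int, int] = (5, 10)
    shared_ref_rate: float = 0.5
    country_dominance: float = 0.8
    countries: tuple[str, ...] = ("US", "GB", "DE", "AU", "JP", "CN")
    score_lognorm: tuple[float, float] = (2.0, 1.0)  # (mean, sd) of log score
    policy_rate: float = 1.0
    patent_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be positive")
        if not 0.0 <= self.shared_ref_rate <= 1.0:
            raise ValueError("shared_ref_rate must be in [0, 1]")
        if not 0.0 <= self.rho_true < 1.0:
            raise ValueError("rho_true must be in [0, 1)")
        if self.tree_signal not in ("none", "brownian"):
            raise ValueError(f"unknown tree_signal {self.tree_signal!r}")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


def gen_tree(n_species: int, seed: int = 0) -> str:
    """Random rooted binary topology as Newick (labels sp1..spN, no lengths).

    Built by random sequential joins of subtrees, giving n-1 internal
    nodes; deterministic for a fixed seed.
    """
    if n_species < 2:
        raise ValueError("need >= 2 species for a tree")
    rng = np.random.default_rng([int(seed), _STREAMS["tree"]])
    subtrees = [f"sp{i + 1}" for i in range(n_species)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        merged = f"({subtrees[i]},{subtrees[j]})"
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)]
        subtrees.append(merged)
    return subtrees[0] + ";"


def gen_effects(config: SynthConfig) -> tuple[Dataset, dict]:
    """Synthetic effect table; returns (dataset, truth) with the generating values.

    Raw two-group outcomes are always generated so Hedges' g is exercised
    end-to-end; yi/vi are filled from them.  When ``n_species > 0`` each
    study is assigned a species; with ``tree_signal="brownian"`` the
    species add correlated deviations drawn along a generated tree.
    """
    rng = config.rng("effects")
    mods = config.moderators
    for name, levels in mods.items():
        if name in config.cell_means:
            missing = set(levels) - set(config.cell_means[name])
            if missing:
                raise ValueError(f"cell_means for {name!r} missing levels {sorted(missing)}")
    truth: dict = {"mu": config.true_mu, "tau2": config.tau2, "theta": {}}
    newick = None
    species_dev = {}
    species_names: list[str] = []
    if config.n_species > 0:
        newick = gen_tree(config.n_species, config.seed)
        ptree = grafen_lengths(parse_newick(newick), power=1.0)
        species_names = ptree.tip_labels
        if config.tree_signal == "brownian":
            corr = brownian_corr(ptree).values
            dev = rng.multivariate_normal(
                np.zeros(len(species_names)), config.species_sigma**2 * corr
            )
        else:
            dev = np.zeros(len(species_names))
        species_dev = dict(zip(species_names, dev))
        truth["species_deviation"] = species_dev
        truth["newick"] = newick
    effects: list[EffectRecord] = []
    for s in range(config.n_studies):
        sid = f"study{s + 1:03d}"
        labels = {
            name: levels[rng.integers(len(levels))] for name, levels in mods.items()
        }
        mu_cell = config.true_mu
        for name, lab in labels.items():
            mu_cell += config.cell_means.get(name, {}).get(lab, 0.0)
        species = None
        if species_names:
            species = species_names[s % len(species_names)]
            mu_cell += species_dev[species]
        theta = mu_cell + rng.normal(0.0, np.sqrt(config.tau2)) if config.tau2 > 0 else mu_cell
        truth["theta"][sid] = theta
        k = int(rng.integers(config.effects_per_study[0], config.effects_per_study[1] + 1))
        for e in range(k):
            n1 = int(rng.integers(config.group_size[0], config.group_size[1] + 1))
            n2 = int(rng.integers(config.group_size[0], config.group_size[1] + 1))
            treat = rng.normal(theta, 1.0, size=n1)
            ctrl = rng.normal(0.0, 1.0, size=n2)
            raw = RawOutcome(
                m1=float(treat.mean()), m2=float(ctrl.mean()),
                s1=float(treat.std(ddof=1)), s2=float(ctrl.std(ddof=1)),
                n1=n1, n2=n2,
            )
            yi, vi = hedges_g(raw)
            effects.append(
                EffectRecord(
                    study_id=sid,
                    effect_id=f"{sid}_e{e + 1}",
                    yi=yi,
                    vi=vi,
                    species=species,
                    moderators=dict(labels),
                    raw=raw,
                )
            )
    schema = {name: list(levels) for name, levels in mods.items()}
    dataset = Dataset(effects=effects, moderator_schema=schema)
    return dataset, truth


def gen_bibliography(config: SynthConfig, dataset: Dataset) -> list[BibRecord]:
    """Clustered bibliography: each paper authored within one author cluster.

    Clusters are disjoint by construction, so connected-components
    clustering of the co-authorship network recovers them exactly.  Each
    cluster holds a preferred reference subpool reused at rate
    ``shared_ref_rate`` (driving within-cluster bibliographic coupling)
    and a home country assigned with probability ``country_dominance``.
    """
    rng = config.rng("biblio")
    n_cl = config.n_author_clusters
    lo, hi = config.authors_per_cluster
    pools: list[list[str]] = []
    a = 0
    for c in range(n_cl):
        size = int(rng.integers(lo, hi + 1))
        pools.append([f"author{a + i + 1:03d}" for i in range(size)])
        a += size
    if any(len(p) < config.authors_per_paper[0] for p in pools):
        raise ValueError(
            "authors_per_cluster too small for authors_per_paper; infeasible config"
        )
    ref_subpools = np.array_split(np.arange(config.refs_pool_size), n_cl)
    home = [config.countries[c % len(config.countries)] for c in range(n_cl)]
    records = []
    fresh_ref = config.refs_pool_size
    for i, sid in enumerate(dataset.study_ids):
        c = i % n_cl  # round-robin keeps every cluster populated
        k = int(rng.integers(config.authors_per_paper[0],
                             min(config.authors_per_paper[1], len(pools[c])) + 1))
        authors = [str(x) for x in rng.choice(pools[c], size=k, replace=False)]
        n_refs = int(rng.integers(config.refs_per_paper[0], config.refs_per_paper[1] + 1))
        refs = []
        for _ in range(n_refs):
            if rng.random() < config.shared_ref_rate and len(ref_subpools[c]):
                refs.append(f"ref{int(rng.choice(ref_subpools[c])):04d}")
            else:
                refs.append(f"ref{fresh_ref:04d}")
                fresh_ref += 1
        country = home[c] if rng.random() < config.country_dominance else str(
            rng.choice([x for x in config.countries if x != home[c]])
        )
        records.append(
            BibRecord(
                paper_id=sid,
                authors=sorted(set(authors)),
                year=int(2000 + rng.integers(0, 25)),
                journal=f"Journal {c + 1}",
                doi=f"10.5555/{sid}",
                countries=[country],
                references=sorted(set(refs)),
            )
        )
        for e in dataset.effects:
            if e.study_id == sid:
                e.author_cluster = f"cluster{c + 1}"
    return records


def gen_altmetric_fixture(dataset: Dataset, config: SynthConfig) -> pd.DataFrame:
    """Altmetric fixture covering every DOI in the dataset's bibliography."""
    rng = config.rng("altmetrics")
    mu, sd = config.score_lognorm
    rows = []
    for b in dataset.bibliography:
        if not b.doi:
            continue
        rows.append(
            {
                "doi": b.doi,
                "score": float(np.round(rng.lognormal(mu, sd), 2)),
                "policy_citations": int(rng.poisson(config.policy_rate)),
                "patent_citations": int(rng.poisson(config.patent_rate)),
            }
        )
    return pd.DataFrame(rows, columns=["doi", "score", "policy_citations", "patent_citations"])


def gen_evidence_base(config: SynthConfig) -> tuple[Dataset, dict]:
    """Full synthetic evidence base: effects + bibliography (+ tree in truth)."""
    dataset, truth = gen_effects(config)
    dataset.bibliography = gen_bibliography(config, dataset)
    truth["altmetric_fixture"] = gen_altmetric_fixture(dataset, config)
    return dataset, truth
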