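"""Phylogenetic scaffolding for species-level forest displays.

Branch lengths are rarely available for the species sets appearing in a
meta-analysis, so they are approximated with Grafen's method: each node's
height is proportional to its number of descendant tips minus one,
normalized so tips sit at 0 and the root at 1, and optionally raised to a
power.  Under a Brownian-motion model of trait evolution the expected
correlation between two species is then the root-to-MRCA depth, which is
``1 - height(MRCA)`` after normalization.

Per-species mean effects are pooled with the same fixed-effect GLS
machinery as the rest of the toolkit, on a within-species sampling VCV
with an assumed correlation rho (default 0.5), and Wald-type 95% CIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .datamodel import ConfigurationError, Dataset
from .meta import ParameterError, build_vcv, fill_effect_sizes, pool_effects

log = logging.getLogger("evimap")


@dataclass
class PhyloTree:
    """Rooted tree with Grafen-scaled node heights.

    ``heights`` maps each node to its scaled height in [0, 1] (tips at 0,
    root at 1); branch lengths on the underlying dendropy tree are parent
    height minus child height, so the tree is ultrametric by construction.
    """

    tree: dendropy.Tree
    power: float | None = None

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class CorrelationMatrix:
    labels: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a rooted tree (input branch lengths ignored)."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    if len(labels) < 1:
        raise ValueError("tree has no labeled tips")
    tree.is_rooted = True
    return PhyloTree(tree=tree)


def grafen_lengths(ptree: PhyloTree, power: float = 1.0) -> PhyloTree:
    """Assign Grafen heights and branch lengths in place.

    Raw height of node u is ``(tips(u) - 1) / (tips(root) - 1)``; heights
    are raised to ``power`` and branch length is the parent–child height
    difference.
    """
    if power <= 0:
        raise ParameterError(f"Grafen power must be > 0, got {power}")
    tree = ptree.tree
    n_tips = len(tree.leaf_nodes())
    if n_tips < 2:
        raise ValueError("Grafen scaling needs >= 2 tips")
    for node in tree.postorder_node_iter():
        k = len(node.leaf_nodes()) if not node.is_leaf() else 1
        raw = (k - 1) / (n_tips - 1)
        node.grafen_height = raw**power if raw > 0 else 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.grafen_height - node.grafen_height
    ptree.power = power
    return ptree


def brownian_corr(ptree: PhyloTree) -> CorrelationMatrix:
    """Expected Brownian trait correlation: root-to-MRCA depth per species pair.

    After Grafen normalization every tip has depth 1, so the matrix has a
    unit diagonal and off-diagonal entries ``1 - height(MRCA)``; it is
    positive semidefinite by construction.
    """
    tree = ptree.tree
    if ptree.power is None:
        raise ValueError("assign branch lengths first (grafen_lengths)")
    labels = ptree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    corr = np.eye(n)
    # For each internal node, tip pairs split across different children
    # have that node as their MRCA; depth from root = 1 - height.
    for node in tree.postorder_internal_node_iter():
        depth = 1.0 - node.grafen_height
        child_tipsets = [
            [index[l.taxon.label] for l in child.leaf_nodes()]
            for child in node.child_nodes()
        ]
        for a in range(len(child_tipsets)):
            for b in range(a + 1, len(child_tipsets)):
                for i in child_tipsets[a]:
                    for j in child_tipsets[b]:
                        corr[i, j] = corr[j, i] = depth
    return CorrelationMatrix(labels=labels, values=corr)


def species_means(
    dataset: Dataset,
    rho: float = 0.5,
    tree: PhyloTree | None = None,
    cluster_by: str = "study_id",
) -> pd.DataFrame:
    """Per-species pooled effects with Wald 95% CIs, ordered by tree tips.

    Effects are pooled within species by fixed-effect GLS on a sampling
    VCV clustered by ``cluster_by`` at correlation ``rho``.  When a tree
    is supplied, output rows follow tip order and species present in only
    one of data/tree are reported in the ``in_tree``/``in_data`` columns.
    """
    fill_effect_sizes(dataset)
    by_species: dict[str, list] = {}
    for e in dataset.effects:
        if e.species:
            by_species.setdefault(e.species, []).append(e)
    if not by_species:
        raise ConfigurationError("no species labels present in the dataset")
    data_species = list(by_species)
    if tree is not None:
        tips = tree.tip_labels
        ordered = [s for s in tips if s in by_species] + [
            s for s in data_species if s not in tips
        ]
        only_data = [s for s in data_species if s not in tips]
        only_tree = [s for s in tips if s not in by_species]
        if only_data or only_tree:
            log.warning(
                "species mismatch: %d only in data %s, %d only in tree %s",
                len(only_data), only_data, len(only_tree), only_tree,
            )
    else:
        ordered, only_data, only_tree = data_species, [], []
        tips = []
    rows = []
    for sp in ordered:
        effs = by_species[sp]
        pooled = pool_effects(effs, method="fixed_gls", rho=rho, cluster_by=cluster_by)
        rows.append(
            {
                "species": sp,
                "k_effects": pooled.n_effects,
                "estimate": pooled.estimate,
                "se": pooled.se,
                "ci_low": pooled.ci_low,
                "ci_high": pooled.ci_high,
                "in_tree": sp in tips if tree is not None else None,
            }
        )
    return pd.DataFrame(rows)


def pool_effects_species(effects, rho: float, cluster_by: str = "study_id"):
    """Convenience: VCV-weighted mean for one species (exposed for tests)."""
    vcv = build_vcv(effects, cluster_by=cluster_by, rho=rho)
    y = np.array([e.yi for e in effects], dtype=float)
    from .meta import pool_fixed_gls

    return pool_fixed_gls(y, vcv)
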