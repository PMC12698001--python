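"""Rooted-tree utilities: Newick I/O, neighbor joining, gene-tree/species-tree
displacement detection, and crown-age divergence scaling.

Trees are represented as :class:`dendropy.Tree` objects throughout; the
helpers here add the conventions the pipeline needs (forced rooting, outgroup
rooting, duplicate-label rejection) plus the two analysis operations:

* ``displaced_taxa`` finds taxa that have moved onto a donor clade's branch
  of a gene tree — the topological signature of introgression at that locus.
* ``calibrate_node_ages`` converts relative node depths on a (possibly
  non-clock) tree into absolute ages by scaling against externally estimated
  crown ages.
"""
from __future__ import annotations

import random
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    DegenerateTreeError,
    FormatError,
    PreconditionError,
    ReferenceLookupError,
)


# ---------------------------------------------------------------------------
# Newick I/O


def parse_newick(text: str, outgroup: str | None = None) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree, optionally rooting on an
    outgroup taxon (the outgroup edge is split at its midpoint)."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise FormatError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate leaf labels in Newick input")
    if outgroup is not None:
        root_on_outgroup(tree, outgroup)
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def root_on_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Re-root ``tree`` in place so the named outgroup attaches at a child of
    the root, splitting the outgroup edge at its midpoint."""
    node = tree.find_node_with_taxon_label(outgroup)
    if node is None:
        raise ReferenceLookupError(f"outgroup {outgroup!r} not in tree")
    length = node.edge.length
    if length is None:
        tree.reroot_at_edge(node.edge)
    else:
        tree.reroot_at_edge(node.edge, length1=length / 2, length2=length / 2)
    tree.update_bipartitions(suppress_unifurcations=True)
    return tree


def leaf_labels(tree: dendropy.Tree) -> set:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


# ---------------------------------------------------------------------------
# neighbor joining (plumbing around scikit-bio's implementation)


def nj_from_distances(D, labels: Sequence[str]) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric zero-diagonal distance matrix.

    Negative branch lengths produced by the agglomeration are clamped to 0.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or D.shape[0] != len(labels):
        raise ConfigError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T):
        raise ConfigError("distance matrix is not symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ConfigError("distance matrix diagonal is not zero")
    skb = nj(DistanceMatrix(D, ids=list(labels)))
    return parse_newick(str(skb))


# ---------------------------------------------------------------------------
# discordance


def _mrca(tree: dendropy.Tree, labels: Iterable[str]):
    labels = list(labels)
    present = leaf_labels(tree)
    missing = [x for x in labels if x not in present]
    if missing:
        raise ReferenceLookupError(f"taxa not in tree: {missing}")
    return tree.mrca(taxon_labels=labels)


def is_monophyletic(tree: dendropy.Tree, labels: Iterable[str]) -> bool:
    labels = set(labels)
    node = _mrca(tree, labels)
    return {leaf.taxon.label for leaf in node.leaf_iter()} == labels


def displaced_taxa(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    donor_clade: Iterable[str],
) -> set:
    """Taxa that fall on the donor clade's branch of the gene tree.

    ``donor_clade`` must be monophyletic in the species tree.  The result is
    the leaf set of the smallest gene-tree clade containing the donor clade,
    minus the donor clade itself: taxa grafted inside the donor clade at this
    locus.  An empty set means the donor clade is itself monophyletic in the
    gene tree (no displacement).
    """
    C = set(donor_clade)
    if len(C) < 1:
        raise ConfigError("donor clade must be non-empty")
    if not is_monophyletic(species_tree, C):
        raise PreconditionError("donor clade is not monophyletic in species tree")
    node = _mrca(gene_tree, C)
    spanned = {leaf.taxon.label for leaf in node.leaf_iter()}
    return spanned - C


# ---------------------------------------------------------------------------
# divergence dating


def _mean_tip_depths(tree: dendropy.Tree) -> dict:
    """Mean path length from each node to its descendant tips."""
    stats: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            stats[node] = (1, 0.0)
        else:
            n = 0
            total = 0.0
            for ch in node.child_nodes():
                cn, ct = stats[ch]
                el = ch.edge.length or 0.0
                n += cn
                total += ct + el * cn
            stats[node] = (n, total)
    return {node: total / n for node, (n, total) in stats.items()}


def calibrate_node_ages(
    tree: dendropy.Tree,
    crown_ages: Sequence[float],
    focal_nodes: Sequence[Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Scale relative node depths to absolute ages using crown-age estimates.

    The relative depth of a node is its mean path length to descendant tips
    divided by the tree-wide mean root-to-tip path length (so the root has
    relative depth 1).  Each crown age ``T`` gives ``age = depth * T``; the
    report carries (min, mean, max) over the calibration set.  A monotonicity
    repair clamps every child's depth to its parent's, so ages never increase
    toward the tips.

    Parameters
    ----------
    crown_ages : positive root ages (e.g. in Mya), one per calibration source
    focal_nodes : optional list of leaf sets; each is resolved to its MRCA.
        Default: every internal node.

    Returns
    -------
    DataFrame with columns ``node`` (comma-joined leaf labels or count),
    ``rel_depth``, ``age_min``, ``age_mean``, ``age_max``.
    """
    ages = [float(a) for a in crown_ages]
    if not ages or any(a <= 0 for a in ages):
        raise ConfigError("crown ages must be positive and non-empty")
    depths = _mean_tip_depths(tree)
    root_depth = depths[tree.seed_node]
    if root_depth <= 0:
        raise DegenerateTreeError("mean root-to-tip path length is zero")
    rel = {node: d / root_depth for node, d in depths.items()}
    for node in tree.preorder_node_iter():  # clamp child depth to parent
        if node.parent_node is not None:
            rel[node] = min(rel[node], rel[node.parent_node])

    if focal_nodes is None:
        nodes = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    else:
        nodes = []
        for leaves in focal_nodes:
            leaves = list(leaves)
            if len(leaves) < 2:
                raise ConfigError("each focal node needs >=2 leaves")
            nodes.append(_mrca(tree, leaves))

    rows = []
    for node in nodes:
        labels = sorted(leaf.taxon.label for leaf in node.leaf_iter())
        name = ",".join(labels) if len(labels) <= 6 else f"clade_{len(labels)}_taxa"
        r = rel[node]
        node_ages = [r * t for t in ages]
        rows.append(
            {
                "node": name,
                "rel_depth": r,
                "age_min": min(node_ages),
                "age_mean": float(np.mean(node_ages)),
                "age_max": max(node_ages),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# random trees (used by the simulator and the test-suite)


def random_yule_tree(
    n_leaves: int, seed: int, birth_rate: float = 1.0
) -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``n_leaves`` extant tips, labels T1..Tn."""
    from dendropy.simulate import treesim

    if n_leaves < 2:
        raise ConfigError("need at least two leaves")
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_leaves,
        rng=random.Random(seed),
    )
    tree.is_rooted = True
    return tree
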