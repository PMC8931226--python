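"""Tree-topology disagreement via Mutual Clustering Information.

A generalized Robinson-Foulds comparison: each nontrivial split of an
unrooted tree is a two-class clustering of the leaves; a pair of splits
(one per tree) shares information equal to the mutual information of
their 2x2 joint leaf-count table (in bits). The score of a tree pair is
the maximum total shared information over injective matchings of the
two split sets (solved as a linear assignment problem), and the
normalized distance is

    d = 1 - shared / mean(H1, H2)

where H_k is tree k's total split entropy (the self-information a tree
shares with itself). Identical trees score d = 0; trees with no split
pair carrying information score d = 1. A discordance approaching the
random-tree baseline, while conserved gene families stay near the
species tree, is the classic horizontal-transfer signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import linear_sum_assignment

_SCORE_EPS = 1e-12  # pair scores below this are noise, never matched


@dataclass
class Topology:
    """Unrooted leaf-labeled topology as a set of nontrivial splits.

    Each split is a frozenset holding the smaller (or lexicographically
    first, on ties) side of the bipartition.
    """

    leaves: frozenset[str]
    splits: list[frozenset[str]] = field(default_factory=list)


@dataclass
class SplitMatch:
    pairs: list[tuple[frozenset, frozenset, float]]
    shared_info: float
    normalizer: float
    distance: float
    pruned_leaves: int = 0
    flags: list[str] = field(default_factory=list)


def _canon(side: set[str], leaves: frozenset[str]) -> frozenset[str]:
    other = leaves - side
    if len(side) < len(other):
        return frozenset(side)
    if len(other) < len(side):
        return frozenset(other)
    return frozenset(min(sorted(side), sorted(other)))


def extract_splits(newick: str) -> Topology:
    """All nontrivial bipartitions induced by internal edges.

    Rooting is ignored; polytomies simply yield fewer splits.
    Duplicate leaf labels are an error.
    """
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise ValueError(f"duplicate leaf labels: {e}") from e
    return splits_from_tree(tree)


def splits_from_tree(tree: dendropy.Tree) -> Topology:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels")
    if len(labels) < 4:
        raise ValueError("need at least 4 leaves")
    leaves = frozenset(labels)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(_canon(side, leaves))
    return Topology(leaves=leaves, splits=sorted(splits, key=sorted))


def _entropy2(k: int, n: int) -> float:
    """Entropy (bits) of a two-class split with class sizes k, n-k."""
    if k == 0 or k == n:
        return 0.0
    p = k / n
    return float(-p * np.log2(p) - (1 - p) * np.log2(1 - p))


def split_mutual_info(
    s1: frozenset[str], s2: frozenset[str], leaves: frozenset[str]
) -> float:
    """Mutual information (bits) of two splits of the same leaf set.

    Each split labels every leaf in/out; the MI of the resulting 2x2
    joint count table measures how much knowing one split's side of a
    leaf says about the other's.
    """
    n = len(leaves)
    n11 = len(s1 & s2)
    n10 = len(s1) - n11
    n01 = len(s2) - n11
    n00 = n - n11 - n10 - n01
    mi = 0.0
    for nij, ri, cj in (
        (n11, len(s1), len(s2)),
        (n10, len(s1), n - len(s2)),
        (n01, n - len(s1), len(s2)),
        (n00, n - len(s1), n - len(s2)),
    ):
        if nij > 0:
            mi += (nij / n) * np.log2(nij * n / (ri * cj))
    return float(max(mi, 0.0))


def total_split_entropy(t: Topology) -> float:
    n = len(t.leaves)
    return sum(_entropy2(len(s), n) for s in t.splits)


def mci_distance(t1: Topology, t2: Topology) -> SplitMatch:
    """Normalized mutual-clustering-information distance between trees.

    Leaf sets must already match (use :func:`prune_to_shared` first).
    The optimal injective split matching maximizes total pairwise MI;
    shared information is its total, normalized by the mean of the two
    trees' total split entropies.
    """
    if t1.leaves != t2.leaves:
        raise ValueError("leaf sets differ; prune to the intersection first")
    flags: list[str] = []
    h1, h2 = total_split_entropy(t1), total_split_entropy(t2)
    normalizer = 0.5 * (h1 + h2)
    if not t1.splits or not t2.splits or normalizer <= 0:
        return SplitMatch(
            pairs=[], shared_info=0.0, normalizer=normalizer, distance=1.0,
            flags=["no informative splits"],
        )
    score = np.zeros((len(t1.splits), len(t2.splits)))
    for i, a in enumerate(t1.splits):
        for j, b in enumerate(t2.splits):
            mi = split_mutual_info(a, b, t1.leaves)
            score[i, j] = mi if mi > _SCORE_EPS else 0.0
    rows, cols = linear_sum_assignment(score, maximize=True)
    pairs = [
        (t1.splits[i], t2.splits[j], float(score[i, j]))
        for i, j in zip(rows, cols)
        if score[i, j] > 0
    ]
    shared = float(sum(s for _, _, s in pairs))
    distance = 1.0 - shared / normalizer
    return SplitMatch(
        pairs=pairs,
        shared_info=shared,
        normalizer=normalizer,
        distance=float(min(max(distance, 0.0), 1.0)),
        flags=flags,
    )


def prune_to_shared(nwk1: str, nwk2: str) -> tuple[Topology, Topology, int]:
    """Prune both trees to their shared leaf set; returns topologies and
    the number of leaves removed (gene presence/absence differs between
    trees as a matter of course)."""
    tr1 = dendropy.Tree.get(data=nwk1, schema="newick")
    tr2 = dendropy.Tree.get(data=nwk2, schema="newick")
    l1 = {lf.taxon.label for lf in tr1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in tr2.leaf_node_iter()}
    shared = l1 & l2
    if len(shared) < 4:
        raise ValueError("fewer than 4 shared leaves")
    pruned = len(l1 - shared) + len(l2 - shared)
    if l1 - shared:
        tr1 = tr1.extract_tree_with_taxa_labels(shared)
    if l2 - shared:
        tr2 = tr2.extract_tree_with_taxa_labels(shared)
    return splits_from_tree(tr1), splits_from_tree(tr2), pruned


def compare_newick(nwk1: str, nwk2: str) -> SplitMatch:
    t1, t2, pruned = prune_to_shared(nwk1, nwk2)
    match = mci_distance(t1, t2)
    match.pruned_leaves = pruned
    return match


def random_topology(leaves: list[str] | frozenset[str], seed: int) -> Topology:
    """Uniform random binary topology via sequential random joining."""
    from .synthio import random_tree_newick

    if len(leaves) < 4:
        raise ValueError("need at least 4 leaves")
    return extract_splits(random_tree_newick(sorted(leaves), seed))


def hgt_report(
    species_nwk: str,
    gene_nwk: str,
    conserved_nwks: list[str],
    n_random: int = 100,
    seed: int = 0,
) -> dict:
    """Distances of a gene tree and conserved-gene trees to the species
    tree, with a random-topology baseline on the same leaf set.

    The report's headline is the ratio of the gene-tree distance to the
    median conserved-tree distance: well above 2 with a distance near
    the random baseline is the horizontal-transfer signature.
    """
    gene_match = compare_newick(species_nwk, gene_nwk)
    conserved = [compare_newick(species_nwk, c).distance for c in conserved_nwks]
    t_sp, t_gn, _ = prune_to_shared(species_nwk, gene_nwk)
    rng = np.random.default_rng(seed)
    rand = []
    for _ in range(n_random):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        rt = random_topology(t_sp.leaves, sub_seed)
        rand.append(mci_distance(t_sp, rt).distance)
    rand = np.asarray(rand)
    med_cons = float(np.median(conserved)) if conserved else float("nan")
    return {
        "gene_distance": gene_match.distance,
        "conserved_distances": conserved,
        "median_conserved": med_cons,
        "gene_to_conserved_ratio": (
            gene_match.distance / med_cons if conserved and med_cons > 0 else float("inf")
        ),
        "random_mean": float(rand.mean()) if n_random > 0 else float("nan"),
        "random_sd": float(rand.std(ddof=1)) if n_random > 1 else 0.0,
        "pruned_leaves": gene_match.pruned_leaves,
    }
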