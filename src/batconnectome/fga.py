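"""Functional genomic alignment: a neighbour-joining tree over biological
distances.

The tree groups connectome genes by functional proximity — it is a
hierarchical clustering rendered as an unrooted tree, *not* a phylogeny, and
carries no evolutionary meaning. Neighbour joining needs a symmetric
dissimilarity, so asymmetric matrices are first symmetrized by the arithmetic
mean of the two directions.

Output is deterministic regardless of input gene order: genes are sorted
before joining and the tree is canonicalized (children ordered by their
smallest descendant leaf) before Newick serialisation.
"""

from __future__ import annotations

import io
from typing import Iterable

import dendropy
import numpy as np
import skbio
from dendropy.calculate import treecompare
from skbio.tree import TreeNode, nj

from .distances import DistanceMatrix, GenePartition
from .errors import ContractError, InputError


def symmetrize(dm: DistanceMatrix) -> DistanceMatrix:
    """Arithmetic-mean symmetrization: d'(a,b) = d'(b,a) = (d(a,b)+d(b,a))/2.

    Idempotent on symmetric input; each entry moves by at most half the
    directional gap.
    """
    v = (dm.values + dm.values.T) / 2.0
    return DistanceMatrix(dm.genes, v)


def _canonicalize(tree: TreeNode) -> TreeNode:
    """Sort children of every node by their smallest descendant leaf label."""

    def key(node: TreeNode) -> str:
        if node.is_tip():
            return node.name
        return min(t.name for t in node.tips())

    for node in tree.postorder(include_self=True):
        if not node.is_tip():
            node.children.sort(key=key)
    return tree


def nj_tree(
    dm: DistanceMatrix,
    genes: Iterable[str] | None = None,
    clamp_negative: bool = True,
) -> TreeNode:
    """Saitou–Nei neighbour joining over (a subset of) a symmetric matrix.

    ``clamp_negative`` maps negative branch-length estimates to zero (NJ can
    produce them when the metric is not additive). Raises ``ContractError``
    if the matrix is not symmetric — symmetrize first.
    """
    ids = sorted(set(genes)) if genes is not None else sorted(dm.genes)
    if len(ids) < 3:
        raise InputError("neighbour joining needs at least 3 genes")
    sub = dm.subset(ids)
    if not sub.is_symmetric(atol=0.0):
        raise ContractError("nj_tree requires a symmetric matrix; apply symmetrize() first")
    skb = skbio.DistanceMatrix(sub.values, ids=ids)
    tree = nj(skb, neg_as_zero=clamp_negative)
    return _canonicalize(tree)


def _format_length(x: float | None) -> str:
    if x is None:
        return ""
    return f":{float(x):.10g}"


def to_newick(tree: TreeNode) -> str:
    """Canonical Newick string, branch lengths to 10 significant digits."""

    def fmt(node: TreeNode) -> str:
        if node.is_tip():
            return f"{node.name}{_format_length(node.length)}"
        inner = ",".join(fmt(c) for c in node.children)
        return f"({inner}){_format_length(node.length)}"

    return fmt(tree) + ";"


def write_newick(tree: TreeNode, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(to_newick(tree) + "\n")


def read_newick(source) -> TreeNode:
    """Read a Newick tree from a path or string and canonicalize it."""
    if isinstance(source, str) and source.lstrip().startswith("("):
        tree = TreeNode.read(io.StringIO(source), format="newick")
    else:
        tree = TreeNode.read(str(source), format="newick")
    return _canonicalize(tree)


def write_leaf_annotations(partition: GenePartition, path) -> None:
    """TSV of (gene, class) with class in {core, known, candidate}, for
    external tree plotting."""
    rows = [(partition.core, "core")]
    rows += [(g, "known") for g in sorted(partition.known)]
    rows += [(g, "candidate") for g in sorted(partition.candidates)]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tclass\n")
        for gene, cls in rows:
            fh.write(f"{gene}\t{cls}\n")


# ---------------------------------------------------------------------------
# Tree comparison helpers (used by the recovery oracles)
# ---------------------------------------------------------------------------

def rf_distance(newick_a: str, newick_b: str) -> int:
    """Robinson–Foulds (symmetric bipartition) distance between two unrooted
    trees given as Newick strings over the same leaf set."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    for t in (ta, tb):
        t.is_rooted = False
        t.encode_bipartitions()
    return int(treecompare.symmetric_difference(ta, tb))


def tip_distance_error(tree: TreeNode, dm: DistanceMatrix) -> float:
    """Largest |tree path length − matrix distance| over all leaf pairs."""
    tt = tree.tip_tip_distances()
    err = 0.0
    ids = list(tt.ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            err = max(err, abs(float(tt[a, b]) - dm.get(a, b)))
    return err
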