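"""Phylogeny input, validation, and tree/character reconciliation.

Trees are handled as rooted dendropy trees with strictly labeled tips and a
branch length on every edge (polytomies allowed).  Branch lengths are used as
supplied — no ultrametric enforcement and no rescaling by default; the rate
scale of the evolutionary model is therefore tied to the supplied units.
"""

from __future__ import annotations

import logging
from pathlib import Path
import dendropy

from .characters import CharacterMatrix

__all__ = ["read_tree", "validate_tree", "reconcile", "tree_height", "total_tree_length"]

log = logging.getLogger(__name__)

#: terminal branches of length zero are replaced by this fraction of tree height
ZERO_LENGTH_EPSILON_FRACTION = 1e-6


def tree_height(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length."""
    return max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())


def total_tree_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.preorder_edge_iter() if e.head_node.parent_node)


def validate_tree(tree: dendropy.Tree, epsilon_fraction: float = ZERO_LENGTH_EPSILON_FRACTION) -> dendropy.Tree:
    """Validate labels and branch lengths; nudge zero-length terminal branches.

    Raises on duplicate or missing tip labels and on edges without a branch
    length.  Zero-length terminal branches are replaced by
    ``epsilon_fraction x tree height`` so transition matrices along them stay
    nondegenerate; each replacement is logged.
    """
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(lbl is None or lbl == "" for lbl in labels):
        raise ValueError("every tip must be labeled")
    dup = sorted({l for l in labels if labels.count(l) > 1})
    if dup:
        raise ValueError(f"duplicate tip labels: {dup}")

    missing = []
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is None:
            continue  # root edge carries no length
        if edge.length is None:
            head = edge.head_node
            name = head.taxon.label if head.taxon else f"internal node {id(head)}"
            missing.append(name)
    if missing:
        raise ValueError(f"branch lengths required; missing on edges above: {missing}")

    height = tree_height(tree)
    if height <= 0:
        raise ValueError("tree has zero height (all branch lengths zero?)")
    eps = epsilon_fraction * height
    for leaf in tree.leaf_node_iter():
        if leaf.edge.length == 0:
            log.info("zero-length terminal branch at %s replaced by %.3g", leaf.taxon.label, eps)
            leaf.edge.length = eps
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node and edge.length < 0:
            raise ValueError("negative branch length encountered")
    return tree


def read_tree(path: str | Path, schema: str = "newick") -> dendropy.Tree:
    """Read and validate a rooted phylogeny (Newick, or a NEXUS trees block)."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema=schema,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except (dendropy.utility.error.DataParseError, Exception) as exc:
        if "Multiple occurrences" in str(exc) or "duplicate" in str(exc).lower():
            raise ValueError(f"{path}: duplicate tip labels") from exc
        raise
    tree.is_rooted = True
    return validate_tree(tree)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def reconcile(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    policy: str = "prune",
) -> tuple[dendropy.Tree, CharacterMatrix, dict]:
    """Reconcile a tree with a character matrix.

    Under ``prune``, tips absent from the matrix are removed (degree-2 nodes
    collapsed, path lengths preserved) and matrix rows absent from the tree
    dropped; under ``strict`` any mismatch raises.  Returns the reconciled
    pair plus a report of what was dropped.
    """
    if policy not in ("prune", "strict"):
        raise ValueError(f"policy must be 'prune' or 'strict', got {policy!r}")
    tree_taxa = set(tip_labels(tree))
    matrix_taxa = set(matrix.taxa)
    tips_only = sorted(tree_taxa - matrix_taxa)
    rows_only = sorted(matrix_taxa - tree_taxa)
    report = {"pruned_tips": tips_only, "dropped_rows": rows_only}

    if policy == "strict" and (tips_only or rows_only):
        raise ValueError(
            f"tree/matrix mismatch: {len(tips_only)} tips without data "
            f"({tips_only[:5]}...), {len(rows_only)} rows without tips ({rows_only[:5]}...)"
        )

    shared = tree_taxa & matrix_taxa
    if len(shared) < 3:
        raise ValueError(f"fewer than 3 shared taxa after reconciliation ({len(shared)})")

    if tips_only:
        tree = tree.extract_tree_with_taxa_labels(
            labels=shared, suppress_unifurcations=True
        )
        tree.is_rooted = True
        log.info("pruned %d tips without character data", len(tips_only))
    if rows_only:
        matrix = matrix.subset(shared)
        log.info("dropped %d matrix rows without tree tips", len(rows_only))
    return tree, matrix, report
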