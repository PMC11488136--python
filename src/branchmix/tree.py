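"""Rooted taxon tree: the coordinate system for branch placements.

Every non-root node identifies the branch between itself and its parent.
A placement lives on such a branch at relative position beta (beta=1 at the
derived/child end, beta=0 at the ancestral/parent end). Internal nodes are
auto-labelled N1..Nm in pre-order when the input Newick leaves them unnamed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Iterator, Optional

import dendropy


class TreeError(ValueError):
    pass


@dataclass
class TreeNode:
    id: int
    label: str
    parent: Optional[int]
    length: Optional[float]  # parent-branch length; None only for the root
    children: list[int] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class TaxonTree:
    """Rooted tree with branch lengths in expected substitutions/site.

    Nodes carry integer ids assigned in pre-order (root = 0), so id order
    doubles as the deterministic tie-break order used elsewhere.
    """

    def __init__(self, nodes: list[TreeNode]):
        self.nodes = nodes
        self.label_to_id = {}
        for n in nodes:
            if n.label in self.label_to_id:
                raise TreeError(f"duplicate node label {n.label!r}")
            self.label_to_id[n.label] = n.id
        roots = [n for n in nodes if n.parent is None]
        if len(roots) != 1:
            raise TreeError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0].id
        for n in nodes:
            if n.parent is not None:
                if n.length is None:
                    raise TreeError(f"node {n.label!r} has no branch length")
                if not (n.length >= 0.0 and n.length < float("inf")):
                    raise TreeError(f"node {n.label!r} has invalid branch length {n.length}")

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, ref: int | str) -> TreeNode:
        if isinstance(ref, str):
            try:
                ref = self.label_to_id[ref]
            except KeyError:
                raise TreeError(f"unknown node label {ref!r}") from None
        return self.nodes[ref]

    def preorder(self) -> Iterator[TreeNode]:
        return iter(self.nodes)  # ids are assigned in pre-order

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves]

    # -- branches ----------------------------------------------------------
    def branches(self) -> list[int]:
        """Branch ids = derived-node ids, in pre-order (root excluded)."""
        return [n.id for n in self.nodes if n.parent is not None]

    def branch_length(self, derived: int | str) -> float:
        n = self.node(derived)
        if n.parent is None:
            raise TreeError("the root has no parent branch")
        return float(n.length)

    def branch_neighbors(self, derived: int | str) -> list[int]:
        """Adjacent branches: parent's branch, sibling branches, child branches."""
        n = self.node(derived)
        if n.parent is None:
            raise TreeError("the root has no parent branch")
        out = []
        parent = self.nodes[n.parent]
        if parent.parent is not None:
            out.append(parent.id)
        out.extend(c for c in parent.children if c != n.id)
        out.extend(n.children)
        return out

    # -- serialization -----------------------------------------------------
    def _newick_node(self, nid: int) -> str:
        n = self.nodes[nid]
        if n.is_leaf:
            core = n.label
        else:
            core = "(" + ",".join(self._newick_node(c) for c in n.children) + ")" + n.label
        if n.parent is None:
            return core
        return f"{core}:{n.length!r}"

    def to_newick(self) -> str:
        return self._newick_node(self.root) + ";"


def _from_dendropy(dtree: dendropy.Tree) -> TaxonTree:
    nodes: list[TreeNode] = []
    counter = 0
    auto = 0

    def visit(dnode, parent_id):
        nonlocal counter, auto
        nid = counter
        counter += 1
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            if not label:
                raise TreeError("leaf without a name")
        else:
            label = dnode.label or (dnode.taxon.label if dnode.taxon else None)
            if not label:
                auto += 1
                label = f"N{auto}"
        length = dnode.edge.length
        if parent_id is not None and length is None:
            raise TreeError(f"missing branch length above node {label!r}")
        nodes.append(TreeNode(nid, label, parent_id, None if parent_id is None else float(length)))
        for child in dnode.child_nodes():
            cid = visit(child, nid)
            nodes[nid].children.append(cid)
        return nid

    visit(dtree.seed_node, None)
    return TaxonTree(nodes)


def load_tree(newick_text: str) -> TaxonTree:
    """Parse a rooted Newick string with branch lengths into a TaxonTree.

    Unlabelled internal nodes are named N1..Nm in pre-order. Branch lengths
    are preserved exactly; a missing length on a non-root edge is an error.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree)


def load_tree_file(path) -> TaxonTree:
    with open(path) as fh:
        return load_tree(fh.read())
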