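"""Reference database construction.

From a pre-aligned set of mitogenomes and their rooted tree this module
(i) reconstructs one aligned ancestral sequence per internal tree node
(marginal maximum likelihood under the same HKY model used downstream, gap
states by Fitch parsimony), (ii) collapses the extended alignment into a
pangenome graph in which every tree node owns exactly one reference path,
and (iii) indexes the signature nodes — graph nodes traversed by a single
path — whose alignment frequencies later seed the source-count estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hky import BASES, BASE_INDEX, HkyModel
from .msa import MsaError, ReferenceMsa
from .tree import TaxonTree


class GraphError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Ancestral reconstruction
# ---------------------------------------------------------------------------

def _leaf_likelihoods(seq_arr: np.ndarray) -> np.ndarray:
    """(n_cols, 4) conditional likelihoods for one leaf; N and '-' are
    treated as missing data (all-ones)."""
    n_cols = seq_arr.shape[0]
    L = np.ones((n_cols, 4))
    for b, i in BASE_INDEX.items():
        mask = seq_arr == b
        L[mask] = 0.0
        L[mask, i] = 1.0
    return L


def reconstruct_ancestral_paths(msa: ReferenceMsa, tree: TaxonTree, model: HkyModel) -> ReferenceMsa:
    """Extend `msa` with one aligned sequence per internal tree node.

    Per column, the base is the marginal maximum-likelihood state under the
    HKY model (ties broken alphabetically); the gap/non-gap indicator is
    reconstructed by Fitch parsimony with ties resolved toward non-gap.
    """
    for leaf in tree.leaves:
        if leaf.label not in msa.names:
            raise MsaError(f"tree leaf {leaf.label!r} has no MSA record")
    n_cols = msa.length
    n_nodes = len(tree)
    seq_arrays = {name: np.frombuffer(seq.encode(), dtype="S1").astype("U1")
                  for name, seq in zip(msa.names, msa.seqs)}

    P = {n.id: model.transition_matrix(n.length) for n in tree.preorder() if n.parent is not None}

    # post-order conditional likelihoods and per-child messages
    down = np.ones((n_nodes, n_cols, 4))
    msg = {}  # child id -> (n_cols, 4): sum_y P[x, y] * down_child[y]
    for node in reversed(list(tree.preorder())):
        if node.is_leaf:
            down[node.id] = _leaf_likelihoods(seq_arrays[node.label])
        else:
            for c in node.children:
                msg[c] = down[c] @ P[c].T
                down[node.id] *= msg[c]
        norm = down[node.id].sum(axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        down[node.id] /= norm

    # pre-order outside probabilities
    up = np.ones((n_nodes, n_cols, 4))
    up[tree.root] = model.pi
    for node in tree.preorder():
        for c in node.children:
            excl = up[node.id].copy()
            for s in node.children:
                if s != c:
                    excl *= msg[s]
            up[c] = excl @ P[c]
            norm = up[c].sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            up[c] /= norm

    # Fitch parsimony on the gap indicator (bit 1 = base, bit 2 = gap)
    state = np.zeros((n_nodes, n_cols), dtype=np.uint8)
    for node in reversed(list(tree.preorder())):
        if node.is_leaf:
            state[node.id] = np.where(seq_arrays[node.label] == "-", 2, 1)
        else:
            inter = np.full(n_cols, 3, dtype=np.uint8)
            union = np.zeros(n_cols, dtype=np.uint8)
            for c in node.children:
                inter &= state[c]
                union |= state[c]
            state[node.id] = np.where(inter != 0, inter, union)
    assigned = np.zeros((n_nodes, n_cols), dtype=bool)  # True = gap
    for node in tree.preorder():
        s = state[node.id]
        if node.parent is None:
            assigned[node.id] = s == 2  # ties (s == 3) resolve to non-gap
        else:
            pg = assigned[node.parent]
            # keep the parent state when admissible, otherwise the forced one
            assigned[node.id] = np.where(s == 3, pg, s == 2)

    bases = np.array(list(BASES))
    names, seqs = [], []
    for node in tree.preorder():
        if node.is_leaf:
            continue
        marginal = down[node.id] * up[node.id]
        best = bases[np.argmax(marginal, axis=1)]  # argmax tie -> alphabetical
        best[assigned[node.id]] = "-"
        names.append(node.label)
        seqs.append("".join(best))
    return msa.extended(names, seqs)


# ---------------------------------------------------------------------------
# Pangenome graph
# ---------------------------------------------------------------------------

@dataclass
class PangenomeGraph:
    """Sequence graph with one reference path per tree node.

    Node ids are positive integers in construction order; `paths` maps a
    tree-node label to its ordered node-id walk and `node_paths` holds, for
    every graph node, the set of path labels traversing it.
    """

    nodes: dict[int, str] = field(default_factory=dict)
    edges: set[tuple[int, int]] = field(default_factory=set)
    paths: dict[str, list[int]] = field(default_factory=dict)
    node_paths: dict[int, frozenset[str]] = field(default_factory=dict)

    def finalize(self) -> "PangenomeGraph":
        support: dict[int, set[str]] = {nid: set() for nid in self.nodes}
        for label, walk in self.paths.items():
            if not walk:
                raise GraphError(f"path {label!r} is empty")
            for nid in walk:
                if nid not in self.nodes:
                    raise GraphError(f"path {label!r} references unknown node {nid}")
                support[nid].add(label)
            for a, b in zip(walk, walk[1:]):
                if (a, b) not in self.edges:
                    raise GraphError(f"path {label!r} uses missing edge {a}->{b}")
        for nid, seq in self.nodes.items():
            if not seq:
                raise GraphError(f"node {nid} has empty sequence")
        self.node_paths = {nid: frozenset(s) for nid, s in support.items()}
        return self

    def path_sequence(self, label: str) -> str:
        return "".join(self.nodes[nid] for nid in self.paths[label])

    def path_layout(self, label: str) -> list[tuple[int, int]]:
        """(node id, start offset in the concatenated path sequence) pairs."""
        out, pos = [], 0
        for nid in self.paths[label]:
            out.append((nid, pos))
            pos += len(self.nodes[nid])
        return out

    def node_base(self, nid: int, offset: int) -> str:
        return self.nodes[nid][offset]

    def __eq__(self, other) -> bool:
        return (isinstance(other, PangenomeGraph)
                and self.nodes == other.nodes
                and self.edges == other.edges
                and self.paths == other.paths)


def _column_key(column: list[str]) -> tuple[int, ...]:
    """Canonical residue-pattern partition of one MSA column: gaps map to 0,
    distinct residues to successive group indices by first occurrence."""
    groups: dict[str, int] = {}
    key = []
    for ch in column:
        if ch == "-":
            key.append(0)
        else:
            if ch not in groups:
                groups[ch] = len(groups) + 1
            key.append(groups[ch])
    return tuple(key)


def build_graph_from_msa(msa: ReferenceMsa, tree: TaxonTree) -> PangenomeGraph:
    """Collapse the extended alignment column-wise into a pangenome graph.

    Maximal runs of columns inducing the same record partition become one
    graph node per distinct non-gap allele; every record becomes one path
    whose concatenated node sequences spell the degapped input sequence.
    """
    order = [n.label for n in tree.preorder()]
    missing = [lab for lab in order if lab not in msa.names]
    if missing:
        raise MsaError(f"tree nodes without MSA records: {missing}")
    recs = [msa.record(lab) for lab in order]
    n_rec, n_cols = len(recs), msa.length

    keys = [_column_key([recs[r][j] for r in range(n_rec)]) for j in range(n_cols)]
    graph = PangenomeGraph(paths={lab: [] for lab in order})
    next_id = 1
    j = 0
    while j < n_cols:
        run_end = j
        while run_end + 1 < n_cols and keys[run_end + 1] == keys[j]:
            run_end += 1
        # group records by their (constant within the run) partition index
        by_group: dict[int, list[int]] = {}
        for r, g in enumerate(keys[j]):
            if g != 0:
                by_group.setdefault(g, []).append(r)
        for g in sorted(by_group):
            members = by_group[g]
            allele = recs[members[0]][j:run_end + 1]
            graph.nodes[next_id] = allele
            for r in members:
                graph.paths[order[r]].append(next_id)
            next_id += 1
        j = run_end + 1

    for walk in graph.paths.values():
        graph.edges.update(zip(walk, walk[1:]))
    return graph.finalize()


# ---------------------------------------------------------------------------
# Signature nodes
# ---------------------------------------------------------------------------

@dataclass
class SignatureIndex:
    """Per path, the graph nodes supported by that path alone, plus (once
    alignments are observed) the fraction of aligned fragments touching the
    set."""

    sets: dict[str, frozenset[int]]
    frequencies: dict[str, float] = field(default_factory=dict)

    def node_owner(self) -> dict[int, str]:
        return {nid: lab for lab, s in self.sets.items() for nid in s}


def compute_signature_sets(graph: PangenomeGraph) -> SignatureIndex:
    sets = {lab: set() for lab in graph.paths}
    for nid, support in graph.node_paths.items():
        if len(support) == 1:
            (lab,) = support
            sets[lab].add(nid)
    return SignatureIndex({lab: frozenset(s) for lab, s in sets.items()})


# ---------------------------------------------------------------------------
# GFA 1.0 serialization
# ---------------------------------------------------------------------------

def export_gfa(graph: PangenomeGraph) -> str:
    lines = ["H\tVN:Z:1.0"]
    for nid in sorted(graph.nodes):
        lines.append(f"S\t{nid}\t{graph.nodes[nid]}")
    for a, b in sorted(graph.edges):
        lines.append(f"L\t{a}\t+\t{b}\t+\t0M")
    for lab, walk in graph.paths.items():
        if not walk:
            raise GraphError(f"cannot export empty path {lab!r}")
        lines.append(f"P\t{lab}\t{','.join(f'{n}+' for n in walk)}\t*")
    return "\n".join(lines) + "\n"


def import_gfa(text: str) -> PangenomeGraph:
    graph = PangenomeGraph()
    for ln, line in enumerate(text.splitlines(), 1):
        if not line or line.startswith("H"):
            continue
        parts = line.split("\t")
        tag = parts[0]
        if tag == "S":
            graph.nodes[int(parts[1])] = parts[2]
        elif tag == "L":
            graph.edges.add((int(parts[1]), int(parts[3])))
        elif tag == "P":
            if len(parts) < 3 or not parts[2]:
                raise GraphError(f"GFA line {ln}: path without nodes")
            walk = [int(tok.rstrip("+-")) for tok in parts[2].split(",")]
            graph.paths[parts[1]] = walk
        else:
            raise GraphError(f"GFA line {ln}: unknown record type {tag!r}")
    return graph.finalize()
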