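"""Vectorised likelihood evaluator used by the MCMC.

The deamination and sequencing-error channels do not depend on the tree
placement, so for every aligned match/mismatch base we precompute the
4-vector w[bs] = sum_bd P_damage(bd|bs) * P_err(b|bd): the base probability
at branch distance t is then just the dot product of w with the HKY row of
the graph base. Per tree node we stack these vectors for all bases the
node's path supports, fold everything placement-independent (indels,
softclips, unresolved bases, unsupported-node bases) into a per-fragment
constant, and reduce per fragment with a small numba kernel. Semantics are
defined by — and tested against — the scalar functions in `likelihood.py`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .damage import DamageProfile
from .graphalign import FragmentAlignment
from .hky import BASE_INDEX, HkyModel
from .likelihood import (INDEL_PROB, PROB_FLOOR, MixtureModel, Placement,
                         _COMP_IDX, base_prob_unsupported)
from .refdb import PangenomeGraph
from .tree import TaxonTree


@njit(cache=True)
def _node_reduce_grouped(P, uG, uW, logp, indptr, idx, cnt, out):  # pragma: no cover
    for u in range(uG.size):
        g = uG[u]
        p = P[g, 0] * uW[u, 0] + P[g, 1] * uW[u, 1] + P[g, 2] * uW[u, 2] + P[g, 3] * uW[u, 3]
        if p < PROB_FLOOR:
            p = PROB_FLOOR
        logp[u] = np.log(p)
    for f in range(out.size):
        acc = 0.0
        for j in range(indptr[f], indptr[f + 1]):
            acc += cnt[j] * logp[idx[j]]
        out[f] += acc


@njit(cache=True)
def _mix_reduce(log_theta, L):  # pragma: no cover - exercised via wrapper
    k, n = L.shape
    total = 0.0
    for f in range(n):
        m = -1e300
        for i in range(k):
            v = log_theta[i] + L[i, f]
            if v > m:
                m = v
        s = 0.0
        for i in range(k):
            s += np.exp(log_theta[i] + L[i, f] - m)
        total += m + np.log(s)
    return total


class PlacementEngine:
    """Precomputed per-(tree node) base tables for fast placement likelihoods."""

    def __init__(self, alignments: list[FragmentAlignment], graph: PangenomeGraph,
                 tree: TaxonTree, model: HkyModel, profile: DamageProfile,
                 indel_prob: float = INDEL_PROB):
        self.alignments = alignments
        self.graph = graph
        self.tree = tree
        self.model = model
        self.profile = profile
        self.indel_prob = indel_prob
        self.n_frag = len(alignments)
        if self.n_frag == 0:
            raise ValueError("no alignments to evaluate")
        self._build()

    def _build(self):
        graph, profile = self.graph, self.profile
        log_indel = np.log(max(self.indel_prob, PROB_FLOOR))
        labels = [n.label for n in self.tree.preorder() if n.label in graph.paths]
        self.labels = labels
        lab_idx = {lab: i for i, lab in enumerate(labels)}
        n_lab = len(labels)

        # flat arrays over all match/mismatch bases of all fragments
        G, W, F = [], [], []
        support = []           # (n_mm, n_lab) bool
        base_const = np.zeros(self.n_frag)   # placement-independent terms
        del_sup = np.zeros((self.n_frag, n_lab))  # supported-deletion log terms
        for fi, aln in enumerate(self.alignments):
            flip = aln.orientation == "-"
            for ab in aln.bases:
                if ab.event in ("unresolved", "softclip"):
                    base_const[fi] += np.log(max(ab.eps / 3.0, PROB_FLOOR))
                elif ab.event == "insertion":
                    base_const[fi] += log_indel
                elif ab.event == "deletion":
                    sup = graph.node_paths[ab.node]
                    for lab in sup:
                        if lab in lab_idx:
                            del_sup[fi, lab_idx[lab]] += log_indel
                else:  # match / mismatch
                    bg = BASE_INDEX[graph.node_base(ab.node, ab.offset)]
                    D = profile.matrix(ab.pos5, ab.pos3)
                    e = np.full(4, ab.eps / 3.0)
                    e[BASE_INDEX[ab.b]] = 1.0 - ab.eps
                    w = D @ e
                    if flip:
                        w = w[_COMP_IDX]
                    G.append(bg)
                    W.append(w)
                    F.append(fi)
                    sup = graph.node_paths[ab.node]
                    support.append([lab in sup for lab in labels])

        G = np.asarray(G, dtype=np.int64)
        W = np.asarray(W, dtype=np.float64).reshape(-1, 4)
        F = np.asarray(F, dtype=np.int64)
        support = np.asarray(support, dtype=bool).reshape(-1, n_lab)

        # per-base unsupported log-probability
        unsup_logp = np.empty(G.shape[0])
        k = 0
        for aln in self.alignments:
            for ab in aln.bases:
                if ab.event in ("match", "mismatch"):
                    unsup_logp[k] = np.log(max(base_prob_unsupported(ab.eps), PROB_FLOOR))
                    k += 1

        self._per_label = {}
        for lab, li in lab_idx.items():
            mask = support[:, li]
            # bases this path does not support contribute a placement-free amount
            const = (base_const + del_sup[:, li]
                     + np.bincount(F[~mask], weights=unsup_logp[~mask],
                                   minlength=self.n_frag))
            self._per_label[lab] = self._grouped_tables(G[mask], W[mask], F[mask], const)

    def _grouped_tables(self, G, W, F, const):
        """Pool bases sharing (graph base, damage/error vector) and store a
        per-fragment CSR of group counts: most bases fall into a few hundred
        groups because qualities repeat and damage rates flatten to the
        residual away from the fragment ends."""
        if G.size == 0:
            empty = np.zeros(0, dtype=np.int64)
            return (empty, np.zeros((0, 4)), np.zeros(0),
                    np.zeros(self.n_frag + 1, dtype=np.int64), empty,
                    np.zeros(0), const)
        rows = np.concatenate([G[:, None].astype(float), W], axis=1)
        uniq, inverse = np.unique(rows, axis=0, return_inverse=True)
        uG = uniq[:, 0].astype(np.int64)
        uW = np.ascontiguousarray(uniq[:, 1:])
        # count (fragment, group) pairs
        key = F * uniq.shape[0] + inverse
        ukey, cnt = np.unique(key, return_counts=True)
        kf = ukey // uniq.shape[0]
        ku = ukey % uniq.shape[0]
        order = np.argsort(kf, kind="stable")
        kf, ku, cnt = kf[order], ku[order], cnt[order].astype(float)
        indptr = np.zeros(self.n_frag + 1, dtype=np.int64)
        np.add.at(indptr, kf + 1, 1)
        indptr = np.cumsum(indptr)
        return (uG, uW, np.zeros(uG.size), indptr,
                ku.astype(np.int64), cnt, const)

    # -- evaluation --------------------------------------------------------
    def node_log_products(self, label: str, t: float) -> np.ndarray:
        """(n_frag,) vector of log prod_b P(b | node `label`, distance t)."""
        uG, uW, logp, indptr, idx, cnt, const = self._per_label[label]
        out = const.copy()
        if uG.size:
            _node_reduce_grouped(self.model.transition_matrix_raw(t),
                                 uG, uW, logp, indptr, idx, cnt, out)
        return out

    def fragment_logliks(self, placement: Placement) -> np.ndarray:
        """(n_frag,) vector of log P(fr | beta) for one placement."""
        beta = placement.beta
        if beta == 0.0:
            return self.node_log_products(placement.a_node, placement.t_a)
        if beta == 1.0:
            return self.node_log_products(placement.d_node, placement.t_d)
        la = self.node_log_products(placement.a_node, placement.t_a)
        ld = self.node_log_products(placement.d_node, placement.t_d)
        return np.logaddexp(np.log1p(-beta) + la, np.log(beta) + ld)

    def mixture_loglik_from_components(self, theta: np.ndarray, L: np.ndarray) -> float:
        """Total log-likelihood from cached per-source fragment logliks
        L (k, n_frag) and mixture weights theta."""
        if L.shape[0] == 1:
            return float(L.sum())  # theta = (1,)
        with np.errstate(divide="ignore"):
            log_theta = np.log(np.asarray(theta, dtype=float))
        return float(_mix_reduce(log_theta, np.ascontiguousarray(L)))

    def mixture_loglik(self, mixture: MixtureModel) -> float:
        L = np.stack([self.fragment_logliks(p) for p in mixture.placements])
        return self.mixture_loglik_from_components(mixture.theta, L)
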