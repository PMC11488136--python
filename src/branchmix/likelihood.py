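"""Damage-aware placement-conditional mixture likelihood.

A source is a continuous position on a tree branch between an ancestral
node N_A and a derived node N_D: at relative position beta the distance to
N_A is t_A = beta*t and to N_D is t_D = (1-beta)*t. The probability of an
observed fragment base chains three independent channels — HKY mutation
over the branch distance, terminal deamination, and sequencing error — by
marginalising over all 16 intermediate (post-mutation, post-damage) base
pairs. Bases landing on graph nodes the evaluated path does not traverse
use a fixed error/match mixture instead. A fragment's likelihood is the
(1-beta, beta)-weighted average of its two per-node base-probability
products, and fragments combine across k sources as a standard mixture with
weights theta.

The functions here are the reference (scalar) semantics; `engine.py` holds
the vectorised equivalent used by the MCMC and is tested against these.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .damage import DamageProfile
from .graphalign import AlignedBase, FragmentAlignment
from .hky import BASE_INDEX, HkyModel
from .refdb import PangenomeGraph
from .tree import TaxonTree

INDEL_PROB = 0.02      # per inserted/deleted base (empirical mitogenome rate)
PROB_FLOOR = 1e-12     # clamp before log; zero-epsilon qualities exist
SIMPLEX_TOL = 1e-12

_COMP_IDX = np.array([BASE_INDEX[c] for c in "TGCA"])  # A,C,G,T -> complement


class LikelihoodError(ValueError):
    pass


@dataclass
class Placement:
    """A source position on the branch between `a_node` (ancestral end) and
    `d_node` (derived end): beta=1 means the source equals the derived node."""

    a_node: str
    d_node: str
    beta: float
    t: float

    def __post_init__(self):
        if not (0.0 <= self.beta <= 1.0):
            raise LikelihoodError(f"beta={self.beta} outside [0, 1]")
        if self.t < 0:
            raise LikelihoodError("branch length must be non-negative")

    @property
    def t_a(self) -> float:
        return self.beta * self.t

    @property
    def t_d(self) -> float:
        return (1.0 - self.beta) * self.t


def placement_on(tree: TaxonTree, derived: int | str, beta: float) -> Placement:
    """Construct the placement at relative position beta on the parent
    branch of `derived`."""
    d = tree.node(derived)
    if d.parent is None:
        raise LikelihoodError("the root has no parent branch")
    return Placement(tree.nodes[d.parent].label, d.label, beta, float(d.length))


@dataclass
class MixtureModel:
    theta: np.ndarray
    placements: list[Placement] = field(default_factory=list)

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if len(self.placements) != self.theta.size:
            raise LikelihoodError("theta and placements differ in length")
        if np.any(self.theta < 0) or abs(self.theta.sum() - 1.0) > max(SIMPLEX_TOL, 4e-16 * self.theta.size):
            raise LikelihoodError("theta must lie on the simplex")

    @property
    def k(self) -> int:
        return int(self.theta.size)


# ---------------------------------------------------------------------------
# Per-base probabilities
# ---------------------------------------------------------------------------

def base_prob_unsupported(eps: float) -> float:
    """Probability of a read base sitting on a graph node untraversed by the
    evaluated path: 6/7 of such bases are treated as sequencing error (prob
    eps/3) and 1/7 as a match (prob 1-eps)."""
    return (6.0 / 7.0) * (eps / 3.0) + (1.0 / 7.0) * (1.0 - eps)


def _error_vector(b: str, eps: float) -> np.ndarray:
    """P(observed b | pre-error base bd) over bd in A,C,G,T."""
    e = np.full(4, eps / 3.0)
    e[BASE_INDEX[b]] = 1.0 - eps
    return e


def base_prob_aligned(model: HkyModel, profile: DamageProfile, t: float,
                      ab: AlignedBase, bg: str | None = None,
                      orientation: str = "+",
                      indel_prob: float = INDEL_PROB) -> float:
    """Probability of one aligned-base event given the graph base `bg` of
    the evaluated path at distance `t` from the source.

    match/mismatch: sum over post-mutation bases bs and post-damage bases bd
    of P_HKY(bs|bg,t) * P_damage(bd|bs; pos5,pos3) * P_err(b|bd,eps).
    Insertions and deletions cost `indel_prob`; unresolved bases and
    softclips cost eps/3. For reverse-complement alignments the mutation
    channel runs on the reference strand and the damage/error channels on
    the fragment strand, so bs is complemented between the two.
    """
    if ab.event in ("insertion", "deletion"):
        return indel_prob
    if ab.event in ("unresolved", "softclip"):
        return ab.eps / 3.0
    if ab.event not in ("match", "mismatch"):
        raise LikelihoodError(f"unknown event {ab.event!r}")
    if bg is None:
        raise LikelihoodError("graph base required for match/mismatch events")
    P = model.transition_matrix(t)[BASE_INDEX[bg.upper()]]
    D = profile.matrix(ab.pos5, ab.pos3)
    e = _error_vector(ab.b, ab.eps)
    total = 0.0
    for bs in range(4):
        bs_frag = bs if orientation == "+" else int(_COMP_IDX[bs])
        for bd in range(4):
            total += P[bs] * D[bs_frag, bd] * e[bd]
    return float(total)


# ---------------------------------------------------------------------------
# Fragment and mixture likelihoods
# ---------------------------------------------------------------------------

def _node_log_product(aln: FragmentAlignment, label: str, t: float,
                      graph: PangenomeGraph, model: HkyModel,
                      profile: DamageProfile, indel_prob: float) -> float:
    """log prod over bases of P(b | placement at distance t on `label`'s side)."""
    total = 0.0
    for ab in aln.bases:
        if ab.event in ("unresolved", "softclip"):
            p = ab.eps / 3.0
        elif ab.event == "insertion":
            p = indel_prob
        elif ab.node is not None and label in graph.node_paths[ab.node]:
            if ab.event == "deletion":
                p = indel_prob
            else:
                bg = graph.node_base(ab.node, ab.offset)
                p = base_prob_aligned(model, profile, t, ab, bg, aln.orientation, indel_prob)
        elif ab.event == "deletion":
            continue  # no read base; unsupported-node model does not apply
        else:
            p = base_prob_unsupported(ab.eps)
        total += np.log(max(p, PROB_FLOOR))
    return total


def fragment_loglik(aln: FragmentAlignment, placement: Placement,
                    graph: PangenomeGraph, model: HkyModel,
                    profile: DamageProfile, indel_prob: float = INDEL_PROB) -> float:
    """log[(1-beta) * prod P(b|N_A, t_A) + beta * prod P(b|N_D, t_D)]."""
    if not aln.bases:
        raise LikelihoodError(f"alignment {aln.read_id} has no bases")
    for lab in (placement.a_node, placement.d_node):
        if lab not in graph.paths:
            raise LikelihoodError(f"tree node {lab!r} has no reference path")
    beta = placement.beta
    la = ld = -np.inf
    if beta < 1.0:
        la = _node_log_product(aln, placement.a_node, placement.t_a,
                               graph, model, profile, indel_prob)
    if beta > 0.0:
        ld = _node_log_product(aln, placement.d_node, placement.t_d,
                               graph, model, profile, indel_prob)
    if beta == 0.0:
        return la
    if beta == 1.0:
        return ld
    return float(np.logaddexp(np.log1p(-beta) + la, np.log(beta) + ld))


def mixture_loglik(alignments: list[FragmentAlignment], mixture: MixtureModel,
                   graph: PangenomeGraph, model: HkyModel,
                   profile: DamageProfile, indel_prob: float = INDEL_PROB) -> float:
    """Sum over fragments of log sum_i theta_i * P(fr | beta_i)."""
    if abs(mixture.theta.sum() - 1.0) > 1e-9 or np.any(mixture.theta < 0):
        raise LikelihoodError("theta must lie on the simplex")
    with np.errstate(divide="ignore"):
        log_theta = np.log(mixture.theta)
    total = 0.0
    for aln in alignments:
        terms = np.array([
            lt + fragment_loglik(aln, pl, graph, model, profile, indel_prob)
            if np.isfinite(lt) else -np.inf
            for lt, pl in zip(log_theta, mixture.placements)
        ])
        m = terms.max()
        total += m + np.log(np.exp(terms - m).sum())
    return float(total)
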