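"""The damage-aware placement likelihood: per-base channel composition
checked against exhaustive 16-term enumeration, fragment and mixture
likelihoods against hand arithmetic and assignment oracles, and the fast
engine against the scalar reference."""

import itertools
import math

import numpy as np
import pytest

import branchmix as bm
from branchmix.damage import DamageProfile
from branchmix.engine import PlacementEngine
from branchmix.graphalign import AlignedBase, FragmentAlignment
from branchmix.hky import BASES, BASE_INDEX
from branchmix.likelihood import (LikelihoodError, MixtureModel, Placement,
                                  base_prob_aligned, base_prob_unsupported,
                                  fragment_loglik, mixture_loglik, placement_on)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def mk_base(b, eps=0.001, event="match", node=1, offset=0, pos5=0, pos3=39):
    return AlignedBase(b, eps, event, node, offset, pos5, pos3)


def oracle_16_terms(model, profile, t, ab, bg, orientation="+"):
    """Independent enumeration over all (post-mutation, post-damage) pairs."""
    P = model.transition_matrix(t)
    total = 0.0
    for bs in BASES:
        bs_frag = bs if orientation == "+" else COMP[bs]
        for bd in BASES:
            p_mut = P[BASE_INDEX[bg], BASE_INDEX[bs]]
            p_dam = bm.delta_at(profile, ab.pos5, ab.pos3, bs_frag, bd)
            p_err = (1 - ab.eps) if bd == ab.b else ab.eps / 3
            total += p_mut * p_dam * p_err
    return total


# ---------------------------------------------------------------------------
# base probabilities
# ---------------------------------------------------------------------------

def test_unsupported_limits_and_monotonicity():
    assert base_prob_unsupported(1e-12) == pytest.approx(1 / 7, rel=1e-6)
    assert base_prob_unsupported(0.75) == pytest.approx(0.25)
    # the 6/7 error-weighted term dominates: linear with slope +1/7
    eps = np.linspace(1e-6, 1, 50)
    vals = [base_prob_unsupported(e) for e in eps]
    assert all(b > a for a, b in zip(vals, vals[1:]))
    assert base_prob_unsupported(1.0) == pytest.approx(2 / 7)


def test_aligned_identity_channels():
    model = bm.HkyModel()
    ab = mk_base("C", eps=0.0)
    assert base_prob_aligned(model, bm.zero_profile(), 0.0, ab, "C") == pytest.approx(1.0)


def test_aligned_pure_damage_channel():
    model = bm.HkyModel()
    prof = DamageProfile(ct5=[0.3], ga3=[0.0])
    ab = mk_base("T", eps=0.0, event="mismatch", pos5=0)
    assert base_prob_aligned(model, prof, 0.0, ab, "C") == pytest.approx(0.3)
    ab_match = mk_base("C", eps=0.0, pos5=0)
    assert base_prob_aligned(model, prof, 0.0, ab_match, "C") == pytest.approx(0.7)


def test_aligned_matches_enumeration_oracle():
    rng = np.random.default_rng(77)
    for _ in range(40):
        model = bm.HkyModel(kappa=float(rng.uniform(0.5, 6)),
                            pi=rng.dirichlet(np.full(4, 5.0)))
        prof = DamageProfile(ct5=rng.uniform(0, 0.5, 6), ga3=rng.uniform(0, 0.5, 6))
        t = float(rng.uniform(0, 1))
        ori = "+" if rng.random() < 0.5 else "-"
        ab = mk_base(BASES[rng.integers(4)], eps=float(rng.uniform(0, 0.3)),
                     event="mismatch", pos5=int(rng.integers(0, 10)),
                     pos3=int(rng.integers(0, 10)))
        bg = BASES[rng.integers(4)]
        got = base_prob_aligned(model, prof, t, ab, bg, ori)
        assert got == pytest.approx(oracle_16_terms(model, prof, t, ab, bg, ori))


def test_observed_base_distribution_sums_to_one():
    rng = np.random.default_rng(13)
    for _ in range(10):
        model = bm.HkyModel(kappa=float(rng.uniform(0.5, 6)),
                            pi=rng.dirichlet(np.full(4, 5.0)))
        prof = DamageProfile(ct5=rng.uniform(0, 1, 4), ga3=rng.uniform(0, 1, 4))
        t, eps = float(rng.uniform(0, 2)), float(rng.uniform(0, 0.5))
        for bg in BASES:
            for ori in "+-":
                tot = sum(base_prob_aligned(model, prof, t,
                                            mk_base(b, eps=eps, pos5=2, pos3=3), bg, ori)
                          for b in BASES)
                assert tot == pytest.approx(1.0)


def test_event_class_probabilities():
    model, prof = bm.HkyModel(), bm.zero_profile()
    assert base_prob_aligned(model, prof, 0.1, mk_base("-", event="deletion")) == 0.02
    assert base_prob_aligned(model, prof, 0.1, mk_base("A", event="insertion")) == 0.02
    ab = mk_base("N", eps=0.3, event="unresolved", node=None)
    assert base_prob_aligned(model, prof, 0.1, ab) == pytest.approx(0.1)
    with pytest.raises(LikelihoodError):
        base_prob_aligned(model, prof, 0.1, mk_base("A", event="match"), bg=None)


# ---------------------------------------------------------------------------
# fragment likelihood on the hand-built two-path graph
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def toy_setup(two_path_graph):
    tree = bm.load_tree("(A:0.1,B:0.2);")
    model = bm.HkyModel(kappa=2.0, pi=np.full(4, 0.25))
    prof = bm.zero_profile()
    return two_path_graph, tree, model, prof


def frag_on_allele(two_path_graph, base_at_allele="G"):
    """A 2-base fragment: one base on the shared prefix node, one on the
    G/T allele node (node 2 = path A's allele, node 3 = B's)."""
    node = 2 if base_at_allele == "G" else 3
    ev = "match"
    bases = [mk_base("A", event="match", node=1, offset=0, pos5=0, pos3=1),
             mk_base(base_at_allele, event=ev, node=node, offset=0, pos5=1, pos3=0)]
    return FragmentAlignment("f0", "+", "A", 2.0, bases)


def test_beta_one_uses_only_derived(toy_setup):
    graph, tree, model, prof = toy_setup
    aln = frag_on_allele(graph)
    pl = placement_on(tree, "A", 1.0)  # derived node A, t_d = 0
    ll = fragment_loglik(aln, pl, graph, model, prof)
    # at t=0 with no damage/low error both bases match A's path exactly
    eps = 0.001
    assert ll == pytest.approx(2 * math.log(1 - eps), rel=1e-6)


def test_beta_half_hand_arithmetic(toy_setup):
    graph, tree, model, prof = toy_setup
    aln = frag_on_allele(graph)
    pl = placement_on(tree, "B", 0.5)  # between root N1 and leaf B
    t_a, t_d = pl.t_a, pl.t_d
    pA = [base_prob_aligned(model, prof, t_a, aln.bases[0], "A"),
          base_prob_aligned(model, prof, t_a, aln.bases[1], "G")]
    # allele base sits on node 2, which B's path does not traverse
    pD = [base_prob_aligned(model, prof, t_d, aln.bases[0], "A"),
          base_prob_unsupported(aln.bases[1].eps)]
    expected = math.log(0.5 * pA[0] * pA[1] + 0.5 * pD[0] * pD[1])
    got = fragment_loglik(aln, pl, graph, model, prof)
    assert got == pytest.approx(expected, rel=1e-9)


def test_likelihood_affine_in_beta_on_zero_branch(two_path_graph):
    tree = bm.load_tree("(A:0.0,B:0.2);")
    model, prof = bm.HkyModel(), bm.zero_profile()
    aln = frag_on_allele(two_path_graph)
    ends = [math.exp(fragment_loglik(aln, placement_on(tree, "A", b),
                                     two_path_graph, model, prof)) for b in (0.0, 1.0)]
    for beta in np.linspace(0, 1, 11):
        lin = (1 - beta) * ends[0] + beta * ends[1]
        got = math.exp(fragment_loglik(aln, placement_on(tree, "A", float(beta)),
                                       two_path_graph, model, prof))
        assert got == pytest.approx(lin, rel=1e-9)


def test_unknown_branch_rejected(toy_setup):
    graph, tree, model, prof = toy_setup
    aln = frag_on_allele(graph)
    with pytest.raises(LikelihoodError):
        fragment_loglik(aln, Placement("A", "Z", 0.5, 0.1), graph, model, prof)


# ---------------------------------------------------------------------------
# mixture likelihood
# ---------------------------------------------------------------------------

def test_k1_equals_fragment_sum(toy_setup):
    graph, tree, model, prof = toy_setup
    alns = [frag_on_allele(graph, "G"), frag_on_allele(graph, "T")]
    pl = placement_on(tree, "B", 0.3)
    mix = MixtureModel(np.array([1.0]), [pl])
    assert mixture_loglik(alns, mix, graph, model, prof) == pytest.approx(
        sum(fragment_loglik(a, pl, graph, model, prof) for a in alns))


def test_identical_placements_theta_independent(toy_setup):
    graph, tree, model, prof = toy_setup
    alns = [frag_on_allele(graph)]
    pl = placement_on(tree, "A", 0.4)
    v1 = mixture_loglik(alns, MixtureModel(np.array([0.9, 0.1]), [pl, pl]),
                        graph, model, prof)
    v2 = mixture_loglik(alns, MixtureModel(np.array([0.2, 0.8]), [pl, pl]),
                        graph, model, prof)
    assert v1 == pytest.approx(v2)


def test_mixture_matches_assignment_oracle(toy_setup):
    """2 fragments x 2 sources: marginalising per fragment must equal the
    brute-force sum over the 4 read-to-source assignments."""
    graph, tree, model, prof = toy_setup
    alns = [frag_on_allele(graph, "G"), frag_on_allele(graph, "T")]
    theta = np.array([0.7, 0.3])
    pls = [placement_on(tree, "A", 0.9), placement_on(tree, "B", 0.2)]
    probs = [[math.exp(fragment_loglik(a, p, graph, model, prof)) for p in pls]
             for a in alns]
    oracle = sum(theta[i] * theta[j] * probs[0][i] * probs[1][j]
                 for i, j in itertools.product(range(2), repeat=2))
    got = mixture_loglik(alns, MixtureModel(theta, pls), graph, model, prof)
    assert got == pytest.approx(math.log(oracle))


def test_label_switching_and_zero_weight(toy_setup):
    graph, tree, model, prof = toy_setup
    alns = [frag_on_allele(graph, "G"), frag_on_allele(graph, "T")]
    theta = np.array([0.7, 0.3])
    pls = [placement_on(tree, "A", 0.9), placement_on(tree, "B", 0.2)]
    v = mixture_loglik(alns, MixtureModel(theta, pls), graph, model, prof)
    v_perm = mixture_loglik(alns, MixtureModel(theta[::-1].copy(), pls[::-1]),
                            graph, model, prof)
    assert v == pytest.approx(v_perm)
    v_pad = mixture_loglik(alns, MixtureModel(np.array([0.7, 0.3, 0.0]),
                                              pls + [placement_on(tree, "A", 0.1)]),
                           graph, model, prof)
    assert v_pad == pytest.approx(v)


def test_off_simplex_rejected(toy_setup):
    graph, tree, model, prof = toy_setup
    with pytest.raises(LikelihoodError):
        MixtureModel(np.array([0.6, 0.3]), [placement_on(tree, "A", 0.5)] * 2)


# ---------------------------------------------------------------------------
# engine agrees with the scalar reference
# ---------------------------------------------------------------------------

def test_engine_matches_reference(small_db, small_alignments):
    db, _ = small_db
    prof = bm.default_damage_profile()
    eng = PlacementEngine(small_alignments, db.graph, db.tree, db.model, prof)
    rng = np.random.default_rng(3)
    branches = db.tree.branches()
    for _ in range(6):
        pl = placement_on(db.tree, int(rng.choice(branches)), float(rng.uniform()))
        fast = eng.fragment_logliks(pl)
        for fi in rng.choice(len(small_alignments), 5, replace=False):
            slow = fragment_loglik(small_alignments[fi], pl, db.graph, db.model, prof)
            assert fast[fi] == pytest.approx(slow, abs=1e-8)
    theta = rng.dirichlet([1, 1, 1])
    pls = [placement_on(db.tree, int(b), float(rng.uniform()))
           for b in rng.choice(branches, 3, replace=False)]
    mix = MixtureModel(theta, pls)
    assert eng.mixture_loglik(mix) == pytest.approx(
        mixture_loglik(small_alignments, mix, db.graph, db.model, prof), abs=1e-6)
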