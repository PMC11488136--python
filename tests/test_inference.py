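"""MCMC machinery: signature-based k estimate, proposals, the
exhaustive-enumeration posterior oracle, ESS, k-selection and summaries."""

import math

import numpy as np
import pytest

import branchmix as bm
from branchmix.engine import PlacementEngine
from branchmix.graphalign import AlignedBase, FragmentAlignment
from branchmix.inference import (InferenceError, KCurve, McmcConfig,
                                 MixtureState, _reflect01, compute_ess,
                                 estimate_initial_k, init_state, propose_move,
                                 run_mcmc, select_k, signature_hits,
                                 summarize_posterior)
from branchmix.likelihood import placement_on
from branchmix.refdb import SignatureIndex


def fake_alignment(rid, nodes):
    bases = [AlignedBase("A", 0.001, "match", n, 0, i, len(nodes) - 1 - i)
             for i, n in enumerate(nodes)]
    return FragmentAlignment(rid, "+", "p", float(len(nodes)), bases)


# ---------------------------------------------------------------------------
# signature-based k estimate
# ---------------------------------------------------------------------------

def test_initial_k_threshold_counting():
    index = SignatureIndex({"a": frozenset({101}), "b": frozenset({202}),
                            "c": frozenset({303})})
    alns = ([fake_alignment(f"x{i}", [101, 1]) for i in range(30)]
            + [fake_alignment(f"y{i}", [202]) for i in range(5)]
            + [fake_alignment(f"z{i}", [1, 2]) for i in range(65)])
    assert estimate_initial_k(alns, index) == 2
    assert index.frequencies["a"] == pytest.approx(0.30)


def test_initial_k_strictly_more_than_one_percent():
    index = SignatureIndex({"a": frozenset({101})})
    alns = ([fake_alignment(f"x{i}", [101]) for i in range(2)]
            + [fake_alignment(f"z{i}", [1]) for i in range(198)])
    # 2/200 = 1.0% exactly: not more than 1% -> excluded, floor k=1
    assert estimate_initial_k(alns, index) == 1


def test_initial_k_floor_and_empty_error():
    index = SignatureIndex({"a": frozenset({101})})
    assert estimate_initial_k([fake_alignment("q", [7])], index) == 1
    with pytest.raises(InferenceError):
        estimate_initial_k([], index)


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

@pytest.fixture()
def five_leaf_tree():
    return bm.load_tree("((A:0.1,B:0.1):0.1,((C:0.1,D:0.1):0.1,E:0.1):0.1);")


def test_signature_init_uses_top_hit_sets(five_leaf_tree):
    tree = five_leaf_tree
    index = SignatureIndex({"A": frozenset({1}), "C": frozenset({2}),
                            "E": frozenset({3})},
                           frequencies={"A": 0.5, "C": 0.3, "E": 0.02})
    st = init_state(2, "signature", index, tree, seed=0)
    labs = {tree.nodes[b].label for b in st.branches}
    assert labs == {"A", "C"}
    assert np.allclose(st.betas, 0.5)
    assert np.allclose(st.thetas, 0.5)


def test_random_init_reproducible_and_bounded(five_leaf_tree):
    s1 = init_state(3, "random", None, five_leaf_tree, seed=5)
    s2 = init_state(3, "random", None, five_leaf_tree, seed=5)
    assert s1.branches == s2.branches
    assert np.allclose(s1.betas, s2.betas)
    assert len(set(s1.branches)) == 3
    with pytest.raises(InferenceError):
        init_state(99, "random", None, five_leaf_tree, seed=0)


def test_random_init_covers_all_branches(five_leaf_tree):
    seen = set()
    for seed in range(400):
        st = init_state(1, "random", None, five_leaf_tree, seed=seed)
        seen.add(st.branches[0])
    assert seen == set(five_leaf_tree.branches())


# ---------------------------------------------------------------------------
# proposals
# ---------------------------------------------------------------------------

def test_beta_reflection():
    assert _reflect01(1.05) == pytest.approx(0.95)
    assert _reflect01(-0.2) == pytest.approx(0.2)
    assert _reflect01(0.3) == pytest.approx(0.3)
    assert _reflect01(2.4) == pytest.approx(0.4)
    assert 0 <= _reflect01(-7.3) <= 1


def test_branch_hop_hastings_between_equal_degree(five_leaf_tree):
    tree = five_leaf_tree
    cfg = McmcConfig(iterations=10, burnin=0.0, branch_hop=1.0, seed=0)
    st = MixtureState([tree.label_to_id["A"]], np.array([0.5]), np.array([1.0]))
    rng = np.random.default_rng(0)
    for _ in range(50):
        prop, log_h, changed = propose_move(st, cfg, rng, tree)
        assert changed == 0
        deg_cur = len(tree.branch_neighbors(st.branches[0]))
        deg_new = len(tree.branch_neighbors(prop.branches[0]))
        assert log_h == pytest.approx(math.log(deg_cur) - math.log(deg_new))
        if deg_cur == deg_new:
            assert log_h == 0.0


def test_theta_step_hastings_correction(five_leaf_tree):
    tree = five_leaf_tree
    cfg = McmcConfig(iterations=10, burnin=0.0, branch_hop=0.0, seed=0)
    st = MixtureState(tree.branches()[:2], np.array([0.5, 0.5]),
                      np.array([0.3, 0.7]))
    rng = np.random.default_rng(1)
    for _ in range(100):
        prop, log_h, changed = propose_move(st, cfg, rng, tree)
        if changed is None:  # theta move
            assert prop.thetas.sum() == pytest.approx(1.0)
            expected = float(np.sum(np.log(prop.thetas)) - np.sum(np.log(st.thetas)))
            assert log_h == pytest.approx(expected)
        else:
            assert log_h == 0.0  # reflected beta walk is symmetric


# ---------------------------------------------------------------------------
# the sampler vs exhaustive enumeration
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def star_setup():
    """3-branch star tree with a tiny graph and 5 fragments."""
    msa = bm.ReferenceMsa(
        ["A", "B", "C", "N1"],
        ["ACGTACGTACGTACGTACGT",
         "ACGTACTTACGTACGAACGT",
         "ACGAACGTACTTACGTACGT",
         "ACGTACGTACGTACGTACGT"])
    tree = bm.load_tree("(A:0.08,B:0.12,C:0.1);")
    graph = bm.build_graph_from_msa(msa, tree)
    reads = ["ACGTACTTACGTACGAACGT"[:15],
             "ACGTACGTACGTACGT",
             "CGAACGTACTTACG",
             "ACTTACGTACGAAC",
             "ACGTACGTACGT"]
    alns = []
    for i, seq in enumerate(reads):
        aln = bm.align_fragment(bm.ReadRecord(f"r{i}", seq, "?" * len(seq)), graph,
                                bm.AlignScoring(min_score_frac=0.5))
        assert aln is not None
        alns.append(aln)
    model = bm.model_from_msa(msa)
    prof = bm.zero_profile()
    eng = PlacementEngine(alns, graph, tree, model, prof)
    return tree, eng


def test_chain_matches_enumerated_posterior(star_setup):
    """Branch visit frequencies of the chain match the numerically
    integrated flat-prior posterior over (branch, beta) within 2%."""
    tree, eng = star_setup
    grid = np.linspace(0.0, 1.0, 201)
    masses = {}
    for b in tree.branches():
        lls = np.array([eng.fragment_logliks(placement_on(tree, b, float(x))).sum()
                        for x in grid])
        w = np.exp(lls - lls.max())
        masses[b] = np.trapezoid(w, grid) * math.exp(lls.max())
    tot = sum(masses.values())
    expected = {b: m / tot for b, m in masses.items()}

    cfg = McmcConfig(iterations=100_000, burnin=0.0, seed=12, branch_hop=0.3,
                     init="random", chains=1)
    tr = run_mcmc(eng, tree, 1, cfg)
    ids, counts = np.unique(tr.branch[:, 0], return_counts=True)
    freq = dict(zip(ids.tolist(), (counts / counts.sum()).tolist()))
    for b in tree.branches():
        assert freq.get(b, 0.0) == pytest.approx(expected[b], abs=0.02)


def test_chain_determinism_and_uphill_acceptance(star_setup):
    tree, eng = star_setup
    cfg = McmcConfig(iterations=3000, seed=4, chains=1)
    t1 = run_mcmc(eng, tree, 1, cfg)
    t2 = run_mcmc(eng, tree, 1, cfg)
    assert np.array_equal(t1.loglik, t2.loglik)
    assert np.array_equal(t1.branch, t2.branch)
    # strictly-uphill proposals with non-negative Hastings terms: beta moves
    # are symmetric, so any rejected uphill move must have been a branch hop
    prev = t1.loglik[:-1]
    uphill_rejected = (~t1.accepted[1:]) & (t1.proposed_loglik[1:] > prev)
    # Metropolis always accepts when dll + log_h >= 0; with log_h bounded by
    # log(max_degree ratio), large uphill jumps are always accepted
    big = t1.proposed_loglik[1:] > prev + 5
    assert not np.any(uphill_rejected & big)


def test_trace_loglik_consistency(star_setup):
    tree, eng = star_setup
    cfg = McmcConfig(iterations=500, seed=8, chains=1)
    tr = run_mcmc(eng, tree, 1, cfg)
    for it in [0, 100, 499]:
        pl = placement_on(tree, int(tr.branch[it, 0]), float(tr.beta[it, 0]))
        assert tr.loglik[it] == pytest.approx(
            eng.fragment_logliks(pl).sum(), abs=1e-8)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def test_ess_iid():
    x = np.random.default_rng(0).normal(size=10_000)
    assert compute_ess(x) == pytest.approx(10_000, rel=0.10)


def test_ess_ar1_closed_form():
    rng = np.random.default_rng(1)
    n, rho = 40_000, 0.9
    x = np.empty(n)
    x[0] = rng.normal()
    for i in range(1, n):
        x[i] = rho * x[i - 1] + math.sqrt(1 - rho ** 2) * rng.normal()
    assert compute_ess(x) == pytest.approx(n * (1 - rho) / (1 + rho), rel=0.10)


def test_ess_constant_series_and_short_error():
    assert compute_ess(np.ones(100)) == 100.0
    with pytest.raises(InferenceError):
        compute_ess(np.ones(5))


def test_select_k_rules():
    flat = KCurve([1, 2, 3], [-100.0, -99.5, -99.4])
    assert select_k(flat, n_fragments=1000) == 1
    assert flat.selected == [True, False, False]
    jump = KCurve([1, 2, 3], [-2000.0, -1000.0, -999.0])
    assert select_k(jump, n_fragments=1000) == 2  # tau = ln(1000) ~ 6.9
    rising = KCurve([1, 2, 3], [-300.0, -200.0, -100.0])
    assert select_k(rising, n_fragments=1000) == 3


def test_summarize_constant_and_map(five_leaf_tree):
    tree = five_leaf_tree
    n, k = 1000, 1
    b = tree.branches()[0]
    tr = bm.McmcTrace(k=k, loglik=np.full(n, -5.0),
                      proposed_loglik=np.zeros(n),
                      branch=np.full((n, k), b), beta=np.full((n, k), 0.25),
                      theta=np.ones((n, k)), accepted=np.ones(n, dtype=bool))
    d = summarize_posterior(tr, 0.1, tree)
    s = d.sources[0]
    assert s.beta_quantiles == (0.25, 0.25, 0.25)
    assert s.theta_quantiles == (1.0, 1.0, 1.0)
    assert d.map_loglik == -5.0  # argmax of recorded loglik
    assert s.map_branch == tree.nodes[b].label
    assert d.low_ess_warning is False  # constant series count as independent
    with pytest.raises(InferenceError):
        summarize_posterior(tr, 1.0, tree)


def test_summarize_recovers_injected_quantiles(five_leaf_tree):
    tree = five_leaf_tree
    rng = np.random.default_rng(2)
    n = 20_000
    beta_samples = rng.beta(5, 2, size=n)
    tr = bm.McmcTrace(k=1, loglik=rng.normal(size=n), proposed_loglik=np.zeros(n),
                      branch=np.full((n, 1), tree.branches()[0]),
                      beta=beta_samples[:, None], theta=np.ones((n, 1)),
                      accepted=np.ones(n, dtype=bool))
    d = summarize_posterior(tr, 0.0, tree)
    from scipy.stats import beta as beta_dist
    for q, got in zip([0.05, 0.5, 0.95], d.sources[0].beta_quantiles):
        assert got == pytest.approx(beta_dist.ppf(q, 5, 2), abs=0.02)
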