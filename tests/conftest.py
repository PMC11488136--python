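import numpy as np
import pytest

import branchmix as bm
from branchmix.refdb import PangenomeGraph


@pytest.fixture(scope="session")
def toy_msa():
    """The 3-record toy alignment used throughout: one shared prefix, one
    tri-allelic column (G/T/gap), one shared suffix."""
    return bm.ReferenceMsa(["r1", "r2", "r3"], ["ACGT", "ACTT", "AC-T"])


@pytest.fixture(scope="session")
def toy_tree():
    return bm.load_tree("(r1:0.1,(r2:0.05,r3:0.05):0.05);")


@pytest.fixture(scope="session")
def toy_db(toy_msa, toy_tree):
    return bm.build_database(toy_msa, toy_tree)


@pytest.fixture(scope="session")
def two_path_graph():
    """Hand-built graph: paths A and B share the flanks and differ at one
    allele node; the root path N1 equals A's walk."""
    g = PangenomeGraph(
        nodes={1: "AC", 2: "G", 3: "T", 4: "T"},
        edges={(1, 2), (1, 3), (2, 4), (3, 4)},
        paths={"N1": [1, 2, 4], "A": [1, 2, 4], "B": [1, 3, 4]},
    )
    return g.finalize()


@pytest.fixture(scope="session")
def small_db():
    """A small simulated reference database (5 taxa, 800 bp, ~90% identity)
    with ancestral paths, shared across tests that need realistic data."""
    msa, tree, truth = bm.make_reference_set(5, 0.90, seed=7, length=800)
    db = bm.build_database(msa, tree)
    return db, truth


@pytest.fixture(scope="session")
def small_alignments(small_db):
    db, truth = small_db
    cfg = bm.SimConfig(sources={"N2": 0.6, next(l for l in truth if l.startswith("T")): 0.4},
                       n_fragments=60, damage=bm.default_damage_profile(), seed=9)
    reads, _ = bm.simulate_fragments(cfg, truth)
    alns = [a for a in (bm.align_fragment(r, db.graph) for r in reads) if a]
    assert alns
    return alns


def random_msa_with_gaps(rng, n_records=4, n_cols=30):
    """Random alignment over ACGT with scattered gaps, no all-gap columns."""
    while True:
        arr = rng.choice(list("ACGT"), size=(n_records, n_cols))
        gap_mask = rng.random((n_records, n_cols)) < 0.15
        arr[gap_mask] = "-"
        if not np.any(np.all(arr == "-", axis=0)):
            seqs = ["".join(row) for row in arr]
            if all(s.replace("-", "") for s in seqs):
                return bm.ReferenceMsa([f"L{i}" for i in range(n_records)], seqs)


def ladder_tree(labels, rng=None):
    """A pectinate tree over the given leaf labels with random lengths."""
    rng = rng or np.random.default_rng(0)
    nwk = labels[0] + ":" + f"{rng.uniform(0.02, 0.2):.4f}"
    for lab in labels[1:]:
        nwk = f"({nwk},{lab}:{rng.uniform(0.02, 0.2):.4f}):{rng.uniform(0.02, 0.2):.4f}"
    # the outermost length is dropped: root has no parent branch
    nwk = nwk.rsplit(":", 1)[0] + ";"
    return bm.load_tree(nwk)
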