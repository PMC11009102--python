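"""Distances, neighbour joining and bootstrap support."""

import numpy as np
import pytest

from mirounga.phylo import (
    DistanceMatrix,
    bootstrap_support,
    distance_matrix,
    nj_tree,
    p_distance,
    tn93_distance,
)


def _mutate(seq, n, rng):
    s = list(seq)
    for i in rng.choice(len(s), n, replace=False):
        s[i] = rng.choice([c for c in "ACGT" if c != s[i]])
    return "".join(s)


def _random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), length))


def test_p_distance_basics():
    assert p_distance("ACGT", "ACGT") == 0.0
    assert p_distance("ACGT", "ACGA") == 0.25
    # pairwise deletion of gaps and N
    assert p_distance("AC-TN", "ACGTA") == 0.0
    assert np.isnan(p_distance("NN--", "ACGT"))


def test_tn93_reduces_to_jukes_cantor():
    """Equal base composition and all 12 substitution types equally frequent:
    TN93 equals the JC69 closed form."""
    a = "ACGT" * 30
    pairs = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"), ("A", "C"), ("A", "T"),
             ("C", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "A"), ("T", "G")]
    b = list(a)
    used = set()
    for x, y in pairs:
        for i, ch in enumerate(a):
            if ch == x and i not in used:
                b[i] = y
                used.add(i)
                break
    b = "".join(b)
    p = p_distance(a, b)
    jc = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    assert tn93_distance(a, b) == pytest.approx(jc, abs=1e-10)


def test_tn93_saturation_and_approach_to_p():
    # maximally diverged: saturation flagged as infinity
    assert tn93_distance("AAAA" * 10, "GGGG" * 10) == np.inf
    # at small divergence TN93 ~ p
    rng = np.random.default_rng(7)
    a = _random_seq(rng, 5000)
    b = _mutate(a, 5, rng)
    p = p_distance(a, b)
    assert tn93_distance(a, b) / p == pytest.approx(1.0, abs=2e-3)


def test_tn93_ge_p_in_distance_matrix():
    rng = np.random.default_rng(19)
    base = _random_seq(rng, 800)
    seqs = {f"t{i}": _mutate(base, 40, rng) for i in range(4)}
    dp = distance_matrix(seqs, "p")
    dt = distance_matrix(seqs, "TN93")
    off = ~np.eye(4, dtype=bool)
    assert (dt.matrix[off] >= dp.matrix[off] - 1e-12).all()


def test_nj_recovers_additive_topology():
    d = np.array(
        [[0, 4, 9, 10], [4, 0, 9, 10], [9, 9, 0, 5], [10, 10, 5, 0]], dtype=float
    )
    tree = nj_tree(DistanceMatrix(["A", "B", "C", "D"], d, "p"))
    assert tree.bipartitions() == {frozenset({"C", "D"})}


def test_nj_three_taxon_closed_form():
    d = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], dtype=float)
    tree = nj_tree(DistanceMatrix(["x", "y", "z"], d, "p"))
    lengths = {leaf.name: leaf.length for leaf in tree.root.children}
    assert lengths == {"x": pytest.approx(1.0), "y": pytest.approx(2.0), "z": pytest.approx(4.0)}


def test_nj_input_order_invariance():
    rng = np.random.default_rng(3)
    base = _random_seq(rng, 600)
    clade1 = _mutate(base, 30, rng)
    clade2 = _mutate(base, 30, rng)
    seqs = {}
    for i in range(3):
        seqs[f"A{i}"] = _mutate(clade1, 3, rng)
        seqs[f"B{i}"] = _mutate(clade2, 3, rng)
    t1 = nj_tree(distance_matrix(seqs, "p"))
    reordered = {k: seqs[k] for k in reversed(list(seqs))}
    t2 = nj_tree(distance_matrix(reordered, "p"))
    # canonicalize both sets against the same reference taxon
    def canon(tree):
        ref = sorted(tree.taxa)[0]
        full = frozenset(tree.taxa)
        return {b if ref not in b else full - b for b in tree.bipartitions()}

    assert canon(t1) == canon(t2)


def test_nj_simulation_recovers_known_tree():
    """Two deep clades from a simulated alignment: the separating edge is
    recovered and gets near-100% bootstrap support."""
    rng = np.random.default_rng(11)
    base = _random_seq(rng, 1500)
    clade1 = _mutate(base, 120, rng)
    clade2 = _mutate(base, 120, rng)
    seqs = {"OG": _mutate(base, 250, rng)}
    for i in range(4):
        seqs[f"A{i}"] = _mutate(clade1, 6, rng)
        seqs[f"B{i}"] = _mutate(clade2, 6, rng)
    tree = bootstrap_support(seqs, n_reps=100, model="TN93", seed=5, outgroup="OG")
    taxa_a = frozenset(f"A{i}" for i in range(4))
    taxa_b = frozenset(f"B{i}" for i in range(4))
    bips = tree.bipartitions()
    full = frozenset(tree.taxa)
    canon = {b if tree.taxa[0] not in b else full - b for b in bips}
    canon_ab = {
        taxa_a if tree.taxa[0] not in taxa_a else full - taxa_a,
        taxa_b if tree.taxa[0] not in taxa_b else full - taxa_b,
    }
    assert canon_ab <= canon
    supports = []

    def collect(node):
        for c in node.children:
            if not c.is_leaf:
                if c.support is not None:
                    supports.append((frozenset(c.leaves()), c.support))
                collect(c)

    collect(tree.root)
    strong = {s for leaves, s in supports if leaves in (taxa_a, taxa_b)}
    assert strong and min(strong) >= 90.0
    # outgroup hangs off the root
    assert "OG" in [c.name for c in tree.root.children]


def test_bootstrap_deterministic_under_seed():
    rng = np.random.default_rng(2)
    base = _random_seq(rng, 400)
    seqs = {f"t{i}": _mutate(base, 12, rng) for i in range(5)}
    t1 = bootstrap_support(seqs, n_reps=60, seed=9)
    t2 = bootstrap_support(seqs, n_reps=60, seed=9)
    assert t1.newick() == t2.newick()


def test_branch_lengths_non_negative_and_newick_parses():
    rng = np.random.default_rng(13)
    base = _random_seq(rng, 300)
    seqs = {f"t{i}": _mutate(base, 20, rng) for i in range(6)}
    tree = nj_tree(distance_matrix(seqs, "TN93"))

    def walk(node):
        assert node.length >= 0.0
        for c in node.children:
            walk(c)

    walk(tree.root)
    nwk = tree.newick()
    from io import StringIO

    from Bio import Phylo

    parsed = Phylo.read(StringIO(nwk), "newick")
    assert parsed.count_terminals() == 6
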