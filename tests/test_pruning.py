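import itertools

import dendropy
import numpy as np
import pytest

from asexpop import (
    LabeledAlignment,
    binarize_pruned,
    build_small_mp_tree,
    four_x_rule,
    map_transitions,
    prune_by_sites,
    tajimas_D,
)
from asexpop.fixtures import FixtureSpec, generate_complex_fixture


def _aln(pairs, clusters=None):
    ids = [p[0] for p in pairs]
    seqs = [p[1] for p in pairs]
    labels = {p[0]: p[2] for p in pairs}
    return LabeledAlignment(ids, seqs, labels, clusters=clusters or {})


# ------------------------------------------------------------ site pruning


def test_prune_by_sites_toy():
    a = _aln(
        [
            ("s1", "AAAAA", "sexual"),
            ("s2", "AAAAT", "sexual"),
            ("a1", "AACAA", "asexual"),
            ("a2", "AAAAA", "asexual"),
            ("a3", "AACAT", "asexual"),
        ]
    )
    pruned, rep = prune_by_sites(a)
    assert rep.removed_columns == [4]
    assert pruned.length == 4
    assert rep.S_pruned == 1  # column 3 (0-based 2) still segregates
    assert set(pruned.ids) == {"a1", "a2", "a3"}


def test_prune_by_sites_no_sexual_polymorphism():
    a = _aln(
        [
            ("s1", "AAAA", "sexual"),
            ("s2", "AAAA", "sexual"),
            ("a1", "ATAA", "asexual"),
            ("a2", "AAAA", "asexual"),
        ]
    )
    pruned, rep = prune_by_sites(a)
    assert rep.removed_columns == []
    assert rep.S_pruned == rep.S_total == 1


def test_prune_by_sites_identical_asexuals():
    a = _aln(
        [
            ("s1", "AAAA", "sexual"),
            ("s2", "ATAA", "sexual"),
            ("a1", "AAAA", "asexual"),
            ("a2", "AAAA", "asexual"),
        ]
    )
    _, rep = prune_by_sites(a)
    assert rep.S_pruned == 0


def test_prune_by_sites_single_sexual_warns():
    a = _aln([("s1", "AA", "sexual"), ("a1", "AT", "asexual")])
    with pytest.warns(UserWarning):
        _, rep = prune_by_sites(a)
    assert rep.removed_columns == []


# ------------------------------------------------------- transition mapping


def test_monophyletic_asexuals_single_transition():
    a = _aln(
        [
            ("s1", "AAAA", "sexual"),
            ("s2", "AATA", "sexual"),
            ("a1", "TAAA", "asexual"),
            ("a2", "TACA", "asexual"),
        ]
    )
    tree = dendropy.Tree.get(
        data="((a1,a2),(s1,s2));", schema="newick", preserve_underscores=True
    )
    tm = map_transitions(a, tree)
    assert tm.transitions == 1


def test_two_independent_origins_two_transitions():
    a = _aln(
        [
            ("s1", "AAAA", "sexual"),
            ("s2", "AATA", "sexual"),
            ("a1", "TAAA", "asexual"),
            ("a2", "AACA", "asexual"),
        ]
    )
    tree = dendropy.Tree.get(
        data="((a1,s1),(a2,s2));", schema="newick", preserve_underscores=True
    )
    tm = map_transitions(a, tree)
    assert tm.transitions == 2


def test_asexual_root_rejected():
    a = _aln([("a1", "AA", "asexual"), ("a2", "AT", "asexual")])
    tree = dendropy.Tree.get(
        data="(a1,a2);", schema="newick", preserve_underscores=True
    )
    with pytest.raises(ValueError, match="root"):
        map_transitions(a, tree)


def _brute_force_parsimony_length(tree: dendropy.Tree, states: dict[str, str]) -> int:
    """Minimal changes over all internal-node base assignments, per column."""
    leaves = [lf for lf in tree.leaf_node_iter()]
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    ncols = len(next(iter(states.values())))
    total = 0
    for col in range(ncols):
        best = None
        for combo in itertools.product("ACGT", repeat=len(internals)):
            assign = {id(nd): b for nd, b in zip(internals, combo)}
            for lf in leaves:
                assign[id(lf)] = states[lf.taxon.label][col]
            changes = 0
            for nd in tree.preorder_node_iter():
                if nd.parent_node is not None and assign[id(nd)] != assign[
                    id(nd.parent_node)
                ]:
                    changes += 1
            best = changes if best is None else min(best, changes)
        total += best
    return total


def test_mapped_mutation_count_is_parsimony_optimal():
    """Fitch mapping places exactly the brute-force minimal number of
    changes, including on a 5-haplotype alignment with one homoplasy."""
    a = _aln(
        [
            ("s1", "AAAAA", "sexual"),
            ("s2", "ATAAG", "sexual"),
            ("a1", "TAACA", "asexual"),
            ("a2", "TATCA", "asexual"),
            ("a3", "ATTAG", "asexual"),  # site 3 (T) arises twice: homoplasy
        ]
    )
    tree = dendropy.Tree.get(
        data="(((a1,a2),a3),(s1,s2));", schema="newick", preserve_underscores=True
    )
    tm = map_transitions(a, tree)
    states = dict(zip(a.ids, a.seqs))
    assert len(tm.mutations) == _brute_force_parsimony_length(tm.tree, states)
    # no asexual-to-sexual transition anywhere (hard invariant)
    for nd in tm.tree.preorder_node_iter():
        if nd.parent_node is not None:
            assert not (
                tm.modes[id(nd.parent_node)] == "asexual"
                and tm.modes[id(nd)] == "sexual"
            )


def test_binarize_zero_retained():
    a = _aln(
        [
            ("s1", "AAAA", "sexual"),
            ("s2", "ATAA", "sexual"),
            ("a1", "AAAA", "asexual"),
            ("a2", "AAAA", "asexual"),
        ]
    )
    # identical asexual haplotypes collapse; supply a 3-tip tree
    tree = dendropy.Tree.get(
        data="((s1,s2),a1);", schema="newick", preserve_underscores=True
    )
    tm = map_transitions(a, tree)
    M = binarize_pruned(tm, locus_length=4)
    assert M.S == 0


def test_binarize_hand_derived_sets_and_stats_integration():
    a = _aln(
        [
            ("s1", "AAAA", "sexual"),
            ("s2", "AATA", "sexual"),
            ("a1", "TAAA", "asexual"),
            ("a2", "TACA", "asexual"),
            ("a3", "GAAA", "asexual"),
            ("a4", "GAAA", "asexual"),  # same haplotype as a3
        ]
    )
    tree = dendropy.Tree.get(
        data="(((a1,a2),a3),(s1,s2));", schema="newick", preserve_underscores=True
    )
    tm = map_transitions(a, tree)
    M = binarize_pruned(tm, locus_length=4)
    # the stem mutation shared by every asexual is fixed among them and
    # dropped; what remains: the a1/a2 split (2/4) and a2's C (1/4);
    # the collapsed a3 haplotype expands back to two individual rows
    assert M.n == 4
    cols = sorted(M.derived_counts().tolist())
    assert cols == [1, 2]
    assert np.isfinite(tajimas_D(M))


def test_binarize_locus_length_guard():
    a = _aln(
        [
            ("s1", "AA", "sexual"),
            ("s2", "AT", "sexual"),
            ("a1", "TA", "asexual"),
            ("a2", "GC", "asexual"),
        ]
    )
    tree = dendropy.Tree.get(
        data="((a1,a2),(s1,s2));", schema="newick", preserve_underscores=True
    )
    tm = map_transitions(a, tree)
    with pytest.raises(ValueError, match="locus length"):
        binarize_pruned(tm, locus_length=1)


# --------------------------------------------------------------- MP search


def test_mp_tree_four_haplotypes_matches_exhaustive_oracle():
    """Additive 4-haplotype data: the returned topology attains the
    brute-force minimum over all 3 unrooted topologies."""
    a = _aln(
        [
            ("s1", "AAAAAAAA", "sexual"),
            ("s2", "TTAAAAAA", "sexual"),
            ("a1", "AATTAAAA", "asexual"),
            ("a2", "AATTTTAA", "asexual"),
        ]
    )
    states = dict(zip(a.ids, a.seqs))
    topos = ["((s1,s2),(a1,a2));", "((s1,a1),(s2,a2));", "((s1,a2),(s2,a1));"]
    lengths = {}
    for t in topos:
        dt = dendropy.Tree.get(data=t, schema="newick", preserve_underscores=True)
        lengths[t] = _brute_force_parsimony_length(dt, states)
    best_len = min(lengths.values())
    assert best_len == 6  # additive: branch changes 0+2 and 2+2 on the true tree

    tree = build_small_mp_tree(a)
    got_len = _brute_force_parsimony_length(tree, states)
    assert got_len == best_len
    # the (s1,s2) | (a1,a2) split is recovered
    taxa = {lf.taxon.label for lf in tree.leaf_node_iter()}
    assert taxa == {"s1", "s2", "a1", "a2"}


def test_mp_tree_three_haplotypes_length_invariant():
    a = _aln(
        [
            ("s1", "AAAA", "sexual"),
            ("a1", "ATAA", "asexual"),
            ("a2", "ATTA", "asexual"),
        ]
    )
    tree = build_small_mp_tree(a)
    states = dict(zip(a.ids, a.seqs))
    assert _brute_force_parsimony_length(tree, states) == 2


def test_mp_tree_tie_break_deterministic():
    a = _aln(
        [
            ("s1", "AAAA", "sexual"),
            ("s2", "ATAA", "sexual"),
            ("a1", "AATA", "asexual"),
            ("a2", "AAAT", "asexual"),
        ]
    )
    t1 = build_small_mp_tree(a).as_string(schema="newick")
    t2 = build_small_mp_tree(a).as_string(schema="newick")
    assert t1 == t2


def test_mp_tree_heuristic_beyond_exact_limit(rng):
    """>9 haplotypes falls back to hill climbing and still returns a tree
    whose length is no worse than a star-ish baseline."""
    base = "A" * 20
    seqs = []
    for i in range(11):
        s = list(base)
        s[i] = "T"
        if i % 2:
            s[12 + i % 4] = "G"
        seqs.append("".join(s))
    pairs = [(f"h{i}", s, "sexual" if i < 2 else "asexual") for i, s in enumerate(seqs)]
    a = _aln(pairs)
    tree = build_small_mp_tree(a, rng, restarts=3)
    assert len(list(tree.leaf_node_iter())) == 11


# ----------------------------------------------------------------- 4X rule


def test_four_x_rule_arithmetic():
    # diversity/divergence checked on a constructed two-cluster alignment:
    # clusters 10% apart, within-diversity 0.5% -> distinct species
    L = 200
    base = "A" * L
    far = "T" * 20 + "A" * (L - 20)  # 10% divergence

    def mutate(s, pos):
        lst = list(s)
        lst[pos] = "C"
        return "".join(lst)

    a = _aln(
        [
            ("x1", base, "asexual"),
            ("x2", mutate(base, 100), "asexual"),
            ("y1", far, "asexual"),
            ("y2", mutate(far, 150), "asexual"),
        ],
        clusters={"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"},
    )
    out = four_x_rule(a)
    assert len(out) == 1
    v = out[0]
    assert v["max_theta_pi"] == pytest.approx(0.005)
    assert v["divergence"] > 0.09
    assert v["distinct_species"] is True


def test_four_x_rule_not_distinct_when_close():
    L = 400
    base = "A" * L

    def mutate(s, *pos):
        lst = list(s)
        for p in pos:
            lst[p] = "C"
        return "".join(lst)

    near = mutate(base, 0, 1, 2, 3)  # 1% away; within-diversity 2/400=0.5%
    a = _aln(
        [
            ("x1", base, "asexual"),
            ("x2", mutate(base, 100, 101), "asexual"),
            ("y1", near, "asexual"),
            ("y2", mutate(near, 200, 201), "asexual"),
        ],
        clusters={"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"},
    )
    v = four_x_rule(a)[0]
    assert v["distinct_species"] is False  # d = ~1.25% < 4 x 0.5%


def test_four_x_rule_singleton_cluster_skipped():
    a = _aln(
        [
            ("x1", "AAAA", "asexual"),
            ("x2", "AATA", "asexual"),
            ("y1", "TTTT", "asexual"),
        ],
        clusters={"x1": "X", "x2": "X", "y1": "Y"},
    )
    with pytest.warns(UserWarning, match="singleton"):
        out = four_x_rule(a)
    assert out == []


# -------------------------------------------------- simulated-truth checks


def test_pruning_recovers_truth_on_fixture():
    """Site pruning keeps every true asexual-phase column and removes every
    sexual-phase column that segregates in the sexual sample."""
    spec = FixtureSpec(seed=42)
    fx = generate_complex_fixture(spec)
    a = LabeledAlignment.from_fasta(fx.fasta, fx.sample_sheet)
    pruned, rep = prune_by_sites(a)
    truth = {
        int(ln.split("\t")[0]): ln.split("\t")[1]
        for ln in fx.truth.strip().splitlines()[1:]
    }
    sex_ids = a.by_label("sexual")
    seqs = dict(zip(a.ids, a.seqs))
    for pos, phase in truth.items():
        col = {seqs[i][pos] for i in sex_ids}
        if phase == "asexual":
            assert pos not in rep.removed_columns  # never deleted
        elif len(col) > 1:  # sexual-phase, visible in the sexual sample
            assert pos in rep.removed_columns
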