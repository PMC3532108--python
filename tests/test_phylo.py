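"""Distances, neighbor joining, bootstrap, subfamilies and parsimony."""

import itertools
import math

import numpy as np
import pytest

from trimkit import phylo, synthetic
from trimkit.core_io import ValidationError, read_newick
from trimkit.phylo import (
    DistanceMatrix,
    SaturationError,
    SequenceAlignment,
    TreeNode,
    bootstrap_support,
    cut_subfamilies,
    enumerate_mprs,
    fitch_parsimony,
    neighbor_joining,
    tamura_nei_distance,
)


def _tn93_reference(a: str, b: str) -> float:
    """Independent evaluation of the TN93 closed form (per-pair frequencies)."""
    pairs = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
    n = len(pairs)
    from collections import Counter

    c = Counter()
    for x, y in pairs:
        c[x] += 1
        c[y] += 1
    gA, gC, gG, gT = (c[b] / (2 * n) for b in "ACGT")
    gR, gY = gA + gG, gC + gT
    p1 = sum({x, y} == {"A", "G"} for x, y in pairs) / n
    p2 = sum({x, y} == {"C", "T"} for x, y in pairs) / n
    q = sum(x != y and {x, y} not in ({"A", "G"}, {"C", "T"})
            for x, y in pairs) / n
    k1 = 2 * gA * gG / gR
    k2 = 2 * gC * gT / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    return (-k1 * math.log(1 - p1 / k1 - q / (2 * gR))
            - k2 * math.log(1 - p2 / k2 - q / (2 * gY))
            - k3 * math.log(1 - q / (2 * gR * gY)))


class TestTamuraNei:
    def test_identical_rows_are_zero(self):
        aln = SequenceAlignment(["a", "b"], ["ACGTACGT" * 10] * 2)
        assert tamura_nei_distance(aln).get("a", "b") == 0.0

    def test_matches_independent_formula(self):
        rng = np.random.default_rng(31)
        a = synthetic.make_internal_template(rng, 400)
        b = synthetic._evolve(a, 0.08, 2.0, rng)
        aln = SequenceAlignment(["a", "b"], [a, b])
        ours = tamura_nei_distance(aln).get("a", "b")
        assert ours == pytest.approx(_tn93_reference(a, b), abs=1e-12)

    def test_all_gap_column_leaves_distances_unchanged(self):
        rng = np.random.default_rng(32)
        a = synthetic.make_internal_template(rng, 200)
        b = synthetic._evolve(a, 0.05, 2.0, rng)
        plain = tamura_nei_distance(SequenceAlignment(["a", "b"], [a, b]))
        gapped = tamura_nei_distance(
            SequenceAlignment(["a", "b"], [a[:100] + "-" + a[100:],
                                           b[:100] + "-" + b[100:]]))
        assert gapped.get("a", "b") == pytest.approx(plain.get("a", "b"), abs=1e-15)

    def test_saturated_pair_names_the_pair(self):
        aln = SequenceAlignment(["near", "far"],
                                ["ACGT" * 25, "CAGC" * 25])
        with pytest.raises(SaturationError, match="near.*far|far.*near"):
            tamura_nei_distance(aln)


def _tree_distances(root: TreeNode) -> dict:
    return root.leaf_distances()


def _random_additive_matrix(rng: np.random.Generator, n: int):
    """Distance matrix generated from a random tree with positive branches."""
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.05, 0.3)))
             for i in range(n)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(length=float(rng.uniform(0.05, 0.3)),
                              children=[a, b]))
    root = TreeNode(children=nodes)
    pat = root.leaf_distances()
    labels = sorted(root.leaf_names())
    m = np.zeros((n, n))
    for (a, b), d in pat.items():
        i, j = labels.index(a), labels.index(b)
        m[i, j] = m[j, i] = d
    return root, DistanceMatrix(labels, m)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        m = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], m))
        lengths = {c.name: c.length for c in tree.children}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_additive_four_taxon_recovery(self):
        #    ((A:1,B:2):1,(C:3,D:4):1) as an unrooted additive metric
        labels = ["A", "B", "C", "D"]
        m = np.array([
            [0, 3, 6, 7],
            [3, 0, 7, 8],
            [6, 7, 0, 7],
            [7, 8, 7, 0],
        ], dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels, m))
        splits = tree.bipartitions()
        # the only non-trivial split of 4 taxa pairs A with B
        assert splits == {frozenset({"C", "D"})} or splits == {frozenset({"B", "A"})}
        pat = tree.leaf_distances()
        for (a, b) in itertools.combinations(labels, 2):
            i, j = labels.index(a), labels.index(b)
            assert pat[(min(a, b), max(a, b))] == pytest.approx(m[i, j])

    def test_additive_recovery_matches_generating_tree(self):
        rng = np.random.default_rng(44)
        for _ in range(10):
            source, dm = _random_additive_matrix(rng, 8)
            tree = neighbor_joining(dm)
            assert tree.bipartitions() == source.bipartitions()

    def test_agrees_with_dendropy_on_additive_input(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(45)
        source, dm = _random_additive_matrix(rng, 7)
        ours = neighbor_joining(dm)
        csv = "," + ",".join(dm.labels) + "\n" + "\n".join(
            l + "," + ",".join(map(str, dm.matrix[i]))
            for i, l in enumerate(dm.labels))
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=",")
        theirs_newick = pdm.nj_tree().as_string(schema="newick").replace("[&U] ", "")
        theirs = read_newick(theirs_newick)
        assert ours.bipartitions() == theirs.bipartitions()


class TestBootstrap:
    def test_identical_sequences_give_flat_tree(self):
        aln = SequenceAlignment([f"s{i}" for i in range(5)], ["ACGT" * 30] * 5)
        tree = bootstrap_support(aln, n_reps=20, seed=1)
        assert all((l.length or 0.0) == 0.0 for l in tree.postorder()
                   if l is not tree)

    def test_diagnostic_columns_give_high_support(self):
        rng = np.random.default_rng(52)
        core = synthetic.make_internal_template(rng, 200)
        # two clades separated by 50 fixed diagnostic columns
        mutant = list(core)
        for i in range(0, 100, 2):
            mutant[i] = {"A": "G", "G": "A", "C": "T", "T": "C"}[mutant[i]]
        mutant = "".join(mutant)
        rows = {
            "a1": core, "a2": synthetic._evolve(core, 0.01, 2.0, rng),
            "b1": mutant, "b2": synthetic._evolve(mutant, 0.01, 2.0, rng),
        }
        aln = SequenceAlignment(list(rows), list(rows.values()))
        tree = bootstrap_support(aln, n_reps=200, seed=2)
        supports = [n.support for n in tree.find_clades()]
        assert supports and min(supports) >= 99.0

    def test_same_seed_reproduces_supports(self):
        rng = np.random.default_rng(53)
        base = synthetic.make_internal_template(rng, 150)
        rows = {f"x{i}": synthetic._evolve(base, 0.05, 2.0, rng) for i in range(5)}
        aln = SequenceAlignment(list(rows), list(rows.values()))
        t1 = bootstrap_support(aln, n_reps=50, seed=9)
        t2 = bootstrap_support(aln, n_reps=50, seed=9)
        s1 = sorted(n.support for n in t1.find_clades())
        s2 = sorted(n.support for n in t2.find_clades())
        assert s1 == s2


class TestSubfamilies:
    def _clustered_alignment(self, n_clusters=4, per=4, seed=61):
        rng = np.random.default_rng(seed)
        root = synthetic.make_internal_template(rng, 500)
        rows = {}
        for c in range(n_clusters):
            founder = synthetic._evolve(root, 0.12, 2.0, rng)
            for i in range(per):
                rows[f"c{c}_{i}"] = synthetic._evolve(founder, 0.02, 2.0, rng)
        return SequenceAlignment(list(rows), list(rows.values()))

    def test_four_planted_clusters_recovered(self):
        aln = self._clustered_alignment()
        tree = bootstrap_support(aln, n_reps=100, seed=3)
        labels = cut_subfamilies(tree, min_support=70, max_within_distance=0.10)
        by_label = {}
        for leaf, lab in labels.items():
            by_label.setdefault(lab, set()).add(leaf)
        assert "unassigned" not in by_label
        assert len(by_label) == 4
        for members in by_label.values():
            assert len({m.split("_")[0] for m in members}) == 1

    def test_star_alignment_all_unassigned(self):
        rng = np.random.default_rng(62)
        root = synthetic.make_internal_template(rng, 400)
        rows = {f"s{i}": synthetic._evolve(root, 0.15, 2.0, rng) for i in range(6)}
        aln = SequenceAlignment(list(rows), list(rows.values()))
        tree = bootstrap_support(aln, n_reps=100, seed=4)
        labels = cut_subfamilies(tree, min_support=70, max_within_distance=0.05)
        assert set(labels.values()) == {"unassigned"}

    def test_outlier_left_unassigned(self):
        rng = np.random.default_rng(63)
        root = synthetic.make_internal_template(rng, 500)
        rows = {f"in{i}": synthetic._evolve(root, 0.02, 2.0, rng) for i in range(4)}
        rows["outlier"] = synthetic._evolve(root, 0.45, 1.0, rng)
        aln = SequenceAlignment(list(rows), list(rows.values()))
        tree = bootstrap_support(aln, n_reps=100, seed=5)
        labels = cut_subfamilies(tree, min_support=70, max_within_distance=0.10)
        assert labels["outlier"] == "unassigned"
        assert len({labels[k] for k in rows if k != "outlier"}) == 1


def _quartet(a, b, c, d):
    return TreeNode(children=[
        TreeNode(children=[TreeNode(name="A"), TreeNode(name="B")]),
        TreeNode(children=[TreeNode(name="C"), TreeNode(name="D")]),
    ])


class TestParsimony:
    def test_quartet_single_step_vs_enumeration(self):
        tree = _quartet("A", "B", "C", "D")
        char = {"A": 1, "B": 1, "C": 0, "D": 0}
        steps, sets = fitch_parsimony(tree, char)
        assert steps == 1
        # exhaustive oracle over all 2^3 internal assignments
        best = min(
            (int(l != root) + int(r != root)
             + int(a != l) + int(b != l) + int(c != r) + int(d != r))
            for root in (0, 1) for l in (0, 1) for r in (0, 1)
            for a, b, c, d in [(1, 1, 0, 0)]
        )
        assert steps == best

    def test_constant_character_is_zero_steps(self):
        tree = _quartet("A", "B", "C", "D")
        steps, _ = fitch_parsimony(tree, {l: 1 for l in "ABCD"})
        assert steps == 0
        recon = enumerate_mprs(tree, {l: 1 for l in "ABCD"})
        assert len(recon.mprs) == 1
        assert recon.gains_losses == [(0, 0)]

    def test_quartet_with_outgroup_mpr_is_single_gain(self):
        # rooting on a 0-state outgroup forces the gain onto the (A,B) stem
        tree = TreeNode(children=[
            _quartet("A", "B", "C", "D"), TreeNode(name="Out")])
        recon = enumerate_mprs(
            tree, {"A": 1, "B": 1, "C": 0, "D": 0, "Out": 0})
        assert recon.steps == 1
        assert recon.gains_losses == [(1, 0)]
        # the gain sits on the (A,B) stem in the unique MPR: every internal
        # node except mrca(A,B) is absent
        vec = recon.mprs[0]
        states = dict(zip(recon.node_order, vec))
        internal_present = [k for k, v in states.items()
                            if v == 1 and k.startswith("mrca")]
        assert internal_present == ["mrca(A,B)+0"]

    def test_every_mpr_realises_step_count(self):
        tree = phylo.load_host_tree()
        char = phylo.load_host_presence()
        recon = enumerate_mprs(tree, char)
        for g, l in recon.gains_losses:
            assert g + l == recon.steps

    def test_acctran_deltran_are_members_of_mpr_set(self):
        recon = enumerate_mprs(phylo.load_host_tree(), phylo.load_host_presence())
        assert recon.acctran in recon.mprs
        assert recon.deltran in recon.mprs

    def test_mpr_state_sets_match_fitch_sets(self):
        tree = phylo.load_host_tree()
        char = phylo.load_host_presence()
        _, sets = fitch_parsimony(tree, char)
        recon = enumerate_mprs(tree, char)
        assert sets == recon.mpr_sets

    def test_polytomy_rejected(self):
        tree = TreeNode(children=[TreeNode(name=n) for n in "ABC"])
        with pytest.raises(ValidationError, match="polytom"):
            fitch_parsimony(tree, {l: 0 for l in "ABC"})

    def test_missing_state_rejected(self):
        tree = _quartet("A", "B", "C", "D")
        with pytest.raises(ValidationError, match="D"):
            fitch_parsimony(tree, {"A": 1, "B": 0, "C": 1})


class TestHostFixture:
    def test_thirteen_taxa(self):
        tree = phylo.load_host_tree()
        presence = phylo.load_host_presence()
        assert len(list(tree.leaves())) == 13
        assert set(tree.leaf_names()) == set(presence)
        assert sum(presence.values()) == 7

    def test_outgroup_is_basal(self):
        tree = phylo.load_host_tree()
        names = [set(c.leaf_names()) if not c.is_leaf() else {c.name}
                 for c in tree.children]
        assert {"Apis_mellifera"} in names


class TestProgressiveAlign:
    def test_equal_length_passthrough(self):
        seqs = {"a": "ACGTACGT", "b": "ACTTACGT"}
        aln = phylo.progressive_align(seqs)
        assert aln.rows == ["ACGTACGT", "ACTTACGT"]

    def test_single_indel_recovered(self):
        rng = np.random.default_rng(71)
        base = synthetic.make_internal_template(rng, 120)
        seqs = {"a": base, "b": base[:60] + base[63:], "c": base}
        aln = phylo.progressive_align(seqs)
        assert len({len(r) for r in aln.rows}) == 1
        ra = dict(zip(aln.labels, aln.rows))
        assert ra["b"].count("-") == 3
        assert ra["a"].replace("-", "") == base
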