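import pytest

from causalpipe.errors import TreeMembershipError
from causalpipe.tree_features import (
    ConstituencyTree, ancestors, c_commands, collapse_path, command_features,
    lowest_common_ancestor, path_from_root, position_path, s_commands,
    vp_commands,
)

from conftest import leaf_by_surface
from oracles import command_oracle, lca_oracle, random_tree_source


class TestPaths:
    def test_single_leaf_path(self):
        tree = ConstituencyTree.from_string("(V suggest)")
        assert path_from_root(tree, tree.leaves[0]) == "V"

    def test_path_includes_preterminal(self):
        tree = ConstituencyTree.from_string("(S (VP (VP (V runs))))")
        assert path_from_root(tree, tree.leaves[0]) == "S/VP/VP/V"

    @pytest.mark.parametrize("path,expected", [
        ("S/VP/VP/V", "S/VP/V"),
        ("S", "S"),
        ("A/A/A/B/B/A", "A/B/A"),
    ])
    def test_collapse(self, path, expected):
        assert collapse_path(path) == expected

    def test_collapse_is_idempotent(self, rng):
        labels = ["S", "VP", "NP", "A", "B"]
        for _ in range(200):
            path = "/".join(rng.choice(labels)
                            for _ in range(rng.randint(1, 10)))
            once = collapse_path(path)
            assert collapse_path(once) == once

    def test_path_length_equals_depth(self, rng):
        for _ in range(30):
            tree = ConstituencyTree.from_string(random_tree_source(rng))
            for leaf in tree.leaves:
                depth = 0
                node = leaf
                while node.parent is not None:
                    depth += 1
                    node = node.parent
                assert len(path_from_root(tree, leaf).split("/")) == depth + 1


class TestPositionPath:
    def test_reconstructed_trigger_sentence(self, trigger_sentence_tree):
        that = leaf_by_surface(trigger_sentence_tree, "that")
        assert position_path(trigger_sentence_tree, that) == "I-S/I-VP/B-CP/C-CX"

    def test_single_leaf_is_sole_constituent(self):
        tree = ConstituencyTree.from_string("(V suggest)")
        assert position_path(tree, tree.leaves[0]) == "C-V"

    def test_prefix_stripping_matches_root_path(self, rng):
        """Stripping B/I/E/C prefixes yields the root path without the
        leaf's own preterminal step."""
        for _ in range(30):
            tree = ConstituencyTree.from_string(random_tree_source(rng))
            for leaf in tree.leaves:
                if leaf.parent is None:
                    continue
                stripped = [step.split("-", 1)[1]
                            for step in position_path(tree, leaf).split("/")]
                full = path_from_root(tree, leaf).split("/")
                assert stripped == full[:-1]


class TestAncestors:
    def test_reconstructed_sentence_ancestors(self, trigger_sentence_tree):
        that = leaf_by_surface(trigger_sentence_tree, "that")
        assert ancestors(trigger_sentence_tree, that, 3) == ["CX", "CP", "VP"]

    def test_sentinel_fills_past_root(self):
        tree = ConstituencyTree.from_string("(S (V v))")
        assert ancestors(tree, tree.leaves[0], 3) == ["S", "none", "none"]

    def test_excess_k_gives_exact_sentinel_count(self, rng):
        for _ in range(20):
            tree = ConstituencyTree.from_string(random_tree_source(rng))
            for leaf in tree.leaves:
                depth = len(leaf.ancestors())
                out = ancestors(tree, leaf, depth + 5)
                assert out[depth:] == ["none"] * 5
                assert "none" not in out[:depth]


class TestLCA:
    def test_reconstructed_sentence_lca(self, trigger_sentence_tree):
        that = leaf_by_surface(trigger_sentence_tree, "that")
        suggest = leaf_by_surface(trigger_sentence_tree, "suggest")
        node, dist = lowest_common_ancestor(trigger_sentence_tree, that, suggest)
        assert node.label == "VP"
        assert dist == 3  # P → CX → CP → VP

    def test_self_lca(self, trigger_sentence_tree):
        leaf = trigger_sentence_tree.leaves[0]
        node, dist = lowest_common_ancestor(trigger_sentence_tree, leaf, leaf)
        assert node is leaf and dist == 0

    def test_oracle_equivalence(self, rng):
        for _ in range(60):
            tree = ConstituencyTree.from_string(random_tree_source(rng))
            for a in tree.leaves:
                for b in tree.leaves:
                    node, dist = lowest_common_ancestor(tree, a, b)
                    onode, odist = lca_oracle(a, b)
                    assert node is onode and dist == odist

    def test_foreign_leaf_rejected(self, trigger_sentence_tree, command_toy_tree):
        with pytest.raises(TreeMembershipError):
            lowest_common_ancestor(trigger_sentence_tree, trigger_sentence_tree.leaves[0],
                                   command_toy_tree.leaves[0])


def _named(tree, label):
    for node in tree.nodes:
        if node.label == label:
            return node
    raise AssertionError(label)


class TestCommands:
    def test_toy_tree_mutual_commands(self, command_toy_tree):
        a, b = _named(command_toy_tree, "A"), _named(command_toy_tree, "B")
        c, d = _named(command_toy_tree, "C"), _named(command_toy_tree, "D")
        assert c_commands(command_toy_tree, a, b) and c_commands(command_toy_tree, b, a)
        assert c_commands(command_toy_tree, c, d) and c_commands(command_toy_tree, d, c)

    def test_no_self_command(self, command_toy_tree):
        for node in command_toy_tree.nodes:
            assert not c_commands(command_toy_tree, node, node)

    def test_sibling_symmetry(self, rng):
        """Under the relaxed definition, command between siblings is
        symmetric."""
        for _ in range(30):
            tree = ConstituencyTree.from_string(random_tree_source(rng))
            for node in tree.nodes:
                for x in node.children:
                    for y in node.children:
                        if x is y:
                            continue
                        assert c_commands(tree, x, y) == \
                            c_commands(tree, y, x)

    def test_label_restricted_implies_structural(self, rng):
        """S-/VP-command hold only when an S/VP ancestor exists and
        dominates the target."""
        for _ in range(20):
            tree = ConstituencyTree.from_string(random_tree_source(rng))
            nodes = tree.nodes
            for x in nodes:
                for y in nodes:
                    if s_commands(tree, x, y):
                        assert command_oracle(x, y, lambda n: n.label == "S")
                    if vp_commands(tree, x, y):
                        assert command_oracle(x, y, lambda n: n.label == "VP")

    def test_oracle_equivalence_exhaustive(self, rng):
        preds = [
            (c_commands, lambda n: len(n.children) > 1),
            (s_commands, lambda n: n.label == "S"),
            (vp_commands, lambda n: n.label == "VP"),
        ]
        for _ in range(40):
            tree = ConstituencyTree.from_string(random_tree_source(rng))
            nodes = tree.nodes
            for fn, pred in preds:
                for x in nodes:
                    for y in nodes:
                        assert fn(tree, x, y) == command_oracle(x, y, pred)


class TestCommandFeatures:
    def test_sibling_vp_sets_c2(self):
        tree = ConstituencyTree.from_string(
            "(S (ADVP (ADV thus)) (VP (V runs) (NP (NN it))))")
        thus = tree.leaves[0]
        flags = command_features(tree, thus)
        assert flags["C2"] and flags["C3"]

    def test_absent_sbar_clears_sbar_flags(self):
        tree = ConstituencyTree.from_string(
            "(S (NP (NN a)) (VP (V v) (NP (NN b))))")
        for leaf in tree.leaves:
            flags = command_features(tree, leaf)
            assert not flags["C1"] and not flags["C4"] and not flags["C7"]

    def test_flags_match_existential_oracle(self, rng):
        preds = {"c": lambda n: len(n.children) > 1,
                 "S": lambda n: n.label == "S",
                 "VP": lambda n: n.label == "VP"}
        targets = ("SBAR", "VP", "NP")
        for _ in range(30):
            tree = ConstituencyTree.from_string(random_tree_source(rng))
            nodes = tree.nodes
            for leaf in tree.leaves:
                flags = command_features(tree, leaf)
                idx = 1
                for pred in preds.values():
                    for target in targets:
                        expected = any(
                            n.label == target and command_oracle(leaf, n, pred)
                            for n in nodes)
                        assert flags[f"C{idx}"] == expected
                        idx += 1
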