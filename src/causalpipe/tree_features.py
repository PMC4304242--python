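"""Constituency-tree feature algebra.

Everything the pipeline derives from a bracketed parse lives here: root
paths, collapsed and position-encoded paths, bounded ancestor lists, lowest
common ancestors and the three command relations (c-command, S-command,
VP-command).

Tree shape
----------
A tree is rooted, ordered and labelled. *Leaves* are preterminal nodes: they
carry a syntactic category label (their ``label``), the surface word and,
once bound, a reference to the sentence token. The word part-of-speech tag
itself lives on the token layer, not the tree, mirroring deep-parser output
where a word has both a PoS (e.g. IN) and a lexical category (e.g. P).

Command relations
-----------------
We implement the relaxed command family: ``X commands Y`` iff the first
proper ancestor of X with the relevant property dominates Y, with no
non-co-dominance restriction and X itself excluded. For plain c-command the
property is "branching node"; for S-command / VP-command it is "label is
S / VP". Dominance is reflexive (every node dominates itself), so a node may
command its own dominators — a deliberate consequence of dropping the
co-dominance condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import FormatError, TreeMembershipError

NONE_SENTINEL = "none"

_VERB_LABELS = ("V", "VB", "VP")  # preterminal labels counting as verbal


@dataclass(eq=False)
class TreeNode:
    label: str
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = None
    surface: Optional[str] = None  # set on preterminals only
    token: Optional[object] = None  # bound Token, set on preterminals

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_branching(self) -> bool:
        return len(self.children) > 1

    def ancestors(self) -> list["TreeNode"]:
        """Proper ancestors from parent up to the root."""
        out = []
        node = self.parent
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    def root(self) -> "TreeNode":
        node = self
        while node.parent is not None:
            node = node.parent
        return node

    def dominates(self, other: "TreeNode") -> bool:
        """Reflexive dominance: a node dominates itself and its descendants."""
        node = other
        while node is not None:
            if node is self:
                return True
            node = node.parent
        return False

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        stack = [self]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    def descendants(self) -> list["TreeNode"]:
        out = []
        stack = list(self.children)
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out

    def __repr__(self):  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"({self.label} {self.surface})"
        return f"({self.label} …{len(self.children)})"


class ConstituencyTree:
    """A parsed sentence: single root, ordered leaves."""

    def __init__(self, root: TreeNode):
        self.root = root
        self.leaves: list[TreeNode] = root.leaves()

    @property
    def nodes(self) -> list[TreeNode]:
        return [self.root] + self.root.descendants()

    def bind_tokens(self, tokens: list) -> None:
        """Attach sentence tokens to leaves, in order."""
        if len(tokens) != len(self.leaves):
            raise FormatError(
                f"cannot bind {len(tokens)} tokens to {len(self.leaves)} leaves"
            )
        for leaf, tok in zip(self.leaves, tokens):
            leaf.token = tok

    def leaf_for(self, token_index: int) -> TreeNode:
        return self.leaves[token_index]

    def _check_member(self, *nodes: TreeNode) -> None:
        for node in nodes:
            if node.root() is not self.root:
                raise TreeMembershipError("node does not belong to this tree")

    # -- serialisation -------------------------------------------------

    @classmethod
    def from_string(cls, text: str) -> "ConstituencyTree":
        """Parse one bracketed tree, e.g. ``(S (NP (DT a) (NN cell)))``."""
        tokens = _lex_brackets(text)
        if not tokens:
            raise FormatError("empty parse string")
        pos = 0

        def parse_node() -> TreeNode:
            nonlocal pos
            if tokens[pos] != "(":
                raise FormatError(f"expected '(' at item {pos} of parse string")
            pos += 1
            if pos >= len(tokens) or tokens[pos] in "()":
                raise FormatError("missing node label in parse string")
            node = TreeNode(label=tokens[pos])
            pos += 1
            words = []
            while pos < len(tokens) and tokens[pos] != ")":
                if tokens[pos] == "(":
                    child = parse_node()
                    child.parent = node
                    node.children.append(child)
                else:
                    words.append(tokens[pos])
                    pos += 1
            if pos >= len(tokens):
                raise FormatError("unbalanced brackets in parse string")
            pos += 1  # consume ')'
            if words:
                if node.children:
                    raise FormatError(
                        f"node {node.label} mixes surface text and children"
                    )
                node.surface = " ".join(words)
            return node

        root = parse_node()
        if pos != len(tokens):
            raise FormatError("trailing content after parse tree")
        return cls(root)

    def to_string(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                return f"({node.label} {node.surface})"
            return "(" + node.label + " " + " ".join(
                render(c) for c in node.children) + ")"

        return render(self.root)


def _lex_brackets(text: str) -> list[str]:
    out = []
    word = []
    for ch in text:
        if ch in "()":
            if word:
                out.append("".join(word))
                word = []
            out.append(ch)
        elif ch.isspace():
            if word:
                out.append("".join(word))
                word = []
        else:
            word.append(ch)
    if word:
        out.append("".join(word))
    return out


# ---------------------------------------------------------------------------
# Path features
# ---------------------------------------------------------------------------

def path_from_root(tree: ConstituencyTree, leaf: TreeNode) -> str:
    """Category labels from the root down to and including the leaf's
    preterminal, ``/``-joined (e.g. ``S/VP/VP/V``)."""
    tree._check_member(leaf)
    labels = [n.label for n in reversed(leaf.ancestors())] + [leaf.label]
    return "/".join(labels)


def collapse_path(path: str) -> str:
    """Delete consecutive repetitions of the same category
    (``S/VP/VP/V`` → ``S/VP/V``)."""
    parts = path.split("/")
    out = [parts[0]]
    for p in parts[1:]:
        if p != out[-1]:
            out.append(p)
    return "/".join(out)


def position_path(tree: ConstituencyTree, leaf: TreeNode) -> str:
    """Root path over phrasal ancestors (the preterminal excluded), each
    label prefixed with the leaf's position among that ancestor's leaves:
    B(eginning), I(nside), E(nd), or C when the leaf is the constituent's
    only leaf."""
    tree._check_member(leaf)
    ancestors = list(reversed(leaf.ancestors()))
    if not ancestors:
        # single-node tree: the leaf is its own (sole) constituent
        return f"C-{leaf.label}"
    steps = []
    for anc in ancestors:
        anc_leaves = anc.leaves()
        if len(anc_leaves) == 1:
            prefix = "C"
        elif anc_leaves[0] is leaf:
            prefix = "B"
        elif anc_leaves[-1] is leaf:
            prefix = "E"
        else:
            prefix = "I"
        steps.append(f"{prefix}-{anc.label}")
    return "/".join(steps)


def ancestors(tree: ConstituencyTree, leaf: TreeNode, k: int) -> list[str]:
    """Nearest ``k`` ancestor labels of the leaf's preterminal, nearest
    first; positions past the root are filled with the sentinel ``none``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    tree._check_member(leaf)
    labels = [n.label for n in leaf.ancestors()]
    labels = labels[:k]
    return labels + [NONE_SENTINEL] * (k - len(labels))


def lowest_common_ancestor(
    tree: ConstituencyTree, leaf_a: TreeNode, leaf_b: TreeNode
) -> tuple[TreeNode, int]:
    """The deepest node dominating both leaves and the edge distance from
    ``leaf_a`` up to it. ``lca(x, x)`` is ``x`` itself at distance 0."""
    tree._check_member(leaf_a, leaf_b)
    if leaf_a is leaf_b:
        return leaf_a, 0
    chain_a = [leaf_a] + leaf_a.ancestors()
    seen = {id(n): d for d, n in enumerate(chain_a)}
    node = leaf_b
    while node is not None:
        if id(node) in seen:
            return node, seen[id(node)]
        node = node.parent
    raise TreeMembershipError("leaves share no ancestor")  # pragma: no cover


# ---------------------------------------------------------------------------
# Command relations
# ---------------------------------------------------------------------------

def _first_proper_ancestor(node: TreeNode, pred) -> Optional[TreeNode]:
    anc = node.parent
    while anc is not None:
        if pred(anc):
            return anc
        anc = anc.parent
    return None


def _commands(tree: ConstituencyTree, x: TreeNode, y: TreeNode, pred) -> bool:
    tree._check_member(x, y)
    if x is y:
        return False
    anc = _first_proper_ancestor(x, pred)
    if anc is None:
        return False
    return anc.dominates(y)


def c_commands(tree: ConstituencyTree, x: TreeNode, y: TreeNode) -> bool:
    """X c-commands Y iff the first branching proper ancestor of X
    dominates Y (relaxed definition, no co-dominance condition)."""
    return _commands(tree, x, y, lambda n: n.is_branching)


def s_commands(tree: ConstituencyTree, x: TreeNode, y: TreeNode) -> bool:
    """Like c-command but the commanding ancestor must be labelled S."""
    return _commands(tree, x, y, lambda n: n.label == "S")


def vp_commands(tree: ConstituencyTree, x: TreeNode, y: TreeNode) -> bool:
    """Like c-command but the commanding ancestor must be labelled VP."""
    return _commands(tree, x, y, lambda n: n.label == "VP")


_COMMAND_FNS = (("c", c_commands), ("S", s_commands), ("VP", vp_commands))
_COMMAND_TARGETS = ("SBAR", "VP", "NP")


def command_features(tree: ConstituencyTree, leaf: TreeNode) -> dict[str, bool]:
    """The nine command flags C1–C9: for each relation in {c, S, VP} and each
    target label in {SBAR, VP, NP}, whether the leaf commands at least one
    node with that label."""
    tree._check_member(leaf)
    # resolve each commanding ancestor once, then scan its subtree
    flags: dict[str, bool] = {}
    idx = 1
    for _, fn in _COMMAND_FNS:
        if fn is c_commands:
            anc = _first_proper_ancestor(leaf, lambda n: n.is_branching)
        elif fn is s_commands:
            anc = _first_proper_ancestor(leaf, lambda n: n.label == "S")
        else:
            anc = _first_proper_ancestor(leaf, lambda n: n.label == "VP")
        dominated_labels: set[str] = set()
        if anc is not None:
            dominated_labels.add(anc.label)
            for d in anc.descendants():
                if d is not leaf:
                    dominated_labels.add(d.label)
        for target in _COMMAND_TARGETS:
            flags[f"C{idx}"] = target in dominated_labels
            idx += 1
    return flags
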