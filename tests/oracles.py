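"""Independent brute-force oracles used to cross-check the implementation.

Each oracle computes its answer from first principles (dominance sets,
ancestor-chain intersection, literal run extraction, literal counting) and
never calls the code path it verifies.
"""

from __future__ import annotations

import random


# -- trees ------------------------------------------------------------------

def dominance_set(node):
    """All nodes dominated by ``node`` (reflexive), by literal traversal."""
    out = [node]
    stack = list(node.children)
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


def command_oracle(x, y, property_pred) -> bool:
    """Literal relaxed-command definition: the first proper ancestor of x
    with the property dominates y, x itself excluded."""
    if x is y:
        return False
    anc = x.parent
    while anc is not None and not property_pred(anc):
        anc = anc.parent
    if anc is None:
        return False
    return any(n is y for n in dominance_set(anc))


def lca_oracle(a, b):
    """Lowest common ancestor by full ancestor-chain intersection."""
    chain_a = [a]
    n = a
    while n.parent is not None:
        n = n.parent
        chain_a.append(n)
    chain_b = [b]
    n = b
    while n.parent is not None:
        n = n.parent
        chain_b.append(n)
    ids_b = {id(n) for n in chain_b}
    for dist, n in enumerate(chain_a):
        if id(n) in ids_b:
            return n, dist
    raise AssertionError("no common ancestor")


def random_tree_source(rng: random.Random, max_nodes: int = 25) -> str:
    """A random bracketed tree string with ≤ max_nodes nodes."""
    labels = ["S", "VP", "NP", "SBAR", "ADVP", "PP", "CP", "CX", "X"]
    pos = ["V", "NN", "DT", "P", "ADV", "CC"]
    budget = rng.randint(1, max_nodes)
    counter = [0]

    def build(depth) -> str:
        counter[0] += 1
        if counter[0] >= budget or depth > 5 or rng.random() < 0.3:
            return f"({rng.choice(pos)} w{counter[0]})"
        k = rng.randint(1, 3)
        children = " ".join(build(depth + 1) for _ in range(k))
        return f"({rng.choice(labels)} {children})"

    return build(0)


# -- BIO --------------------------------------------------------------------

def bio_runs_oracle(tags: list[str]) -> list[tuple[int, int, str]]:
    """Run extraction on an already BIO-consistent sequence: every maximal
    B..I run of one type becomes a span."""
    spans = []
    i = 0
    while i < len(tags):
        if tags[i].startswith("B"):
            ty = tags[i][1:].lstrip("-")
            j = i
            while j + 1 < len(tags) and tags[j + 1].startswith("I") \
                    and tags[j + 1][1:].lstrip("-") == ty:
                j += 1
            spans.append((i, j, ty))
            i = j + 1
        else:
            i += 1
    return spans


def repair_oracle(tags: list[str]) -> list[str]:
    """Literal BIO repair: I without a compatible open span becomes B."""
    out = []
    for i, tag in enumerate(tags):
        if tag.startswith("I"):
            ty = tag[1:]
            prev = out[-1] if out else "O"
            if prev == "O" or (prev[0] in "BI" and prev[1:] != ty):
                tag = "B" + ty
        out.append(tag)
    return out


# -- voting -----------------------------------------------------------------

def majority_oracle(votes: list[tuple[str, float]]) -> str:
    """Plain counting majority; ties resolved by mean confidence then
    first-seen order."""
    labels = [v[0] for v in votes]
    counts = {lab: labels.count(lab) for lab in labels}
    best = max(counts.values())
    tied = [lab for lab in dict.fromkeys(labels) if counts[lab] == best]
    if len(tied) == 1:
        return tied[0]
    means = {lab: sum(c for l2, c in votes if l2 == lab) / counts[lab]
             for lab in tied}
    top = max(means.values())
    for lab in tied:
        if means[lab] == top:
            return lab
    raise AssertionError
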