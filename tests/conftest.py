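import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from causalpipe.doc_model import (
    AnnotatedDocument, Sentence, SemanticLayer, Token,
)
from causalpipe.synthetic_corpus import GeneratorConfig, generate
from causalpipe.tree_features import ConstituencyTree

# The partial parse of a sentence starting with the causal trigger
# "Our results suggest that": reconstructed so that the token "that" has
# ancestors CX/CP/VP, lowest common ancestor VP with "suggest", and
# position path I-S/I-VP/B-CP/C-CX.
TRIGGER_SENTENCE_SOURCE = ("(S (NP (DT Our) (NN results)) "
               "(VP (V suggest) "
               "(CP (CX (P that)) "
               "(S (NP (DT the) (NN mutant)) "
               "(VP (V is) (ADJP (ADJ viable)))))))")

# The toy command-relation tree: A and B are siblings, C and D are siblings
# inside B, so A and B mutually c-command, as do C and D.
COMMAND_TOY_SOURCE = "(S (A (X x)) (B (C (Y y)) (D (Z z))))"


@pytest.fixture(scope="session")
def trigger_sentence_tree():
    return ConstituencyTree.from_string(TRIGGER_SENTENCE_SOURCE)


@pytest.fixture(scope="session")
def command_toy_tree():
    return ConstituencyTree.from_string(COMMAND_TOY_SOURCE)


def leaf_by_surface(tree, surface):
    for leaf in tree.leaves:
        if leaf.surface == surface:
            return leaf
    raise AssertionError(f"no leaf {surface!r}")


def make_plain_document(n_sentences=3, tokens_per_sentence=5,
                        doc_id="plain") -> AnnotatedDocument:
    """A minimal hand-built document without parses."""
    words = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta"]
    sentences = []
    offset = 0
    text_parts = []
    for s in range(n_sentences):
        toks = []
        for i in range(tokens_per_sentence):
            w = words[(s + i) % len(words)]
            toks.append(Token(index=i, surface=w, lemma=w, pos="NN",
                              start=offset, end=offset + len(w)))
            offset += len(w) + 1
        text_parts.append(" ".join(t.surface for t in toks))
        sentences.append(Sentence(index=s, tokens=toks))
    return AnnotatedDocument(doc_id=doc_id, text=" ".join(text_parts),
                             sentences=sentences,
                             semantics=SemanticLayer())


@pytest.fixture(scope="session")
def small_corpus():
    """A small parsed, annotated corpus (deterministic)."""
    docs, truth = generate(
        GeneratorConfig(n_documents=10, sentences_per_document=12), seed=17)
    return docs, truth


@pytest.fixture(scope="session")
def rng():
    return random.Random(20240901)


@pytest.fixture(scope="session")
def study_corpus():
    """The planted-recovery study corpus: 50 documents, ~15k tokens,
    trigger rarity 1:50, ambiguity present."""
    return generate(GeneratorConfig(), seed=101)


@pytest.fixture(scope="session")
def trained_pipeline(study_corpus):
    """Pipeline trained on the first half of the study corpus."""
    from causalpipe.pipeline import CausalPipeline

    docs, _truth = study_corpus
    train = docs[:len(docs) // 2]
    return CausalPipeline().fit(train)
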