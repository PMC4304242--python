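import random

import pytest

from causalpipe.doc_model import (
    AnnotatedDocument, Sentence, SemanticLayer, Span, Token, TypedSpan,
)
from causalpipe.errors import StageError, StagingError
from causalpipe.feature_extraction import (
    FEATURES, SENTINEL, allowed, base_id, main_verb, pipeline_flags,
    semantic_features, to_sparse_line, token_features, trigger_features,
    voice,
)
from causalpipe.io_standoff import read_bracketed_tree


def _doc_from_layers(words_pos, parse, doc_id="fx"):
    """Build a one-sentence document from (surface, pos) pairs and a
    bracketed parse."""
    toks, off = [], 0
    for i, (w, pos) in enumerate(words_pos):
        toks.append(Token(index=i, surface=w, lemma=w.lower(), pos=pos,
                          start=off, end=off + len(w)))
        off += len(w) + 1
    sent = Sentence(index=0, tokens=toks)
    tree = read_bracketed_tree(parse)
    tree.bind_tokens(toks)
    sent.tree = tree
    return AnnotatedDocument(doc_id=doc_id,
                             text=" ".join(w for w, _ in words_pos),
                             sentences=[sent], semantics=SemanticLayer())


@pytest.fixture(scope="module")
def example_doc():
    # "SsrB binds within SPI-2 and activates genes ."
    words = [("SsrB", "NN"), ("binds", "VBZ"), ("within", "IN"),
             ("SPI-2", "NN"), ("and", "CC"), ("activates", "VBZ"),
             ("genes", "NNS"), (".", ".")]
    parse = ("(S (NP (NN SsrB)) "
             "(VP (VP (V binds) (PP (P within) (NP (NN SPI-2)))) "
             "(CC and) (VP (V activates) (NP (NN genes)))) (. .))")
    return _doc_from_layers(words, parse)


class TestStageMasks:
    def test_ts_vector_has_no_trigger_or_flag_features(self, example_doc):
        vec = token_features(example_doc, 0, 4, "TS")
        for key in vec:
            assert allowed(key, "TS"), key
            assert base_id(key) not in {"X11", "X12", "X13", "X14", "X15",
                                        "X16", "X17", "S8", "S9"}

    def test_as_vector_carries_pipeline_flag_and_main_verb(self, example_doc):
        vec = token_features(example_doc, 0, 4, "AS",
                             predicted_triggers={(0, 4)})
        assert vec["S8"] is True
        assert "X16" in vec
        for key in vec:
            assert allowed(key, "AS"), key

    def test_ap_vector_within_mask(self, example_doc):
        vec = trigger_features(example_doc, Span(0, 4, 4), "AP")
        for key in vec:
            assert allowed(key, "AP"), key
        assert "S9" not in vec and "X17" not in vec

    def test_ar_vector_contains_s9_and_voice(self, example_doc):
        vec = trigger_features(example_doc, Span(0, 4, 4), "AR",
                               predicted_dep_tokens={(0, 5), (0, 6)})
        assert vec["S9"] is True
        assert "X17" in vec
        for key in vec:
            assert allowed(key, "AR"), key

    def test_unknown_stage_rejected(self, example_doc):
        with pytest.raises(StageError):
            token_features(example_doc, 0, 0, "XX")
        with pytest.raises(StageError):
            trigger_features(example_doc, Span(0, 4, 4), "TS")

    def test_registry_matches_stage_columns(self):
        # spot checks of the applicability matrix
        assert FEATURES["L1"][1] == frozenset({"TS", "AP", "AS", "AR"})
        assert FEATURES["X5"][1] == frozenset({"TS"})
        assert FEATURES["X16"][1] == frozenset({"AS"})
        assert FEATURES["X17"][1] == frozenset({"AR"})
        assert FEATURES["S9"][1] == frozenset({"AR"})


class TestLexicalAndPositional:
    def test_sentence_initial_left_window_is_sentinel(self, example_doc):
        vec = token_features(example_doc, 0, 0, "TS")
        for k in range(1, 6):
            assert vec[f"L3.l{k}"] == SENTINEL
            assert vec[f"L4.l{k}"] == SENTINEL

    def test_left_neighbour_surface(self, example_doc):
        vec = token_features(example_doc, 0, 4, "TS")
        assert vec["L3.l1"] == "SPI-2"
        assert vec["L3.r1"] == "activates"

    def test_relative_position_arithmetic(self):
        words = [(f"w{i}", "NN") for i in range(10)]
        parse = "(S " + " ".join(f"(NN w{i})" for i in range(10)) + ")"
        doc = _doc_from_layers(words, parse)
        vec = token_features(doc, 0, 3, "TS")
        assert vec["P1"] == 3
        assert vec["P2"] == pytest.approx(0.3)
        assert vec["P3"] == "Middle"
        assert vec["P4"] == 10

    def test_p3_edges(self, example_doc):
        first = token_features(example_doc, 0, 0, "TS")
        last = token_features(example_doc, 0, 7, "TS")
        assert first["P3"] == "Beginning" and last["P3"] == "End"

    def test_extraction_is_deterministic(self, example_doc):
        a = token_features(example_doc, 0, 4, "TS")
        b = token_features(example_doc, 0, 4, "TS")
        assert a == b


class TestTriggerVectors:
    def test_pos_string_duplicate_collapse(self):
        words = [("These", "DT"), ("results", "NN"), ("show", "V"),
                 ("clearly", "V"), ("that", "DT"), ("it", "NN"),
                 ("works", "VBZ")]
        parse = ("(S (X (DT These) (NN results) (V show) (V clearly) "
                 "(DT that)) (NP (NN it)) (V works))")
        doc = _doc_from_layers(words, parse)
        vec = trigger_features(doc, Span(0, 0, 4), "AP")
        assert vec["X11"] == "DT-NN-V-V-DT"
        assert vec["X13"] == "DT-NN-V-DT"

    def test_capitalised_initial_trigger(self):
        words = [("Thus", "RB"), (",", ","), ("it", "NN"), ("works", "VBZ")]
        parse = "(S (ADVP (ADV Thus)) (, ,) (NP (NN it)) (V works))"
        doc = _doc_from_layers(words, parse)
        vec = trigger_features(doc, Span(0, 0, 0), "AP")
        assert vec["L5"] is True
        assert vec["P3"] == "Beginning"

    def test_single_token_trigger_strings_coincide(self, example_doc):
        vec = trigger_features(example_doc, Span(0, 4, 4), "AP")
        assert vec["X11"] == example_doc.sentences[0].tokens[4].pos
        assert vec["X13"] == vec["X11"]


class TestVerbFeatures:
    def test_main_verb_of_single_vp(self):
        words = [("it", "NN"), ("works", "VBZ")]
        parse = "(S (NP (NN it)) (VP (V works)))"
        doc = _doc_from_layers(words, parse)
        mv = main_verb(doc.sentences[0])
        # exhaustive search oracle: the unique verbal leaf
        assert mv is not None and mv.surface == "works"

    def test_passive_trigger_voice(self):
        words = [("this", "DT"), ("is", "VBZ"), ("supported", "VBN"),
                 ("by", "IN"), ("data", "NN")]
        parse = ("(S (NP (DT this)) (VP (V is) (VP (V supported) "
                 "(PP (P by) (NP (NN data))))))")
        doc = _doc_from_layers(words, parse)
        # lemma of "is" must be "be" for the auxiliary test
        toks = doc.sentences[0].tokens
        object.__setattr__(toks[1], "lemma", "be")
        assert voice(doc.sentences[0], Span(0, 1, 3)) == "passive"

    def test_verbless_trigger(self):
        words = [("Since", "IN"), ("it", "NN"), ("works", "VBZ")]
        parse = "(S (SBAR (P Since) (S (NP (NN it)) (VP (V works)))))"
        doc = _doc_from_layers(words, parse)
        sent = doc.sentences[0]
        assert voice(sent, Span(0, 0, 0)) == "none"
        vec = trigger_features(doc, Span(0, 0, 0), "AP")
        assert vec["X15"] is False


class TestSemanticLayer:
    def test_entity_membership_and_type(self, example_doc):
        example_doc.semantics.entities = [
            TypedSpan(span=Span(0, 0, 0), type="Bacterium")]
        vec = semantic_features(example_doc, 0, 0)
        assert vec["S1"] is True and vec["S2"] == "Bacterium"
        example_doc.semantics.entities = []

    def test_empty_layer_all_sentinel(self, example_doc):
        vec = semantic_features(example_doc, 0, 1)
        assert vec["S1"] is False and vec["S2"] == SENTINEL
        assert vec["S3"] is False and vec["S6"] is False

    def test_thirty_span_containment_oracle(self):
        words = [(f"w{i}", "NN") for i in range(40)]
        parse = "(S " + " ".join(f"(NN w{i})" for i in range(40)) + ")"
        doc = _doc_from_layers(words, parse)
        rng = random.Random(5)
        spans = []
        for _ in range(30):
            a = rng.randrange(40)
            b = min(39, a + rng.randrange(3))
            spans.append(TypedSpan(span=Span(0, a, b),
                                   type=rng.choice(["A", "B"])))
        doc.semantics.entities = spans
        for i in range(40):
            vec = semantic_features(doc, 0, i)
            covering = [ts for ts in spans if ts.span.first <= i <= ts.span.last]
            assert vec["S1"] == bool(covering)
            if covering:
                assert vec["S2"] == covering[0].type


class TestPipelineFlags:
    def test_trigger_membership(self, example_doc):
        vec = pipeline_flags(example_doc, 0, 4, "AS",
                             predicted_triggers={(0, 4)})
        assert vec["S8"] is True

    def test_outside_all_predictions(self, example_doc):
        vec = pipeline_flags(example_doc, 0, 1, "AR",
                             predicted_triggers=set(),
                             predicted_dep_tokens=set())
        assert vec["S8"] is False and vec["S9"] is False

    def test_s9_before_span_stage_is_staging_error(self, example_doc):
        with pytest.raises(StagingError):
            pipeline_flags(example_doc, 0, 1, "AR",
                           predicted_triggers=set())

    def test_dep_arg_tokens_flagged_exactly(self, example_doc):
        dep = {(0, 5), (0, 6)}
        for i in range(8):
            vec = pipeline_flags(example_doc, 0, i, "AR",
                                 predicted_triggers={(0, 4)},
                                 predicted_dep_tokens=dep)
            assert vec["S9"] == ((0, i) in dep)


def test_sparse_serialisation_is_deterministic(example_doc):
    vec = token_features(example_doc, 0, 4, "TS")
    line = to_sparse_line("fx:0:4", vec)
    assert line.startswith("fx:0:4 ")
    assert line == to_sparse_line("fx:0:4", dict(reversed(list(vec.items()))))
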