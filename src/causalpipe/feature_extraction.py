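"""Per-stage feature vectors.

Six feature families feed the four pipeline stages (TS trigger span
detection, AP argument position, AS argument span, AR argument role):

* lexical (L1–L5): surface, lemma, ±5 neighbour windows, trigger
  capitalisation;
* syntactic (X1–X17): PoS and category of token and neighbours, root paths
  (plain, collapsed, position-encoded), bounded ancestors, lowest common
  ancestor with the left neighbour and its distance, trigger PoS/category
  strings with duplicate collapsing, main-verb containment, voice;
* dependency (D1a/D1b/D2/D3): predicate-argument links of the token, their
  roles, PoS and distances;
* command (C1–C9): c-/S-/VP-command of SBAR/VP/NP targets;
* semantic (S1–S9): named-entity and event membership and types, dictionary
  hypernym and concept type, plus the pipeline flags "is a predicted
  trigger" (S8) and "is in the predicted dependent argument" (S9);
* positional (P1–P4): index, relative index, coarse position, sentence
  length.

Each family member carries a stage mask; a vector only ever contains
features enabled for the requesting stage, and missing context is encoded
with an explicit sentinel rather than omitted.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .doc_model import AnnotatedDocument, Sentence, Span, Token
from .errors import SpanError, StageError, StagingError
from . import tree_features as tf

SENTINEL = "NONE"
STAGES = ("TS", "AP", "AS", "AR")

_ALL = frozenset(STAGES)
_TS_AS = frozenset({"TS", "AS"})
_AP_AR = frozenset({"AP", "AR"})

#: feature id -> (description, stages in which it may appear)
FEATURES: dict[str, tuple[str, frozenset]] = {
    "L1": ("token surface / trigger surface string", _ALL),
    "L2": ("lemma of L1", _ALL),
    "L3": ("neighbour tokens, 5 left + 5 right", _ALL),
    "L4": ("lemmas of L3", _ALL),
    "L5": ("trigger starts with a capital letter", frozenset({"AP", "AS", "AR"})),
    "X1": ("part of speech of token", _TS_AS),
    "X2": ("syntactic category of token", _TS_AS),
    "X3": ("part of speech of neighbours", _TS_AS),
    "X4": ("syntactic category of neighbours", _TS_AS),
    "X5": ("category path from root", frozenset({"TS"})),
    "X6": ("collapsed category path from root", frozenset({"TS"})),
    "X7": ("position-encoded category path from root", frozenset({"TS"})),
    "X8": ("ancestor categories to the third degree", frozenset({"TS"})),
    "X9": ("lowest common ancestor with left neighbour", frozenset({"TS"})),
    "X10": ("edge distance to X9", frozenset({"TS"})),
    "X11": ("PoS string of trigger", _AP_AR),
    "X12": ("category string of trigger", _AP_AR),
    "X13": ("X11 with consecutive duplicates collapsed", _AP_AR),
    "X14": ("X12 with consecutive duplicates collapsed", _AP_AR),
    "X15": ("trigger contains the sentence's main verb", _AP_AR),
    "X16": ("main verb of the sentence", frozenset({"AS"})),
    "X17": ("voice of the trigger's verb", frozenset({"AR"})),
    "D1a": ("predicate-argument partners (surface)", _TS_AS),
    "D1b": ("predicate-argument roles", _TS_AS),
    "D2": ("PoS of D1a partners", _TS_AS),
    "D3": ("token distance to D1a partners", _TS_AS),
    **{f"C{i}": (desc, _TS_AS) for i, desc in enumerate(
        ["c-commands an SBAR", "c-commands a VP", "c-commands an NP",
         "S-commands an SBAR", "S-commands a VP", "S-commands an NP",
         "VP-commands an SBAR", "VP-commands a VP", "VP-commands an NP"],
        start=1)},
    "S1": ("token is inside a named entity", _TS_AS),
    "S2": ("named entity type", _TS_AS),
    "S3": ("token is inside an event trigger", _TS_AS),
    "S4": ("event type", _TS_AS),
    "S5": ("first-sense hypernym", _TS_AS),
    "S6": ("token has a concept-dictionary type", _TS_AS),
    "S7": ("concept-dictionary type", _TS_AS),
    "S8": ("token was predicted to be a trigger", frozenset({"AP", "AS", "AR"})),
    "S9": ("token was predicted inside the dependent argument",
           frozenset({"AR"})),
    "P1": ("index of token in sentence", _ALL),
    "P2": ("relative index of token in sentence", _ALL),
    "P3": ("coarse position: Beginning / Middle / End", _ALL),
    "P4": ("sentence length", _ALL),
}


def base_id(feature_key: str) -> str:
    """``"L3.l2"`` → ``"L3"``; used to check stage masks."""
    return feature_key.split(".", 1)[0]


def allowed(feature_key: str, stage: str) -> bool:
    return stage in FEATURES[base_id(feature_key)][1]


def _check_stage(stage: str, permitted: Iterable[str]) -> None:
    if stage not in STAGES:
        raise StageError(f"unknown stage {stage!r}")
    if stage not in permitted:
        raise StageError(f"stage {stage} not valid here (expected one of "
                         f"{sorted(permitted)})")


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def _neighbour_window(sent: Sentence, index: int, width: int = 5) -> dict:
    """L3/L4/X3/X4 neighbour slots, sentinel-padded at sentence edges.
    Windows never cross sentence boundaries."""
    out = {}
    for off in range(1, width + 1):
        for side, j in (("l", index - off), ("r", index + off)):
            if 0 <= j < len(sent.tokens):
                tok = sent.tokens[j]
                surface, lemma, pos = tok.surface, tok.lemma, tok.pos
                cat = (sent.tree.leaf_for(j).label
                       if sent.tree is not None else SENTINEL)
            else:
                surface = lemma = pos = cat = SENTINEL
            out[f"L3.{side}{off}"] = surface
            out[f"L4.{side}{off}"] = lemma
            out[f"X3.{side}{off}"] = pos
            out[f"X4.{side}{off}"] = cat
    return out


def positional_features(sent: Sentence, index: int,
                        p3_scheme: str = "edges") -> dict:
    """P1–P4. The coarse position P3 uses the sentence edges by default
    (first token = Beginning, last = End); ``p3_scheme="thirds"`` switches
    to a thirds-based discretisation."""
    n = len(sent.tokens)
    if p3_scheme == "thirds":
        frac = index / n
        p3 = "Beginning" if frac < 1 / 3 else ("End" if frac >= 2 / 3 else "Middle")
    else:
        p3 = ("Beginning" if index == 0
              else "End" if index == n - 1 else "Middle")
    return {"P1": index, "P2": index / n, "P3": p3, "P4": n}


def dependency_features(sent: Sentence, index: int, max_arcs: int = 3) -> dict:
    """D1a/D1b/D2/D3 from the predicate-argument arcs headed by the token."""
    out = {}
    arcs = sent.arcs_with_head(index)[:max_arcs]
    for k in range(1, max_arcs + 1):
        if k <= len(arcs):
            arc = arcs[k - 1]
            partner = sent.tokens[arc.dep]
            out[f"D1a.{k}"] = partner.surface
            out[f"D1b.{k}"] = arc.label
            out[f"D2.{k}"] = partner.pos
            out[f"D3.{k}"] = abs(arc.dep - index)
        else:
            out[f"D1a.{k}"] = SENTINEL
            out[f"D1b.{k}"] = SENTINEL
            out[f"D2.{k}"] = SENTINEL
            out[f"D3.{k}"] = 0
    return out


def semantic_features(doc: AnnotatedDocument, sentence_index: int,
                      token_index: int) -> dict:
    """S1–S7 from the semantic layer. Booleans by span containment; types
    and hypernyms fall back to the sentinel."""
    sem = doc.semantics
    tok = doc.sentence(sentence_index).tokens[token_index]
    ne_type = sem.entity_type_at(sentence_index, token_index)
    ev_type = sem.event_type_at(sentence_index, token_index)
    hyper = sem.hypernym(tok.lemma)
    concept = sem.concept(tok.lemma)
    return {
        "S1": ne_type is not None,
        "S2": ne_type if ne_type is not None else SENTINEL,
        "S3": ev_type is not None,
        "S4": ev_type if ev_type is not None else SENTINEL,
        "S5": hyper if hyper is not None else SENTINEL,
        "S6": concept is not None,
        "S7": concept if concept is not None else SENTINEL,
    }


def pipeline_flags(doc: AnnotatedDocument, sentence_index: int,
                   token_index: int, stage: str,
                   predicted_triggers: Optional[set] = None,
                   predicted_dep_tokens: Optional[set] = None) -> dict:
    """S8/S9: decisions of earlier pipeline stages, as token flags.

    ``predicted_triggers`` / ``predicted_dep_tokens`` are sets of
    ``(sentence_index, token_index)`` pairs. Passing ``None`` means the
    producing stage has not run, which is a staging error.
    """
    _check_stage(stage, ("AP", "AS", "AR"))
    if predicted_triggers is None:
        raise StagingError("S8 queried before trigger detection has run")
    out = {"S8": (sentence_index, token_index) in predicted_triggers}
    if stage == "AR":
        if predicted_dep_tokens is None:
            raise StagingError("S9 queried before argument span "
                               "identification has run")
        out["S9"] = (sentence_index, token_index) in predicted_dep_tokens
    return out


# ---------------------------------------------------------------------------
# Syntax helpers: main verb and voice
# ---------------------------------------------------------------------------

_VERBAL = ("V", "VB")


def _is_verbal_label(label: str) -> bool:
    return label == "V" or label.startswith("VB")


def main_verb(sent: Sentence) -> Optional[Token]:
    """The verbal leaf of the highest VP on the root's spine.

    Head percolation: take the shallowest VP (breadth-first, leftmost on
    ties); inside it prefer a direct verbal preterminal child, else recurse
    into a child VP, else take the leftmost verbal leaf of the subtree.
    """
    if sent.tree is None:
        return None
    queue = [sent.tree.root]
    vp = None
    while queue:
        node = queue.pop(0)
        if node.label == "VP":
            vp = node
            break
        queue.extend(node.children)
    if vp is None:
        return None
    node = vp
    while True:
        direct = [c for c in node.children
                  if c.is_leaf and _is_verbal_label(c.label)]
        if direct:
            return direct[0].token
        nested = [c for c in node.children if c.label == "VP"]
        if nested:
            node = nested[0]
            continue
        verbal = [lf for lf in node.leaves() if _is_verbal_label(lf.label)]
        return verbal[0].token if verbal else None


def contains_main_verb(sent: Sentence, span: Span) -> bool:
    mv = main_verb(sent)
    return mv is not None and span.first <= mv.index <= span.last


def voice(sent: Sentence, span: Span) -> str:
    """``passive`` iff the span's verb is a past participle with a
    be-lemma auxiliary among its dependency links (or immediately to its
    left when no arcs are available); ``active`` for other verbs; ``none``
    when the span contains no verb."""
    verbs = [sent.tokens[i] for i in span.tokens()
             if sent.tokens[i].pos.startswith("V")]
    if not verbs:
        return "none"
    for verb in verbs:
        if verb.pos != "VBN":
            continue
        linked = {a.head for a in sent.arcs_with_dep(verb.index)}
        linked |= {a.dep for a in sent.arcs_with_head(verb.index)}
        if any(sent.tokens[j].lemma == "be" for j in linked):
            return "passive"
        if not sent.arcs and verb.index > 0 \
                and sent.tokens[verb.index - 1].lemma == "be":
            return "passive"
    return "active"


# ---------------------------------------------------------------------------
# Stage vectors
# ---------------------------------------------------------------------------

def token_features(doc: AnnotatedDocument, sentence_index: int,
                   token_index: int, stage: str,
                   predicted_triggers: Optional[set] = None,
                   p3_scheme: str = "edges") -> dict:
    """The token-instance vector for the TS and AS stages."""
    _check_stage(stage, ("TS", "AS"))
    sent = doc.sentence(sentence_index)
    if not 0 <= token_index < len(sent.tokens):
        raise SpanError(f"token index {token_index} out of range")
    tok = sent.tokens[token_index]

    vec = {"L1": tok.surface, "L2": tok.lemma, "X1": tok.pos}
    vec.update(_neighbour_window(sent, token_index))
    tree = sent.tree
    leaf = tree.leaf_for(token_index) if tree is not None else None
    vec["X2"] = leaf.label if leaf is not None else SENTINEL

    if stage == "TS" and tree is not None:
        x5 = tf.path_from_root(tree, leaf)
        vec["X5"] = x5
        vec["X6"] = tf.collapse_path(x5)
        vec["X7"] = tf.position_path(tree, leaf)
        for i, label in enumerate(tf.ancestors(tree, leaf, 3), start=1):
            vec[f"X8.{i}"] = label
        if token_index > 0:
            lca, dist = tf.lowest_common_ancestor(
                tree, leaf, tree.leaf_for(token_index - 1))
            vec["X9"] = lca.label
            vec["X10"] = dist
        else:
            vec["X9"] = SENTINEL
            vec["X10"] = 0

    vec.update(dependency_features(sent, token_index))
    if tree is not None:
        vec.update(tf.command_features(tree, leaf))
    else:
        vec.update({f"C{i}": False for i in range(1, 10)})
    vec.update(semantic_features(doc, sentence_index, token_index))
    vec.update(positional_features(sent, token_index, p3_scheme))

    if stage == "AS":
        vec.update(pipeline_flags(doc, sentence_index, token_index, "AS",
                                  predicted_triggers=predicted_triggers))
        mv = main_verb(sent)
        vec["X16"] = mv.surface if mv is not None else SENTINEL
        trig_here = sorted(t for t in predicted_triggers
                           if t[0] == sentence_index)
        if trig_here:
            first = sent.tokens[trig_here[0][1]]
            vec["L5"] = first.surface[:1].isupper()
        else:
            vec["L5"] = False
    return vec


def _dedup(parts: list[str]) -> list[str]:
    out = [parts[0]]
    for p in parts[1:]:
        if p != out[-1]:
            out.append(p)
    return out


def trigger_features(doc: AnnotatedDocument, trigger: Span, stage: str,
                     predicted_dep_tokens: Optional[set] = None,
                     p3_scheme: str = "edges") -> dict:
    """The trigger-instance vector for the AP and AR stages.

    ``predicted_dep_tokens`` (set of ``(sentence, token)`` pairs) is
    required for AR, where the dependent-argument flag S9 is part of the
    vector.
    """
    _check_stage(stage, ("AP", "AR"))
    toks = doc.slice(trigger)
    if not toks:
        raise SpanError("empty trigger span")
    sent = doc.sentence(trigger.sentence)

    pos_parts = [t.pos for t in toks]
    if sent.tree is not None:
        cat_parts = [sent.tree.leaf_for(i).label for i in trigger.tokens()]
    else:
        cat_parts = [SENTINEL] * len(toks)

    vec = {
        "L1": " ".join(t.surface for t in toks),
        "L2": " ".join(t.lemma for t in toks),
        "L5": toks[0].surface[:1].isupper(),
        "X11": "-".join(pos_parts),
        "X12": "-".join(cat_parts),
        "X13": "-".join(_dedup(pos_parts)),
        "X14": "-".join(_dedup(cat_parts)),
        "X15": contains_main_verb(sent, trigger),
    }
    # neighbour windows flank the whole span
    left = _neighbour_window(sent, trigger.first)
    right = _neighbour_window(sent, trigger.last)
    for off in range(1, 6):
        for fid in ("L3", "L4"):
            vec[f"{fid}.l{off}"] = left[f"{fid}.l{off}"]
            vec[f"{fid}.r{off}"] = right[f"{fid}.r{off}"]
    vec.update(positional_features(sent, trigger.first, p3_scheme))

    if stage == "AR":
        vec["X17"] = voice(sent, trigger)
        if predicted_dep_tokens is None:
            raise StagingError("S9 queried before argument span "
                               "identification has run")
        vec["S9"] = bool(predicted_dep_tokens)
        same = [t for t in predicted_dep_tokens if t[0] == trigger.sentence]
        if same:
            vec["S9.side"] = ("after" if min(i for _, i in same) > trigger.last
                              else "before")
        else:
            vec["S9.side"] = "other_sentence"
    return vec


# ---------------------------------------------------------------------------
# Sparse attribute-value serialisation
# ---------------------------------------------------------------------------

def to_sparse_line(instance_id: str, vec: dict) -> str:
    """``id feature=value ...`` with deterministic feature order."""
    parts = [instance_id]
    for key in sorted(vec):
        value = vec[key]
        if isinstance(value, bool):
            value = int(value)
        parts.append(f"{key}={value}")
    return " ".join(parts)


def write_vectors(instances: list[tuple[str, dict]]) -> str:
    return "\n".join(to_sparse_line(i, v) for i, v in instances) + "\n"
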