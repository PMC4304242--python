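"""Synthetic causally-annotated corpus generator.

Produces fully parsed, semantically layered documents whose causal
annotations follow the corpus statistics the pipeline is designed around:

* trigger-token rarity ≈ 1 positive per 50 negative tokens;
* ≈ 69% of triggers sentence-initial or comma-preceded;
* ≈ 45% of triggers followed by a determiner or comma;
* ≈ half of all relations cross-sentence (DS), with the independent
  argument in the previous sentence half of the time and a geometric tail
  up to 10 sentences back;
* direction skew C-T-E : E-T-C ≈ 7.54 : 1.

Template grammar
----------------
Sentences are realised from a small hand-written grammar (subject NP,
verb, object NP, optional SBAR/CP complements) so that path and command
features have non-trivial, known values; every planted trigger constituent
c-commands its dependent argument. Ambiguity is planted deliberately: the
coordination ``and`` is overwhelmingly non-causal but occurs rarely as a
trigger, and the gerunds ``suggesting``/``indicating`` occur both as causal
triggers and in non-causal reduced relatives.

Proportions are planned with largest-remainder quotas rather than sampled
independently, so a generated corpus reproduces the configured statistics
almost exactly; trigger rarity is balanced by padding filler sentences
with extra conjuncts until the global token budget matches the target.

The truth table returned next to the documents is the single source for
planted-recovery evaluation.
"""

from __future__ import annotations

import copy
import random
from dataclasses import dataclass, field

import pandas as pd

from .doc_model import (
    AnnotatedDocument, CausalRelation, CTE, DS, ETC, PasArc, Sentence,
    SemanticLayer, Span, SS, Token, TypedSpan,
)
from .errors import ConfigError
from .tree_features import ConstituencyTree


@dataclass
class GeneratorConfig:
    n_documents: int = 50
    sentences_per_document: int = 25
    rarity_negatives_per_positive: float = 50.0
    initial_or_comma: float = 0.69
    det_follow: float = 0.45  # trigger followed by determiner or comma
    ds_rate: float = 0.5
    ds_prev1_rate: float = 0.5  # half of DS at distance 1
    ds_max_distance: int = 10
    direction_skew: float = 7.54  # CTE per ETC
    ss_initial_rate: float = 0.05  # trigger-initial SS ("Since …") share
    and_causal_rate: float = 0.02
    ambiguity_rate: float = 0.15  # fillers containing ambiguous lexemes
    ne_rate: float = 0.3
    event_rate: float = 0.2

    def validate(self) -> None:
        for name in ("initial_or_comma", "det_follow", "ds_rate",
                     "ds_prev1_rate", "ss_initial_rate", "and_causal_rate",
                     "ambiguity_rate", "ne_rate", "event_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.direction_skew <= 0:
            raise ConfigError("direction_skew must be positive")
        if self.rarity_negatives_per_positive <= 0:
            raise ConfigError("rarity must be positive")
        if self.ds_rate > 0 and self.sentences_per_document < 2:
            raise ConfigError("cross-sentence relations require documents "
                              "with at least 2 sentences")


# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

_NE_TYPES = ("Bacterium", "Gene", "Protein")
_HYPERNYMS = {"Bacterium": "organism", "Gene": "gene", "Protein": "protein"}
_CONCEPTS = {"Bacterium": "Organism", "Gene": "GeneOrGenome",
             "Protein": "AminoAcidSequence"}
_VERBS = [("activates", "activate", "Activation"),
          ("represses", "repress", "Repression"),
          ("encodes", "encode", "GeneExpression"),
          ("binds", "bind", "Binding"),
          ("regulates", "regulate", "Regulation"),
          ("induces", "induce", "Activation"),
          ("expresses", "express", "GeneExpression"),
          ("inhibits", "inhibit", "Repression")]
_GERUNDS = [("suggesting", "suggest"), ("indicating", "indicate")]


@dataclass
class _Vocab:
    nouns: list[str]
    noun_type: dict[str, str]
    hypernyms: dict[str, str]
    concepts: dict[str, str]


def _make_vocab(rng: random.Random, size: int = 400) -> _Vocab:
    onsets = ["s", "p", "m", "h", "c", "f", "t", "r", "l", "n", "g", "v"]
    vowels = ["a", "e", "i", "o", "u"]
    codas = ["d", "r", "l", "m", "n", "t", "s", "x", "v"]
    nouns: list[str] = []
    seen = set()
    while len(nouns) < size:
        stem = (rng.choice(onsets) + rng.choice(vowels) + rng.choice(codas)
                + rng.choice(onsets) + rng.choice(vowels))
        word = stem + rng.choice("ABCDEFGHRSTXYZ")
        if word not in seen:
            seen.add(word)
            nouns.append(word)
    noun_type = {n: rng.choice(_NE_TYPES) for n in nouns}
    hypernyms = {n: _HYPERNYMS[noun_type[n]] for n in nouns}
    hypernyms.update({lemma: "state" for _, lemma in _GERUNDS})
    hypernyms.update({lemma: "act" for _, lemma, _t in _VERBS})
    concepts = {n: _CONCEPTS[noun_type[n]] for n in nouns
                if rng.random() < 0.6}
    return _Vocab(nouns=nouns, noun_type=noun_type, hypernyms=hypernyms,
                  concepts=concepts)


# ---------------------------------------------------------------------------
# Sentence building blocks
# ---------------------------------------------------------------------------

class _SB:
    """Sentence builder: accumulates tokens while the tree is assembled."""

    def __init__(self):
        self.toks: list[list[str]] = []  # [surface, lemma, pos, cat]
        self.arcs: list[PasArc] = []

    def leaf(self, surface: str, lemma: str, pos: str, cat: str):
        self.toks.append([surface, lemma, pos, cat])
        return ("L", len(self.toks) - 1)

    @property
    def n(self) -> int:
        return len(self.toks)


def _node(label: str, *children):
    return (label, list(children))


def _render(node, toks) -> str:
    if node[0] == "L":
        surface, _lemma, _pos, cat = toks[node[1]]
        return f"({cat} {surface})"
    label, children = node
    return "(" + label + " " + " ".join(_render(c, toks) for c in children) + ")"


def _np(sb: _SB, noun: str, det: bool = True):
    if det:
        return _node("NP", sb.leaf("the", "the", "DT", "DT"),
                     sb.leaf(noun, noun, "NN", "NN"))
    return _node("NP", sb.leaf(noun, noun, "NN", "NN"))


def _clause(sb: _SB, rng: random.Random, vocab: _Vocab,
            det_subj: bool = True, det_obj: bool = True,
            forced_obj: str | None = None):
    """(S (NP subj) (VP (V verb) (NP obj))); returns the node."""
    subj = rng.choice(vocab.nouns)
    obj = forced_obj or rng.choice(vocab.nouns)
    surface, lemma, _ = rng.choice(_VERBS)
    np1 = _np(sb, subj, det_subj)
    v_idx = sb.n
    v = sb.leaf(surface, lemma, "VBZ", "V")
    np2 = _np(sb, obj, det_obj)
    sb.arcs.append(PasArc(head=v_idx, dep=v_idx - 1, label="ARG1"))
    sb.arcs.append(PasArc(head=v_idx, dep=sb.n - 1, label="ARG2"))
    return _node("S", np1, _node("VP", v, np2))


def _comma(sb: _SB):
    return sb.leaf(",", ",", ",", ",")


def _period(sb: _SB):
    return sb.leaf(".", ".", ".", ".")


# ---------------------------------------------------------------------------
# Trigger inventory
# ---------------------------------------------------------------------------

# (key, kind) — kind selects the sentence template
DS_TRIGGERS = ["therefore", "thus", "consequently", "hence", "as_a_result"]
SS_COMMA_TRIGGERS = ["thereby", "thus", "hence", "consequently",
                     "as_a_result", "suggesting_that", "indicating_that"]
SS_NONCOMMA_TRIGGERS = ["resulting_in"]
SS_ETC_TRIGGERS = ["is_attributed_to", "follows_from"]
SS_INITIAL_TRIGGERS = ["since", "because"]


def _adverb_trigger(sb: _SB, key: str, capital: bool):
    def cap(word):
        return word.capitalize() if capital else word

    if key == "as_a_result":
        return _node("ADVP", sb.leaf(cap("as"), "as", "IN", "P"),
                     sb.leaf("a", "a", "DT", "DT"),
                     sb.leaf("result", "result", "NN", "NN"))
    return _node("ADVP", sb.leaf(cap(key), key, "RB", "ADV"))


# ---------------------------------------------------------------------------
# Sentence templates: fillers
# ---------------------------------------------------------------------------

def _pad_np(sb: _SB, rng, vocab, np_node, pads: int,
            forced: str | None = None):
    """Wrap an NP in ``pads`` coordination layers: (NP np (CC and) (NP …))."""
    for k in range(pads):
        noun = forced if (forced and k == 0) else rng.choice(vocab.nouns)
        np_node = _node("NP", np_node, sb.leaf("and", "and", "CC", "CC"),
                        _np(sb, noun))
    return np_node


def _filler_basic(rng, vocab, pads: int, forced: str | None):
    sb = _SB()
    subj = forced or rng.choice(vocab.nouns)
    surface, lemma, _ = rng.choice(_VERBS)
    np1 = _np(sb, subj, det=True)
    v_idx = sb.n
    v = sb.leaf(surface, lemma, "VBZ", "V")
    np2 = _pad_np(sb, rng, vocab, _np(sb, rng.choice(vocab.nouns)), pads)
    sb.arcs.append(PasArc(head=v_idx, dep=v_idx - 1, label="ARG1"))
    root = _node("S", np1, _node("VP", v, np2), _period(sb))
    return sb, root


def _filler_gerund(rng, vocab, pads: int, forced: str | None):
    """Reduced relative with an ambiguous gerund:
    ``the A suggesting the B activates the C .``"""
    sb = _SB()
    subj = forced or rng.choice(vocab.nouns)
    ger_s, ger_l = rng.choice(_GERUNDS)
    np1 = _np(sb, subj)
    ger = sb.leaf(ger_s, ger_l, "VBG", "V")
    np_rel = _np(sb, rng.choice(vocab.nouns))
    subj_np = _node("NP", np1, _node("VP", ger, np_rel))
    surface, lemma, _ = rng.choice(_VERBS)
    v = sb.leaf(surface, lemma, "VBZ", "V")
    np2 = _pad_np(sb, rng, vocab, _np(sb, rng.choice(vocab.nouns)), pads)
    root = _node("S", subj_np, _node("VP", v, np2), _period(sb))
    return sb, root


# ---------------------------------------------------------------------------
# Sentence templates: causal
# ---------------------------------------------------------------------------

def _ss_adverbial(rng, vocab, key, comma: bool, det: bool, forced: str | None):
    """``the A v1 the B [,] TRIG the C v2 the D .`` — CTE, dep = effect
    clause after the trigger."""
    sb = _SB()
    c1 = _clause(sb, rng, vocab, forced_obj=forced)
    ind = (0, sb.n - 1)
    pieces = [c1]
    if comma:
        pieces.append(_comma(sb))
    if key in ("suggesting_that", "indicating_that"):
        ger_s, ger_l = ("suggesting", "suggest") if key.startswith("sugg") \
            else ("indicating", "indicate")
        t0 = sb.n
        gv = sb.leaf(ger_s, ger_l, "VBG", "V")
        that = sb.leaf("that", "that", "IN", "P")
        trig = (t0, sb.n - 1)
        d0 = sb.n
        c2 = _clause(sb, rng, vocab, det_subj=det)
        dep = (d0, sb.n - 1)
        vp = _node("VP", gv, _node("CP", _node("CX", that), c2))
    else:
        t0 = sb.n
        adv = _adverb_trigger(sb, key, capital=False)
        trig = (t0, sb.n - 1)
        d0 = sb.n
        c2 = _clause(sb, rng, vocab, det_subj=det)
        dep = (d0, sb.n - 1)
        vp = _node("VP", adv, c2)
    pieces.append(vp)
    pieces.append(_period(sb))
    return sb, _node("S", *pieces), trig, dep, ind, CTE


def _ss_resulting_in(rng, vocab, det: bool, forced: str | None):
    """``the A v1 the B resulting in the D .`` — CTE, dep = object of
    ``in``."""
    sb = _SB()
    subj = rng.choice(vocab.nouns)
    surface, lemma, _ = rng.choice(_VERBS)
    np1 = _np(sb, subj)
    v = sb.leaf(surface, lemma, "VBZ", "V")
    np2 = _np(sb, forced or rng.choice(vocab.nouns))
    ind = (0, sb.n - 1)
    t0 = sb.n
    res = sb.leaf("resulting", "result", "VBG", "V")
    inn = sb.leaf("in", "in", "IN", "P")
    trig = (t0, sb.n - 1)
    d0 = sb.n
    np3 = _np(sb, rng.choice(vocab.nouns), det=det)
    dep = (d0, sb.n - 1)
    root = _node("S", np1,
                 _node("VP", _node("VP", v, np2),
                       _node("VP", res, _node("PP", inn, np3))),
                 _period(sb))
    return sb, root, trig, dep, ind, CTE


def _ss_and(rng, vocab, forced: str | None):
    """``the A v1 the B and v2 the D .`` — the rare causal ``and``."""
    sb = _SB()
    np1 = _np(sb, rng.choice(vocab.nouns))
    s1, l1, _ = rng.choice(_VERBS)
    v1 = sb.leaf(s1, l1, "VBZ", "V")
    np2 = _np(sb, forced or rng.choice(vocab.nouns))
    ind = (0, sb.n - 1)
    t0 = sb.n
    cc = sb.leaf("and", "and", "CC", "CC")
    trig = (t0, t0)
    d0 = sb.n
    s2, l2, _ = rng.choice(_VERBS)
    v2 = sb.leaf(s2, l2, "VBZ", "V")
    np3 = _np(sb, rng.choice(vocab.nouns))
    dep = (d0, sb.n - 1)
    root = _node("S", np1,
                 _node("VP", _node("VP", v1, np2), cc, _node("VP", v2, np3)),
                 _period(sb))
    return sb, root, trig, dep, ind, CTE


def _ss_etc_mid(rng, vocab, key, det: bool, forced: str | None):
    """``the A is attributed to the C .`` / ``the A follows from the C .``
    — ETC, dep = cause after the trigger."""
    sb = _SB()
    np1 = _np(sb, forced or rng.choice(vocab.nouns))
    ind = (0, sb.n - 1)
    t0 = sb.n
    if key == "is_attributed_to":
        is_idx = sb.n
        isv = sb.leaf("is", "be", "VBZ", "V")
        att_idx = sb.n
        att = sb.leaf("attributed", "attribute", "VBN", "V")
        to = sb.leaf("to", "to", "TO", "P")
        sb.arcs.append(PasArc(head=att_idx, dep=is_idx, label="aux"))
        trig = (t0, sb.n - 1)
        d0 = sb.n
        np2 = _np(sb, rng.choice(vocab.nouns), det=det)
        dep = (d0, sb.n - 1)
        vp = _node("VP", isv, _node("VP", att, _node("PP", to, np2)))
    else:  # follows_from
        fol = sb.leaf("follows", "follow", "VBZ", "V")
        frm = sb.leaf("from", "from", "IN", "P")
        trig = (t0, sb.n - 1)
        d0 = sb.n
        np2 = _np(sb, rng.choice(vocab.nouns), det=det)
        dep = (d0, sb.n - 1)
        vp = _node("VP", fol, _node("PP", frm, np2))
    root = _node("S", np1, vp, _period(sb))
    return sb, root, trig, dep, ind, ETC


def _ss_initial(rng, vocab, key, det: bool, forced: str | None):
    """``Since the C v2 the D , the A v1 the B .`` — trigger-initial SS,
    dep = cause clause right after the trigger (ETC)."""
    sb = _SB()
    t0 = sb.n
    word = key.capitalize()
    p = sb.leaf(word, key, "IN", "P")
    trig = (t0, t0)
    d0 = sb.n
    c1 = _clause(sb, rng, vocab, det_subj=det, forced_obj=forced)
    dep = (d0, sb.n - 1)
    comma = _comma(sb)
    i0 = sb.n
    c2 = _clause(sb, rng, vocab)
    ind = (i0, sb.n - 1)
    per = _period(sb)
    root = _node("S", _node("SBAR", p, c1), comma, c2, per)
    return sb, root, trig, dep, ind, ETC


def _ds_initial(rng, vocab, key, det: bool, comma: bool,
                forced: str | None):
    """``Therefore [,] the C v2 the D .`` — DS, dep = rest of sentence."""
    sb = _SB()
    t0 = sb.n
    adv = _adverb_trigger(sb, key, capital=True)
    trig = (t0, sb.n - 1)
    d0 = sb.n
    pieces = [adv]
    if comma:
        pieces.append(_comma(sb))
    c = _clause(sb, rng, vocab, det_subj=det, forced_obj=forced)
    dep = (d0, sb.n - 1)
    pieces.extend([c, _period(sb)])
    root = _node("S", *pieces)
    return sb, root, trig, dep, None, CTE


# ---------------------------------------------------------------------------
# Corpus planning
# ---------------------------------------------------------------------------

@dataclass
class _RelPlan:
    kind: str  # template family
    key: str  # trigger key
    det: bool
    comma: bool = False
    distance: int = 0  # DS only; >0 means that many sentences back
    doc: int = -1
    slot: int = -1
    shared_noun: str | None = None


@dataclass
class _SentPlan:
    kind: str  # "filler-basic" | "filler-gerund" | "causal"
    rel: _RelPlan | None = None
    pads: int = 0
    forced_noun: str | None = None


def _quota(n: int, fraction: float) -> int:
    return max(0, min(n, round(fraction * n)))


def _plan_relations(cfg: GeneratorConfig, rng: random.Random,
                    n_rel: int) -> list[_RelPlan]:
    n_ds = _quota(n_rel, cfg.ds_rate)
    n_ss = n_rel - n_ds
    n_ss_init = min(n_ss, _quota(n_rel, cfg.ss_initial_rate))
    n_etc = max(_quota(n_rel, 1.0 / (1.0 + cfg.direction_skew)), n_ss_init)
    n_etc_mid = min(n_ss - n_ss_init, n_etc - n_ss_init)
    n_cte_mid = n_ss - n_ss_init - n_etc_mid
    n_init = n_ds + n_ss_init
    n_comma = max(0, min(n_cte_mid,
                         round(cfg.initial_or_comma * n_rel) - n_init))
    n_noncomma = n_cte_mid - n_comma
    n_and = min(_quota(n_rel, cfg.and_causal_rate), n_noncomma)
    n_resulting = n_noncomma - n_and

    plans: list[_RelPlan] = []
    for _ in range(n_ds):
        if rng.random() < cfg.ds_prev1_rate:
            d = 1
        else:
            d = 2
            while d < cfg.ds_max_distance and rng.random() < 0.5:
                d += 1
        plans.append(_RelPlan(kind="ds", key=rng.choice(DS_TRIGGERS),
                              det=False, distance=d))
    for _ in range(n_ss_init):
        plans.append(_RelPlan(kind="ss-initial",
                              key=rng.choice(SS_INITIAL_TRIGGERS), det=False))
    for _ in range(n_etc_mid):
        plans.append(_RelPlan(kind="ss-etc",
                              key=rng.choice(SS_ETC_TRIGGERS), det=False))
    for _ in range(n_comma):
        plans.append(_RelPlan(kind="ss-adverbial",
                              key=rng.choice(SS_COMMA_TRIGGERS), det=False,
                              comma=True))
    for _ in range(n_resulting):
        plans.append(_RelPlan(kind="ss-resulting",
                              key=SS_NONCOMMA_TRIGGERS[0], det=False))
    for _ in range(n_and):
        plans.append(_RelPlan(kind="ss-and", key="and", det=False))

    # determiner-or-comma-after-trigger quota: a selected DS trigger is
    # followed by a comma, any other selected trigger by a determiner;
    # the causal ``and`` is always followed by a verb
    eligible = [p for p in plans if p.kind != "ss-and"]
    rng.shuffle(eligible)
    for p in eligible[:_quota(n_rel, cfg.det_follow)]:
        if p.kind == "ds":
            p.comma = True
        else:
            p.det = True
    rng.shuffle(plans)
    return plans


def _realise_causal(plan: _RelPlan, rng: random.Random, vocab: _Vocab,
                    forced: str | None):
    if plan.kind == "ds":
        return _ds_initial(rng, vocab, plan.key, plan.det, plan.comma, forced)
    if plan.kind == "ss-initial":
        return _ss_initial(rng, vocab, plan.key, plan.det, forced)
    if plan.kind == "ss-etc":
        return _ss_etc_mid(rng, vocab, plan.key, plan.det, forced)
    if plan.kind == "ss-adverbial":
        return _ss_adverbial(rng, vocab, plan.key, plan.comma, plan.det,
                             forced)
    if plan.kind == "ss-resulting":
        return _ss_resulting_in(rng, vocab, plan.det, forced)
    if plan.kind == "ss-and":
        return _ss_and(rng, vocab, forced)
    raise ValueError(f"unknown relation template {plan.kind!r}")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate(config: GeneratorConfig, seed: int
             ) -> tuple[list[AnnotatedDocument], pd.DataFrame]:
    """Generate a corpus and its truth table, deterministically for a
    given seed."""
    config.validate()
    rng = random.Random(seed)
    vocab = _make_vocab(rng)
    n_docs = config.n_documents
    spd = config.sentences_per_document
    total_slots = n_docs * spd

    # relation budget: aim for an average realised sentence length of ~12
    # tokens once fillers are padded up to the rarity target
    inv = 1.0 + config.rarity_negatives_per_positive
    mean_trig = 1.4
    denom = max(1.0, mean_trig * inv - 13.0 + 12.0)
    n_rel = max(1, int(round(total_slots * 12.0 / denom)))
    n_rel = min(n_rel, total_slots // 2)
    rel_plans = _plan_relations(config, rng, n_rel)

    # distribute relations over documents and slots
    sent_plans: list[list[_SentPlan]] = [
        [_SentPlan(kind="filler-basic") for _ in range(spd)]
        for _ in range(n_docs)
    ]
    per_doc = [n_rel // n_docs + (1 if d < n_rel % n_docs else 0)
               for d in range(n_docs)]
    cursor = 0
    for d in range(n_docs):
        slots = list(range(spd))
        rng.shuffle(slots)
        taken: set[int] = set()
        for plan in rel_plans[cursor:cursor + per_doc[d]]:
            placed = False
            for slot in slots:
                if slot in taken:
                    continue
                if plan.kind == "ds":
                    dist = min(plan.distance, max(1, slot))
                    target = slot - dist
                    if target < 0 or target in taken:
                        continue
                    plan.distance = dist
                    plan.shared_noun = rng.choice(vocab.nouns)
                    sent_plans[d][target].forced_noun = plan.shared_noun
                plan.doc, plan.slot = d, slot
                sent_plans[d][slot] = _SentPlan(kind="causal", rel=plan)
                taken.add(slot)
                if plan.kind == "ds":
                    taken.add(slot - plan.distance)
                placed = True
                break
            if not placed:  # pragma: no cover - ample slots by construction
                raise ConfigError("could not place a relation; increase "
                                  "sentences_per_document")
        cursor += per_doc[d]
    rel_plans = [p for p in rel_plans if p.doc >= 0]

    # ambiguity: some fillers use the gerund template
    for d in range(n_docs):
        for sp in sent_plans[d]:
            if sp.kind == "filler-basic" and rng.random() < config.ambiguity_rate:
                sp.kind = "filler-gerund"

    # realise causal sentences now; fillers after padding is known
    realised: dict[tuple[int, int], tuple] = {}
    trigger_tokens = 0
    base_tokens = 0
    for d in range(n_docs):
        for s, sp in enumerate(sent_plans[d]):
            if sp.kind == "causal":
                forced = (sp.rel.shared_noun if sp.rel.kind == "ds" else None)
                sb, root, trig, dep, ind, direction = _realise_causal(
                    sp.rel, rng, vocab, forced)
                realised[(d, s)] = (sb, root, trig, dep, ind, direction)
                trigger_tokens += trig[1] - trig[0] + 1
                base_tokens += sb.n
            else:
                base_tokens += 6 if sp.kind == "filler-basic" else 9

    target_total = round(trigger_tokens * inv)
    pad_units = max(0, (target_total - base_tokens) // 3)
    fillers = [(d, s) for d in range(n_docs)
               for s, sp in enumerate(sent_plans[d])
               if sp.kind != "causal"]
    for k in range(pad_units):
        d, s = fillers[k % len(fillers)] if fillers else (None, None)
        if d is None:
            break
        sent_plans[d][s].pads += 1

    # realise everything, assemble documents
    docs: list[AnnotatedDocument] = []
    truth_rows = []
    for d in range(n_docs):
        doc_id = f"synth{d:04d}"
        sentences: list[Sentence] = []
        parse_sources = []
        offset = 0
        text_parts = []
        rels_here: list[tuple[_RelPlan, tuple, tuple, tuple | None, str]] = []
        for s, sp in enumerate(sent_plans[d]):
            if sp.kind == "causal":
                sb, root, trig, dep, ind, direction = realised[(d, s)]
                rels_here.append((sp.rel, trig, dep, ind, direction))
            else:
                fn = (_filler_basic if sp.kind == "filler-basic"
                      else _filler_gerund)
                sb, root = fn(rng, vocab, sp.pads, sp.forced_noun)
            sb.toks[0][0] = sb.toks[0][0][:1].upper() + sb.toks[0][0][1:]
            tokens = []
            for i, (surface, lemma, pos, _cat) in enumerate(sb.toks):
                tokens.append(Token(index=i, surface=surface, lemma=lemma,
                                    pos=pos, start=offset,
                                    end=offset + len(surface)))
                offset += len(surface) + 1
            text_parts.append(" ".join(t.surface for t in tokens))
            sent = Sentence(index=s, tokens=tokens, arcs=tuple(sb.arcs))
            tree = ConstituencyTree.from_string(_render(root, sb.toks))
            tree.bind_tokens(tokens)
            sent.tree = tree
            sentences.append(sent)
            parse_sources.append(None)
        text = " ".join(text_parts)

        semantics = SemanticLayer(hypernyms=dict(vocab.hypernyms),
                                  concepts=dict(vocab.concepts))
        doc = AnnotatedDocument(doc_id=doc_id, text=text,
                                sentences=sentences, semantics=semantics)

        # causal relations + truth rows
        blocked: set[tuple[int, int]] = set()
        for plan, trig, dep, ind, direction in rels_here:
            s = plan.slot
            trigger = Span(s, trig[0], trig[1])
            dep_span = Span(s, dep[0], dep[1])
            if plan.kind == "ds":
                j = s - plan.distance
                ind_span = Span(j, 0, len(sentences[j].tokens) - 1)
                position = DS
            else:
                ind_span = Span(s, ind[0], ind[1])
                position = SS
            rel = CausalRelation(trigger=trigger, dep_arg=dep_span,
                                 ind_arg=ind_span, position=position,
                                 direction=direction)
            doc.relations.append(rel)
            for i in trigger.tokens():
                blocked.add((s, i))
            truth_rows.append({
                "doc_id": doc_id, "sentence": s, "position": position,
                "direction": direction, "template": plan.kind,
                "trigger_key": plan.key,
                "trig_first": trigger.first, "trig_last": trigger.last,
                "dep_sent": dep_span.sentence, "dep_first": dep_span.first,
                "dep_last": dep_span.last,
                "ind_sent": ind_span.sentence, "ind_first": ind_span.first,
                "ind_last": ind_span.last,
            })

        # semantic spans: never on trigger tokens
        for sent in sentences:
            for tok in sent.tokens:
                if (sent.index, tok.index) in blocked:
                    continue
                if tok.lemma in vocab.noun_type and rng.random() < config.ne_rate:
                    semantics.entities.append(TypedSpan(
                        span=Span(sent.index, tok.index, tok.index),
                        type=vocab.noun_type[tok.lemma]))
                elif tok.pos == "VBZ" and rng.random() < config.event_rate:
                    ev = {s: t for s, _, t in _VERBS}.get(tok.surface)
                    if ev:
                        semantics.events.append(TypedSpan(
                            span=Span(sent.index, tok.index, tok.index),
                            type=ev))
        doc.validate()
        docs.append(doc)

    truth = pd.DataFrame(truth_rows)
    return docs, truth


# ---------------------------------------------------------------------------
# Corruption (label-noise stress testing)
# ---------------------------------------------------------------------------

def corrupt(docs: list[AnnotatedDocument], rate: float, seed: int
            ) -> tuple[list[AnnotatedDocument], pd.DataFrame]:
    """Flip/shift exactly ``round(rate × n_relations)`` gold labels.

    Corruptions alternate between flipping the relation direction and
    shifting the trigger span start by one token; a ledger of applied
    corruptions is returned.
    """
    if not 0.0 <= rate < 1.0:
        raise ConfigError("corruption rate must be in [0,1)")
    out = copy.deepcopy(docs)
    index = [(di, ri) for di, doc in enumerate(out)
             for ri in range(len(doc.relations))]
    n = round(rate * len(index))
    rng = random.Random(seed)
    chosen = rng.sample(index, n) if n else []
    rows = []
    for k, (di, ri) in enumerate(sorted(chosen)):
        rel = out[di].relations[ri]
        sent = out[di].sentences[rel.trigger.sentence]
        if k % 2 == 0 or rel.trigger.last + 1 >= len(sent.tokens):
            rel.direction = ETC if rel.direction == CTE else CTE
            op = "flip-direction"
        else:
            rel.trigger = Span(rel.trigger.sentence, rel.trigger.first + 1,
                               max(rel.trigger.first + 1, rel.trigger.last))
            op = "shift-trigger"
        rows.append({"doc_id": out[di].doc_id, "relation": ri, "op": op})
    return out, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Corpus statistics (used by the acceptance checks and the CLI)
# ---------------------------------------------------------------------------

def corpus_statistics(docs: list[AnnotatedDocument]) -> dict[str, float]:
    """Empirical counterparts of the generator's configured proportions."""
    total_tokens = sum(len(s.tokens) for d in docs for s in d.sentences)
    trig_tokens = 0
    n_rel = n_ds = n_cte = 0
    init_or_comma = det_follow = 0
    for doc in docs:
        for rel in doc.relations:
            n_rel += 1
            trig_tokens += len(rel.trigger)
            if rel.position == DS:
                n_ds += 1
            if rel.direction == CTE:
                n_cte += 1
            sent = doc.sentences[rel.trigger.sentence]
            if rel.trigger.first == 0 or \
                    sent.tokens[rel.trigger.first - 1].surface == ",":
                init_or_comma += 1
            nxt = rel.trigger.last + 1
            if nxt < len(sent.tokens) and \
                    (sent.tokens[nxt].pos == "DT"
                     or sent.tokens[nxt].surface == ","):
                det_follow += 1
    return {
        "tokens": total_tokens,
        "relations": n_rel,
        "trigger_tokens": trig_tokens,
        "rarity_negatives_per_positive":
            (total_tokens - trig_tokens) / trig_tokens if trig_tokens else 0.0,
        "initial_or_comma": init_or_comma / n_rel if n_rel else 0.0,
        "det_follow": det_follow / n_rel if n_rel else 0.0,
        "ds_rate": n_ds / n_rel if n_rel else 0.0,
        "direction_skew": n_cte / max(1, n_rel - n_cte),
    }
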