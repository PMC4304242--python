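"""The four-stage causality recognition pipeline.

TS (trigger span detection) → AP (argument position, SS vs DS) → AS
(argument span identification) → AR (argument role assignment, CTE vs ETC).
Each stage can run on gold inputs (to score it in isolation) or chained on
the previous stage's predictions (errors propagate).

Argument geometry
-----------------
For an SS relation the two arguments are disjoint token spans inside the
trigger sentence, neither overlapping the trigger. For a DS relation the
dependent argument is the trigger's sentence minus the trigger tokens
(clipped to the larger contiguous side when the trigger sits mid-sentence)
and the independent argument is one whole sentence chosen from a candidate
window of 10 sentences before to 1 after the trigger.

Scoring
-------
Triggers are matched by exact span. Argument spans are scored token-level.
AP and AR are scored over relations: in gold-input mode every gold relation
receives a prediction, so precision, recall and F1 all equal accuracy; in
chained mode a gold relation whose trigger was missed counts as a false
negative and spurious predictions count as false positives, which makes the
chained score structurally ≤ the gold-input score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .doc_model import (
    AnnotatedDocument, CausalRelation, CTE, DS, ETC, Span, SS,
)
from .errors import AlignmentError, WindowError
from .feature_extraction import token_features, trigger_features
from .learners import DEFAULT_SEED, SequenceLabeller, make_classifier

STAGE_NAMES = ("TS", "AP", "AS", "AR")


@dataclass
class PipelineConfig:
    window_before: int = 10
    window_after: int = 1
    learner_ap: str = "vote"
    learner_ar: str = "vote"
    learner_ds: str = "maxent"
    rng_seed: int = DEFAULT_SEED


@dataclass
class EvalReport:
    """Contingency counts with derived precision/recall/F1.

    Divisions by zero are defined as 0.
    """

    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def __add__(self, other: "EvalReport") -> "EvalReport":
        return EvalReport(self.tp + other.tp, self.fp + other.fp,
                          self.fn + other.fn)


@dataclass
class StagePrediction:
    """Predictions of one stage for one document, with provenance."""

    stage: str
    provenance: str  # "gold-input" | "predicted-input"
    relations: list[CausalRelation] = field(default_factory=list)
    triggers: list[tuple[Span, float]] = field(default_factory=list)


def _trigger_tokens(spans) -> set[tuple[int, int]]:
    out = set()
    for span in spans:
        for i in span.tokens():
            out.add((span.sentence, i))
    return out


def _span_tokens(span: Span) -> set[tuple[int, int]]:
    return {(span.sentence, i) for i in span.tokens()}


def _content_lemmas(sent) -> set[str]:
    # nouns only: the verb inventory is small enough that verb overlap is
    # uninformative for sentence linking
    return {t.lemma for t in sent.tokens if t.pos.startswith("NN")}


class CausalPipeline:
    """Trainable four-stage extractor."""

    def __init__(self, config: Optional[PipelineConfig] = None):
        self.config = config or PipelineConfig()
        seed = self.config.rng_seed
        self.ts_model = SequenceLabeller(seed=seed)
        self.ap_model = make_classifier(self.config.learner_ap, seed=seed)
        self.as_model = SequenceLabeller(seed=seed)
        self.ds_model = make_classifier(self.config.learner_ds, seed=seed)
        self.ar_model = make_classifier(self.config.learner_ar, seed=seed)

    # -- feature assembly -------------------------------------------------

    def _ts_sequences(self, doc: AnnotatedDocument):
        for sent in doc.sentences:
            feats = [token_features(doc, sent.index, i, "TS")
                     for i in range(len(sent.tokens))]
            yield sent, feats

    @staticmethod
    def _bio_tags(doc: AnnotatedDocument, sent) -> list[str]:
        tags = ["O"] * len(sent.tokens)
        for rel in doc.relations:
            if rel.trigger.sentence != sent.index:
                continue
            tags[rel.trigger.first] = "B"
            for i in range(rel.trigger.first + 1, rel.trigger.last + 1):
                tags[i] = "I"
        return tags

    def _as_sequence(self, doc: AnnotatedDocument, trigger: Span):
        trig_toks = _span_tokens(trigger)
        return [token_features(doc, trigger.sentence, i, "AS",
                               predicted_triggers=trig_toks)
                for i in range(len(doc.sentence(trigger.sentence).tokens))]

    def _ds_candidate_features(self, doc: AnnotatedDocument, trigger: Span,
                               candidate_index: int) -> dict:
        trig_sent = doc.sentence(trigger.sentence)
        cand = doc.sentence(candidate_index)
        overlap = len(_content_lemmas(trig_sent) & _content_lemmas(cand))
        return {
            "dist": abs(trigger.sentence - candidate_index),
            "before": candidate_index < trigger.sentence,
            "adjacent": abs(trigger.sentence - candidate_index) == 1,
            "len": len(cand.tokens),
            "overlap": overlap,
            "overlap_frac": overlap / max(1, len(_content_lemmas(cand))),
        }

    def _ds_candidates(self, doc: AnnotatedDocument, trigger: Span) -> list[int]:
        window = doc.sentence_window(trigger.sentence,
                                     self.config.window_before,
                                     self.config.window_after)
        return [s.index for s in window]

    # -- training ----------------------------------------------------------

    def fit(self, docs: list[AnnotatedDocument]) -> "CausalPipeline":
        ts_X, ts_y = [], []
        ap_X, ap_y = [], []
        as_X, as_y = [], []
        ds_X, ds_y = [], []
        ar_X, ar_y = [], []
        for doc in docs:
            for sent, feats in self._ts_sequences(doc):
                ts_X.append(feats)
                ts_y.append(self._bio_tags(doc, sent))
            for rel in doc.relations:
                ap_X.append(trigger_features(doc, rel.trigger, "AP"))
                ap_y.append(rel.position)
                ar_X.append(trigger_features(
                    doc, rel.trigger, "AR",
                    predicted_dep_tokens=_span_tokens(rel.dep_arg)))
                ar_y.append(rel.direction)
                if rel.position == SS:
                    as_X.append(self._as_sequence(doc, rel.trigger))
                    as_y.append(self._argument_tags(doc, rel))
                else:
                    for ci in self._ds_candidates(doc, rel.trigger):
                        ds_X.append(self._ds_candidate_features(
                            doc, rel.trigger, ci))
                        ds_y.append("IND" if ci == rel.ind_arg.sentence
                                    else "O")
        self.ts_model.fit(ts_X, ts_y)
        if ap_X:
            self.ap_model.fit(ap_X, ap_y)
        if as_X:
            self.as_model.fit(as_X, as_y)
        if ds_X and len(set(ds_y)) > 1:
            self.ds_model.fit(ds_X, ds_y)
        if ar_X:
            self.ar_model.fit(ar_X, ar_y)
        return self

    @staticmethod
    def _argument_tags(doc: AnnotatedDocument, rel: CausalRelation) -> list[str]:
        sent = doc.sentence(rel.trigger.sentence)
        tags = ["O"] * len(sent.tokens)
        for span, ty in ((rel.dep_arg, "DA"), (rel.ind_arg, "IA")):
            tags[span.first] = f"B-{ty}"
            for i in range(span.first + 1, span.last + 1):
                tags[i] = f"I-{ty}"
        return tags

    # -- stage predictions --------------------------------------------------

    def detect_triggers(self, doc: AnnotatedDocument) -> list[tuple[Span, float]]:
        """Stage TS: non-overlapping predicted trigger spans with
        confidences. Overlaps are resolved by confidence, then
        leftmost-longest."""
        found: list[tuple[Span, float]] = []
        for sent, feats in self._ts_sequences(doc):
            _tags, spans = self.ts_model.predict(feats)
            for first, last, _ty, conf in spans:
                found.append((Span(sent.index, first, last), conf))
        found.sort(key=lambda sc: (-sc[1], sc[0].sentence, sc[0].first,
                                   -len(sc[0])))
        kept: list[tuple[Span, float]] = []
        for span, conf in found:
            if not any(span.overlaps(k) for k, _ in kept):
                kept.append((span, conf))
        kept.sort(key=lambda sc: sc[0])
        return kept

    def classify_position(self, doc: AnnotatedDocument,
                          trigger: Span) -> tuple[str, float]:
        """Stage AP: SS vs DS for one trigger."""
        return self.ap_model.predict_one(
            trigger_features(doc, trigger, "AP"))

    def detect_argument_spans(self, doc: AnnotatedDocument, trigger: Span,
                              position: str) -> tuple[Span, Span]:
        """Stage AS: (dependent, independent) argument spans."""
        if position == SS:
            return self._ss_spans(doc, trigger)
        return self._ds_spans(doc, trigger)

    def _ss_spans(self, doc: AnnotatedDocument, trigger: Span) -> tuple[Span, Span]:
        sent = doc.sentence(trigger.sentence)
        _tags, spans = self.as_model.predict(self._as_sequence(doc, trigger))
        # arguments are contiguous: fragmented same-type predictions are
        # merged into their envelope before clipping against the trigger
        best: dict[str, tuple[int, int, float]] = {}
        for first, last, ty, conf in spans:
            if ty in best:
                pf, pl, pc = best[ty]
                merged = self._clip_to_trigger(sent, trigger,
                                               min(pf, first), max(pl, last))
                if merged is not None:
                    best[ty] = (*merged, max(pc, conf))
                continue
            clipped = self._clip_to_trigger(sent, trigger, first, last)
            if clipped is None:
                continue
            best[ty] = (*clipped, conf)
        dep = (Span(sent.index, best["DA"][0], best["DA"][1])
               if "DA" in best else self._fallback_side(sent, trigger, after=True))
        ind = (Span(sent.index, best["IA"][0], best["IA"][1])
               if "IA" in best else self._fallback_side(sent, trigger, after=False))
        if dep.overlaps(ind):
            ind = self._fallback_side(
                sent, trigger, after=not (dep.first > trigger.last))
        return dep, ind

    @staticmethod
    def _clip_to_trigger(sent, trigger: Span, first: int,
                         last: int) -> Optional[tuple[int, int]]:
        """Remove any overlap with the trigger, keeping the larger side."""
        if last < trigger.first or first > trigger.last:
            return first, last
        left = (first, trigger.first - 1) if first < trigger.first else None
        right = (trigger.last + 1, last) if last > trigger.last else None
        sides = [s for s in (left, right) if s is not None]
        if not sides:
            return None
        return max(sides, key=lambda s: s[1] - s[0])

    @staticmethod
    def _fallback_side(sent, trigger: Span, after: bool) -> Span:
        """Deterministic fallback: the contiguous non-trigger region on one
        side of the trigger (skipping final punctuation when possible)."""
        if after:
            first = trigger.last + 1
            last = len(sent.tokens) - 1
            if last > first and sent.tokens[last].pos == ".":
                last -= 1
            if first > last:
                first = last = max(0, trigger.first - 1)
        else:
            first = 0
            last = trigger.first - 1
            if last < first:
                first = last = min(len(sent.tokens) - 1, trigger.last + 1)
        return Span(sent.index, first, last)

    def _ds_spans(self, doc: AnnotatedDocument, trigger: Span) -> tuple[Span, Span]:
        sent = doc.sentence(trigger.sentence)
        dep = self._sentence_minus_trigger(sent, trigger)
        candidates = self._ds_candidates(doc, trigger)
        if not candidates:
            raise WindowError(
                f"no candidate sentences around sentence {trigger.sentence}")
        feats = [self._ds_candidate_features(doc, trigger, ci)
                 for ci in candidates]
        classes, proba = self.ds_model.predict_proba(feats)
        ind_col = classes.index("IND") if "IND" in classes else 0
        best = max(range(len(candidates)), key=lambda i: proba[i, ind_col])
        ind_sent = doc.sentence(candidates[best])
        ind = Span(ind_sent.index, 0, len(ind_sent.tokens) - 1)
        return dep, ind

    @staticmethod
    def _sentence_minus_trigger(sent, trigger: Span) -> Span:
        """The trigger's sentence minus the trigger tokens; when the trigger
        is mid-sentence, the larger contiguous side."""
        left = (0, trigger.first - 1) if trigger.first > 0 else None
        right = ((trigger.last + 1, len(sent.tokens) - 1)
                 if trigger.last < len(sent.tokens) - 1 else None)
        sides = [s for s in (left, right) if s is not None]
        if not sides:
            return Span(sent.index, 0, len(sent.tokens) - 1)
        first, last = max(sides, key=lambda s: s[1] - s[0])
        if last > first and sent.tokens[last].pos == ".":
            last -= 1
        return Span(sent.index, first, last)

    def assign_roles(self, doc: AnnotatedDocument, trigger: Span,
                     dep_arg: Span) -> tuple[str, float]:
        """Stage AR: relation direction (CTE vs ETC)."""
        return self.ar_model.predict_one(trigger_features(
            doc, trigger, "AR",
            predicted_dep_tokens=_span_tokens(dep_arg)))

    # -- end-to-end ---------------------------------------------------------

    def predict(self, doc: AnnotatedDocument) -> list[CausalRelation]:
        """Chained prediction: every stage consumes the previous stage's
        output."""
        out = []
        for trigger, _conf in self.detect_triggers(doc):
            out.append(self._complete_relation(doc, trigger))
        return out

    def _complete_relation(self, doc: AnnotatedDocument,
                           trigger: Span) -> CausalRelation:
        position, _ = self.classify_position(doc, trigger)
        if position == DS and len(doc.sentences) == 1:
            position = SS  # a one-sentence document cannot host DS
        dep, ind = self.detect_argument_spans(doc, trigger, position)
        direction, _ = self.assign_roles(doc, trigger, dep)
        return CausalRelation(trigger=trigger, dep_arg=dep, ind_arg=ind,
                              position=position, direction=direction)

    def predict_gold_inputs(self, doc: AnnotatedDocument) -> dict:
        """Each stage run on gold inputs; returns per-stage predictions
        aligned with ``doc.relations``."""
        positions, spans, directions = [], [], []
        for rel in doc.relations:
            positions.append(self.classify_position(doc, rel.trigger)[0])
            spans.append(self.detect_argument_spans(doc, rel.trigger,
                                                    rel.position))
            directions.append(self.assign_roles(doc, rel.trigger,
                                                rel.dep_arg)[0])
        return {"AP": positions, "AS": spans, "AR": directions,
                "TS": self.detect_triggers(doc)}


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate_triggers(gold_docs: list[AnnotatedDocument],
                      predictions: dict[str, list[tuple[Span, float]]]
                      ) -> EvalReport:
    """Exact-span trigger matching."""
    report = EvalReport()
    for doc in gold_docs:
        if doc.doc_id not in predictions:
            raise AlignmentError(f"no predictions for document {doc.doc_id}")
        gold = {rel.trigger for rel in doc.relations}
        pred = {span for span, _ in predictions[doc.doc_id]}
        report.tp += len(gold & pred)
        report.fp += len(pred - gold)
        report.fn += len(gold - pred)
    return report


def evaluate_labels(gold: list[str], pred: list[str]) -> EvalReport:
    """Gold-input-mode stage scoring: every gold item has a prediction, so
    a wrong label is both a false positive and a false negative."""
    if len(gold) != len(pred):
        raise AlignmentError(f"{len(gold)} gold vs {len(pred)} predicted")
    tp = sum(1 for g, p in zip(gold, pred) if g == p)
    wrong = len(gold) - tp
    return EvalReport(tp=tp, fp=wrong, fn=wrong)


def evaluate_argument_tokens(
        gold_pairs: list[tuple[Span, Span]],
        pred_pairs: list[tuple[Span, Span]]) -> EvalReport:
    """Token-level argument scoring over aligned relation lists."""
    if len(gold_pairs) != len(pred_pairs):
        raise AlignmentError(f"{len(gold_pairs)} gold vs {len(pred_pairs)} "
                             "predicted relations")
    report = EvalReport()
    for (g_dep, g_ind), (p_dep, p_ind) in zip(gold_pairs, pred_pairs):
        g = _span_tokens(g_dep) | _span_tokens(g_ind)
        p = _span_tokens(p_dep) | _span_tokens(p_ind)
        report.tp += len(g & p)
        report.fp += len(p - g)
        report.fn += len(g - p)
    return report


def evaluate_chained(gold_docs: list[AnnotatedDocument],
                     predictions: dict[str, list[CausalRelation]]
                     ) -> dict[str, EvalReport]:
    """Per-stage scoring of chained predictions.

    Relations are matched by exact trigger span. A gold relation with no
    matching predicted trigger contributes false negatives to every stage;
    an unmatched predicted relation contributes false positives.
    """
    reports = {name: EvalReport() for name in STAGE_NAMES}
    for doc in gold_docs:
        preds = predictions.get(doc.doc_id, [])
        by_trigger = {rel.trigger: rel for rel in preds}
        matched_pred = set()
        for rel in doc.relations:
            pred = by_trigger.get(rel.trigger)
            if pred is None:
                reports["TS"].fn += 1
                reports["AP"].fn += 1
                reports["AR"].fn += 1
                reports["AS"].fn += len(_span_tokens(rel.dep_arg)
                                        | _span_tokens(rel.ind_arg))
                continue
            matched_pred.add(rel.trigger)
            reports["TS"].tp += 1
            if pred.position == rel.position:
                reports["AP"].tp += 1
            else:
                reports["AP"].fp += 1
                reports["AP"].fn += 1
            if pred.direction == rel.direction:
                reports["AR"].tp += 1
            else:
                reports["AR"].fp += 1
                reports["AR"].fn += 1
            g = _span_tokens(rel.dep_arg) | _span_tokens(rel.ind_arg)
            p = _span_tokens(pred.dep_arg) | _span_tokens(pred.ind_arg)
            reports["AS"].tp += len(g & p)
            reports["AS"].fp += len(p - g)
            reports["AS"].fn += len(g - p)
        for pred in preds:
            if pred.trigger not in matched_pred:
                reports["TS"].fp += 1
                reports["AP"].fp += 1
                reports["AR"].fp += 1
                reports["AS"].fp += len(_span_tokens(pred.dep_arg)
                                        | _span_tokens(pred.ind_arg))
    return reports


def evaluate_gold_inputs(gold_docs: list[AnnotatedDocument],
                         pipeline: CausalPipeline) -> dict[str, EvalReport]:
    """Per-stage scoring with each stage fed gold inputs."""
    ap_gold, ap_pred = [], []
    ar_gold, ar_pred = [], []
    as_gold, as_pred = [], []
    trig_pred = {}
    for doc in gold_docs:
        stage = pipeline.predict_gold_inputs(doc)
        trig_pred[doc.doc_id] = stage["TS"]
        for rel, pos, sp, direction in zip(
                doc.relations, stage["AP"], stage["AS"], stage["AR"]):
            ap_gold.append(rel.position)
            ap_pred.append(pos)
            ar_gold.append(rel.direction)
            ar_pred.append(direction)
            as_gold.append((rel.dep_arg, rel.ind_arg))
            as_pred.append(sp)
    return {
        "TS": evaluate_triggers(gold_docs, trig_pred),
        "AP": evaluate_labels(ap_gold, ap_pred),
        "AS": evaluate_argument_tokens(as_gold, as_pred),
        "AR": evaluate_labels(ar_gold, ar_pred),
    }
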