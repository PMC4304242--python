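"""Confidence-thresholded self-training.

The loop: train a model µ on the labelled pool Λ, classify the unlabelled
pool Υ, move every instance whose confidence strictly exceeds the threshold
τ into Λ with its predicted label, and repeat until Υ is empty. When no
instance clears τ the loop is *blocked* and a stage-specific policy selects
at least one instance from the top 5% of confidences; a policy that selects
nothing is a hard error. τ = 0 therefore degenerates to a single supervised
pass that labels everything at once.

Blocked-state policies
----------------------
* Trigger stage: a candidate must satisfy at least two of five equally
  weighted rules — (1) its lemma belongs to a lexicon pre-compiled from the
  trigger lemmas currently in Λ, (2) one of its first three ancestor
  constituents is VP, NP or S, (3) it c-commands a VP or NP, (4) it
  VP-commands a VP or NP, (5) it bears no biomedical meaning (not a named
  entity, not an event trigger, no concept-dictionary type).
* Argument-position stage: a sentence-initial trigger signals DS, any other
  SS.
* Other stages: promote the single highest-confidence instance.

The candidate pool (top 5%) is recomputed at every loop.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import pandas as pd

from .errors import BlockedStateError, SamplingError

RATIOS = ("1:1", "1:2", "1:5", "natural")


@dataclass
class Instance:
    """One classification instance: an id, a feature dict, an optional
    label, and free-form metadata (provenance, loop index, …)."""

    uid: str
    features: dict
    label: Optional[str] = None
    meta: dict = field(default_factory=dict)


@dataclass
class SelfTrainConfig:
    tau: float = 0.8
    seed_fraction: float = 1.0
    ratio: str | float = "natural"
    max_loops: Optional[int] = None
    rng_seed: int = 13
    top_fraction: float = 0.05  # blocked-state candidate pool

    def __post_init__(self):
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must be in [0,1], got {self.tau}")
        if not 0.0 < self.seed_fraction <= 1.0:
            raise ValueError("seed_fraction must be in (0,1]")


@dataclass
class LoopRecord:
    loop: int
    promoted: int
    heuristic: int
    pool_size: int


@dataclass
class SelfTrainState:
    labelled: list[Instance]
    unlabelled: list[Instance]
    model: Optional[object] = None
    loop: int = 0
    ledger: list[LoopRecord] = field(default_factory=list)


@dataclass
class SelfTrainResult:
    model: object
    labelled: list[Instance]
    ledger: list[LoopRecord]

    @property
    def loops(self) -> int:
        return len(self.ledger)


# ---------------------------------------------------------------------------
# Blocked-state policies
# ---------------------------------------------------------------------------

def top_pool(predictions: Sequence[tuple[Instance, str, float]],
             fraction: float) -> list[tuple[Instance, str, float]]:
    """The top ``fraction`` of predictions by confidence (at least one)."""
    k = max(1, math.ceil(fraction * len(predictions)))
    return sorted(predictions, key=lambda p: -p[2])[:k]


@dataclass
class TriggerBlockedPolicy:
    """Rule-filtered promotion for the trigger-detection stage."""

    positive_label: str = "B"
    min_rules: int = 2
    lexicon: Optional[set[str]] = None  # None → recompiled from Λ per call

    def _compile_lexicon(self, labelled: Sequence[Instance]) -> set[str]:
        lex = set()
        for inst in labelled:
            if inst.label is not None and inst.label != "O":
                lemma = inst.features.get("L2")
                if lemma:
                    lex.update(str(lemma).lower().split())
        return lex

    def rules_satisfied(self, inst: Instance, lexicon: set[str]) -> int:
        f = inst.features
        n = 0
        if str(f.get("L2", "")).lower() in lexicon:
            n += 1
        if any(f.get(f"X8.{i}") in ("VP", "NP", "S") for i in (1, 2, 3)):
            n += 1
        if f.get("C2") or f.get("C3"):
            n += 1
        if f.get("C8") or f.get("C9"):
            n += 1
        if not (f.get("S1") or f.get("S3") or f.get("S6")):
            n += 1
        return n

    def __call__(self, state: SelfTrainState,
                 predictions: Sequence[tuple[Instance, str, float]],
                 fraction: float) -> list[tuple[Instance, str]]:
        lexicon = (self.lexicon if self.lexicon is not None
                   else self._compile_lexicon(state.labelled))
        selected = []
        for inst, _label, _conf in top_pool(predictions, fraction):
            if self.rules_satisfied(inst, lexicon) >= self.min_rules:
                selected.append((inst, self.positive_label))
        return selected


def argument_position_policy(state: SelfTrainState,
                             predictions: Sequence[tuple[Instance, str, float]],
                             fraction: float) -> list[tuple[Instance, str]]:
    """Sentence-initial trigger → DS, otherwise SS, applied to the top-5%
    pool."""
    out = []
    for inst, _label, _conf in top_pool(predictions, fraction):
        out.append((inst, "DS" if inst.features.get("P1", 1) == 0 else "SS"))
    return out


def max_confidence_policy(state: SelfTrainState,
                          predictions: Sequence[tuple[Instance, str, float]],
                          fraction: float) -> list[tuple[Instance, str]]:
    """Minimal intervention: promote the single most confident prediction
    with its predicted label."""
    best = max(predictions, key=lambda p: p[2])
    return [(best[0], best[1])]


Policy = Callable[[SelfTrainState, Sequence[tuple[Instance, str, float]], float],
                  list[tuple[Instance, str]]]


def token_trigger_instances(docs) -> list[Instance]:
    """Token-level trigger instances (BIO labels) for a document set —
    the instance space of trigger-stage self-training."""
    from .feature_extraction import token_features

    instances = []
    for doc in docs:
        tags: dict[tuple[int, int], str] = {}
        for rel in doc.relations:
            tags[(rel.trigger.sentence, rel.trigger.first)] = "B"
            for i in range(rel.trigger.first + 1, rel.trigger.last + 1):
                tags[(rel.trigger.sentence, i)] = "I"
        for sent in doc.sentences:
            for tok in sent.tokens:
                instances.append(Instance(
                    uid=f"{doc.doc_id}:{sent.index}:{tok.index}",
                    features=token_features(doc, sent.index, tok.index, "TS"),
                    label=tags.get((sent.index, tok.index), "O")))
    return instances


# ---------------------------------------------------------------------------
# Core loop
# ---------------------------------------------------------------------------

def promote(state: SelfTrainState,
            predictions: Sequence[tuple[Instance, str, float]],
            tau: float, policy: Optional[Policy],
            top_fraction: float = 0.05) -> LoopRecord:
    """Move confident instances from Υ to Λ in place.

    Every instance with confidence strictly above ``tau`` is promoted with
    its predicted label; if none clears the threshold the blocked-state
    ``policy`` must select at least one, else :class:`BlockedStateError`.
    """
    state.loop += 1
    confident = [(inst, label) for inst, label, conf in predictions
                 if conf > tau]
    heuristic = 0
    if not confident:
        if policy is None:
            raise BlockedStateError(state.loop)
        confident = policy(state, predictions, top_fraction)
        if not confident:
            raise BlockedStateError(state.loop)
        heuristic = len(confident)
    chosen = {id(inst) for inst, _ in confident}
    for inst, label in confident:
        inst.label = label
        inst.meta["provenance"] = ("heuristic-promoted" if heuristic
                                   else "threshold-promoted")
        inst.meta["loop"] = state.loop
        state.labelled.append(inst)
    state.unlabelled = [i for i in state.unlabelled if id(i) not in chosen]
    record = LoopRecord(loop=state.loop, promoted=len(confident),
                        heuristic=heuristic,
                        pool_size=len(predictions))
    state.ledger.append(record)
    return record


def self_train(seed_labelled: Sequence[Instance],
               unlabelled: Sequence[Instance],
               learner_factory: Callable[[], object],
               config: SelfTrainConfig,
               policy: Optional[Policy] = None) -> SelfTrainResult:
    """Run the loop to exhaustion and return the final model plus the fully
    labelled corpus with provenance."""
    if not seed_labelled:
        raise ValueError("seed set must be non-empty")
    for inst in seed_labelled:
        inst.meta.setdefault("provenance", "seed")
    state = SelfTrainState(labelled=list(seed_labelled),
                           unlabelled=list(unlabelled))
    max_loops = (config.max_loops if config.max_loops is not None
                 else len(state.unlabelled) + 1)
    while state.unlabelled:
        if state.loop >= max_loops:
            raise BlockedStateError(
                state.loop, f"loop guard exceeded at loop {state.loop}")
        model = learner_factory()
        model.fit([i.features for i in state.labelled],
                  [i.label for i in state.labelled])
        state.model = model
        preds = model.predict([i.features for i in state.unlabelled])
        predictions = [(inst, label, conf)
                       for inst, (label, conf) in zip(state.unlabelled, preds)]
        promote(state, predictions, config.tau, policy, config.top_fraction)
    # final refit on the complete labelled pool
    model = learner_factory()
    model.fit([i.features for i in state.labelled],
              [i.label for i in state.labelled])
    return SelfTrainResult(model=model, labelled=state.labelled,
                           ledger=state.ledger)


# ---------------------------------------------------------------------------
# Seed construction and the experiment grid
# ---------------------------------------------------------------------------

def _ratio_multiplier(ratio: str | float, n_pos: int, n_neg: int) -> float:
    if isinstance(ratio, (int, float)):
        return float(ratio)
    if ratio == "natural":
        if n_pos == 0:
            raise SamplingError("natural ratio undefined without positives")
        return n_neg / n_pos
    try:
        one, k = ratio.split(":")
        if one.strip() != "1":
            raise ValueError
        return float(k)
    except ValueError as exc:
        raise SamplingError(f"unrecognised ratio {ratio!r}") from exc


def build_seed(instances: Sequence[Instance], fraction: float,
               ratio: str | float, rng_seed: int,
               positive: Callable[[Instance], bool] | None = None
               ) -> list[Instance]:
    """Sample a seed set: ``round(fraction × positives)`` positive
    instances plus negatives at the requested positive:negative ratio,
    without replacement, reproducibly."""
    if not 0.0 < fraction <= 1.0:
        raise SamplingError("fraction must be in (0,1]")
    if positive is None:
        positive = lambda inst: inst.label not in (None, "O")
    rng = random.Random(rng_seed)
    pos = [i for i in instances if positive(i)]
    neg = [i for i in instances if not positive(i)]
    n_pos = round(fraction * len(pos))
    if n_pos == 0:
        raise SamplingError("seed fraction selects zero positive instances")
    mult = _ratio_multiplier(ratio, len(pos), len(neg))
    n_neg = round(n_pos * mult)
    if n_neg > len(neg):
        raise SamplingError(
            f"requested {n_neg} negatives but only {len(neg)} available")
    chosen = rng.sample(pos, n_pos) + rng.sample(neg, n_neg)
    rng.shuffle(chosen)
    return chosen


def _prf(gold: Sequence[str], pred: Sequence[str],
         positive_label: str) -> tuple[float, float, float]:
    tp = sum(1 for g, p in zip(gold, pred)
             if g == positive_label and p == positive_label)
    fp = sum(1 for g, p in zip(gold, pred)
             if g != positive_label and p == positive_label)
    fn = sum(1 for g, p in zip(gold, pred)
             if g == positive_label and p != positive_label)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


def _split_swap_folds(instances: Sequence[Instance],
                      rng: random.Random) -> list[tuple[list, list]]:
    """Two equally sized label-stratified halves, used seed/test and then
    swapped."""
    by_label: dict[str, list[Instance]] = {}
    for inst in instances:
        by_label.setdefault(inst.label, []).append(inst)
    half_a, half_b = [], []
    for group in by_label.values():
        group = group[:]
        rng.shuffle(group)
        half_a.extend(group[::2])
        half_b.extend(group[1::2])
    return [(half_a, half_b), (half_b, half_a)]


def run_grid(labelled: Sequence[Instance], unlabelled: Sequence[Instance],
             learner_names: Sequence[str],
             taus: Sequence[float] = (0.6, 0.7, 0.8, 0.9),
             fractions: Sequence[float] = tuple(i / 8 for i in range(1, 9)),
             ratios: Sequence[str | float] = RATIOS,
             reps: int = 1, rng_seed: int = 13,
             positive_label: str = "B",
             policy: Optional[Policy] = None,
             learner_factory: Optional[Callable[[str], object]] = None
             ) -> pd.DataFrame:
    """The experiment grid: per (learner, τ, seed fraction, ratio) cell,
    self-train on each of the two split-swap folds for ``reps``
    repetitions, score P/R/F of the positive label on the held-out half,
    and average. Loop counts are averaged alongside."""
    from .learners import make_classifier

    if learner_factory is None:
        learner_factory = lambda name: make_classifier(name, seed=rng_seed)
    rng = random.Random(rng_seed)
    folds = _split_swap_folds(labelled, rng)
    rows = []
    for name in learner_names:
        for tau in taus:
            for fraction in fractions:
                for ratio in ratios:
                    scores, loops = [], []
                    for rep in range(reps):
                        for fi, (train_half, test_half) in enumerate(folds):
                            sub_seed = rng_seed + 997 * rep + 31 * fi
                            try:
                                seed_set = build_seed(
                                    train_half, fraction, ratio, sub_seed)
                            except SamplingError:
                                seed_set = None
                            if seed_set is None:
                                continue
                            pool = [Instance(uid=i.uid, features=i.features)
                                    for i in unlabelled]
                            cfg = SelfTrainConfig(tau=tau,
                                                  seed_fraction=fraction,
                                                  ratio=ratio,
                                                  rng_seed=sub_seed)
                            result = self_train(
                                [replace(i, meta={}) for i in seed_set],
                                pool, lambda: learner_factory(name), cfg,
                                policy=policy or max_confidence_policy)
                            preds = result.model.predict(
                                [i.features for i in test_half])
                            gold = [i.label for i in test_half]
                            scores.append(_prf(gold, [p for p, _ in preds],
                                               positive_label))
                            loops.append(result.loops)
                    if not scores:
                        continue
                    p = sum(s[0] for s in scores) / len(scores)
                    r = sum(s[1] for s in scores) / len(scores)
                    f = sum(s[2] for s in scores) / len(scores)
                    rows.append({"learner": name, "tau": tau,
                                 "fraction": fraction, "ratio": str(ratio),
                                 "P": p, "R": r, "F": f,
                                 "loops": sum(loops) / len(loops),
                                 "runs": len(scores)})
    return pd.DataFrame(rows)
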