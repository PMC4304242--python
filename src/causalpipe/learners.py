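"""Classifier adapters behind uniform contracts.

Two contracts drive the pipeline:

* :class:`InstanceClassifier` — ``fit`` on labelled feature dicts,
  ``predict`` returns ``(label, confidence)`` with confidence in [0, 1],
  comparable across instances of one model (the self-training loop only
  needs a total order against its threshold);
* :class:`SequenceLabeller` — ``fit`` on token sequences with BIO tags,
  ``predict`` returns a BIO-consistent tag sequence plus per-span
  confidences (geometric mean of the per-token marginals over the span).

All adapters vectorise feature dicts with a ``DictVectorizer`` (string
values one-hot encoded, numeric values passed through). Margin-based
classifiers report confidence through a logistic squash of the decision
value; probabilistic ones report the maximum class probability. Sequence
labelling is realised as a windowed maximum-entropy per-token tagger with
BIO-consistency repair (stray ``I`` opens a new span).
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import MultinomialNB
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .errors import AlignmentError, NotFittedError

DEFAULT_SEED = 13

LEARNER_NAMES = ("maxent", "nb", "svm", "rf", "j48", "rules", "vote")


def _as_int32(M):
    # some estimators only accept 32-bit sparse indices
    M = M.tocsr()
    M.indices = M.indices.astype(np.int32, copy=False)
    M.indptr = M.indptr.astype(np.int32, copy=False)
    return M


class InstanceClassifier:
    """One estimator behind the instance-classification contract."""

    def __init__(self, name: str, estimator, probabilistic: bool):
        self.name = name
        self._vec = DictVectorizer(sparse=True)
        self._est = estimator
        self._probabilistic = probabilistic
        self._fitted = False

    def fit(self, X: Sequence[dict], y: Sequence[str]) -> "InstanceClassifier":
        if not len(X):
            raise ValueError("cannot fit on an empty training set")
        M = _as_int32(self._vec.fit_transform(X))
        self._est.fit(M, list(y))
        self._fitted = True
        return self

    @property
    def classes_(self) -> list[str]:
        self._require_fitted()
        return list(self._est.classes_)

    def _require_fitted(self):
        if not self._fitted:
            raise NotFittedError(f"classifier {self.name!r} is not fitted")

    def predict(self, X: Sequence[dict]) -> list[tuple[str, float]]:
        self._require_fitted()
        if not len(X):
            return []
        M = _as_int32(self._vec.transform(X))
        proba = self._class_proba(M)
        idx = np.argmax(proba, axis=1)
        classes = self._est.classes_
        return [(classes[i], float(proba[r, i]))
                for r, i in enumerate(idx)]

    def predict_one(self, x: dict) -> tuple[str, float]:
        return self.predict([x])[0]

    def predict_proba(self, X: Sequence[dict]) -> tuple[list[str], np.ndarray]:
        """Class order plus a (n, k) matrix of class scores in [0, 1]."""
        self._require_fitted()
        M = _as_int32(self._vec.transform(X))
        return list(self._est.classes_), self._class_proba(M)

    def _class_proba(self, M) -> np.ndarray:
        if self._probabilistic:
            return self._est.predict_proba(M)
        # margin-based: logistic squash / softmax of decision values
        dec = self._est.decision_function(M)
        if dec.ndim == 1:  # binary
            p1 = 1.0 / (1.0 + np.exp(-dec))
            return np.column_stack([1.0 - p1, p1])
        dec = dec - dec.max(axis=1, keepdims=True)
        e = np.exp(dec)
        return e / e.sum(axis=1, keepdims=True)


class VoteEnsemble:
    """Majority vote over five base classifiers.

    The prediction is the majority label; ties are broken by the highest
    mean confidence among the tied labels' agreeing bases, then by fixed
    base order. The reported confidence is the mean confidence of the
    agreeing bases.
    """

    def __init__(self, bases: Optional[list[InstanceClassifier]] = None,
                 seed: int = DEFAULT_SEED):
        if bases is None:
            bases = [make_classifier(n, seed=seed)
                     for n in ("nb", "svm", "rules", "j48", "rf")]
        self.name = "vote"
        self.bases = bases

    def fit(self, X: Sequence[dict], y: Sequence[str]) -> "VoteEnsemble":
        for base in self.bases:
            base.fit(X, y)
        return self

    @property
    def classes_(self) -> list[str]:
        return self.bases[0].classes_

    def predict(self, X: Sequence[dict]) -> list[tuple[str, float]]:
        if len(self.bases) < 3:
            raise ValueError("vote requires at least 3 fitted bases")
        per_base = [base.predict(X) for base in self.bases]
        out = []
        for i in range(len(X)):
            out.append(combine_votes([pb[i] for pb in per_base]))
        return out

    def predict_one(self, x: dict) -> tuple[str, float]:
        return self.predict([x])[0]


def combine_votes(votes: Sequence[tuple[str, float]]) -> tuple[str, float]:
    """Majority label with mean-of-agreeing confidence; ties broken by the
    higher mean confidence, then by base order."""
    counts: dict[str, int] = {}
    confs: dict[str, list[float]] = {}
    first_seen: dict[str, int] = {}
    for order, (label, conf) in enumerate(votes):
        counts[label] = counts.get(label, 0) + 1
        confs.setdefault(label, []).append(conf)
        first_seen.setdefault(label, order)
    best = max(counts.values())
    tied = [lab for lab, c in counts.items() if c == best]
    if len(tied) > 1:
        tied.sort(key=lambda lab: (-sum(confs[lab]) / len(confs[lab]),
                                   first_seen[lab]))
    label = tied[0]
    return label, sum(confs[label]) / len(confs[label])


def make_classifier(name: str, seed: int = DEFAULT_SEED):
    """Factory for the learner inventory.

    ``maxent`` logistic regression; ``nb`` multinomial naive Bayes (feature
    values are non-negative by construction); ``svm`` a linear-margin
    classifier with logistic-squashed confidence; ``rf`` a random forest;
    ``j48`` an entropy-criterion decision tree; ``rules`` a depth-limited
    decision tree read as an ordered rule list; ``vote`` the five-base
    majority ensemble.
    """
    if name == "maxent":
        # balanced class weights: trigger tokens are ~50x rarer than
        # negatives, and unweighted fits sacrifice rare trigger types
        return InstanceClassifier(
            name, LogisticRegression(max_iter=2000, class_weight="balanced"),
            probabilistic=True)
    if name == "nb":
        return InstanceClassifier(name, MultinomialNB(alpha=0.5),
                                  probabilistic=True)
    if name == "svm":
        return InstanceClassifier(name, LinearSVC(random_state=seed),
                                  probabilistic=False)
    if name == "rf":
        return InstanceClassifier(
            name, RandomForestClassifier(n_estimators=60, random_state=seed),
            probabilistic=True)
    if name == "j48":
        return InstanceClassifier(
            name, DecisionTreeClassifier(criterion="entropy", random_state=seed),
            probabilistic=True)
    if name == "rules":
        return InstanceClassifier(
            name, DecisionTreeClassifier(criterion="entropy", max_depth=3,
                                         random_state=seed),
            probabilistic=True)
    if name == "vote":
        return VoteEnsemble(seed=seed)
    raise ValueError(f"unknown learner {name!r}; choose from {LEARNER_NAMES}")


# ---------------------------------------------------------------------------
# Sequence labelling
# ---------------------------------------------------------------------------

def repair_bio(tags: Sequence[str]) -> list[str]:
    """Make a tag sequence BIO-consistent: a stray ``I``(-type) without a
    matching open span becomes ``B``(-type)."""
    out = []
    prev = "O"
    for tag in tags:
        if tag.startswith("I"):
            ty = tag[1:]
            if not (prev.startswith("B") or prev.startswith("I")) \
                    or prev[1:] != ty:
                tag = "B" + ty
        out.append(tag)
        prev = tag
    return out


def spanify(tags: Sequence[str],
            n_tokens: Optional[int] = None) -> list[tuple[int, int, str]]:
    """Maximal B..I runs as ``(first, last, type)`` triples; the type is
    ``""`` for untyped BIO. Input is repaired first."""
    if n_tokens is not None and len(tags) != n_tokens:
        raise AlignmentError(f"{len(tags)} tags for {n_tokens} tokens")
    spans = []
    tags = repair_bio(tags)
    start = None
    ty = ""
    for i, tag in enumerate(tags):
        if tag.startswith("B"):
            if start is not None:
                spans.append((start, i - 1, ty))
            start, ty = i, tag[1:].lstrip("-")
        elif tag.startswith("I"):
            continue
        else:
            if start is not None:
                spans.append((start, i - 1, ty))
                start = None
    if start is not None:
        spans.append((start, len(tags) - 1, ty))
    return spans


class SequenceLabeller:
    """BIO token tagger with span confidences.

    A maximum-entropy classifier scores each token (the feature dicts are
    expected to carry the neighbour windows, so the tagger sees local
    context); decoding takes the per-token argmax and repairs the sequence
    to be BIO-consistent. Span confidence is the geometric mean of the
    chosen-tag marginals over the span.
    """

    def __init__(self, seed: int = DEFAULT_SEED, C: float = 2.0):
        self._clf = InstanceClassifier(
            "seq-maxent",
            LogisticRegression(max_iter=2000, C=C, class_weight="balanced"),
            probabilistic=True)
        self.seed = seed

    def fit(self, sequences: Sequence[Sequence[dict]],
            tag_sequences: Sequence[Sequence[str]]) -> "SequenceLabeller":
        X, y = [], []
        for seq, tags in zip(sequences, tag_sequences):
            if len(seq) != len(tags):
                raise AlignmentError(f"{len(tags)} tags for {len(seq)} tokens")
            X.extend(seq)
            y.extend(tags)
        self._clf.fit(X, y)
        return self

    def predict_marginals(self, sequence: Sequence[dict]) -> list[dict]:
        classes, proba = self._clf.predict_proba(list(sequence))
        return [dict(zip(classes, row)) for row in proba]

    def predict(self, sequence: Sequence[dict]) -> tuple[
            list[str], list[tuple[int, int, str, float]]]:
        """Tags plus spans as ``(first, last, type, confidence)``."""
        if not len(sequence):
            return [], []
        marginals = self.predict_marginals(sequence)
        raw = [max(m, key=m.get) for m in marginals]
        tags = repair_bio(raw)
        spans = []
        for first, last, ty in spanify(tags):
            logs = [math.log(max(marginals[i].get(tags[i], 1e-12), 1e-12))
                    for i in range(first, last + 1)]
            conf = math.exp(sum(logs) / len(logs))
            spans.append((first, last, ty, conf))
        return tags, spans


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

BUNDLE_VERSION = 1


def save_model(model, path) -> None:
    """Persist any adapter as a versioned bundle."""
    joblib.dump({"version": BUNDLE_VERSION, "model": model}, path)


def load_model(path):
    bundle = joblib.load(path)
    if bundle.get("version") != BUNDLE_VERSION:
        raise ValueError(f"unsupported model bundle version "
                         f"{bundle.get('version')}")
    return bundle["model"]
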