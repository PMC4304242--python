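"""Core document model.

A document is plain text plus layered annotations: a token layer (surface,
lemma, PoS, character offsets), one constituency parse per sentence, optional
predicate-argument arcs, optional semantic layers (named entities, event
triggers, dictionary lookups) and gold causal relations.

Conventions
-----------
* Character offsets are 0-based half-open (brat standoff convention).
* Token spans are inclusive ``(first, last)`` token-index pairs within one
  sentence; a cross-sentence independent argument is represented as a
  whole-sentence span.
* A causal relation is a trigger span plus a dependent argument (the clause
  or sentence syntactically attached to the trigger) and an independent
  argument. ``position`` says whether both arguments share the trigger's
  sentence (SS) or not (DS). ``direction`` is CTE when the dependent
  argument plays the Effect role and ETC when it plays the Cause role; for
  mid-sentence triggers this coincides with the linear
  Cause-Trigger-Effect / Effect-Trigger-Cause reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

from .errors import SpanError

SS = "SS"
DS = "DS"
CTE = "CTE"
ETC = "ETC"

CAUSE = "Cause"
EFFECT = "Effect"


@dataclass(frozen=True)
class Token:
    """One token of a sentence.

    ``index`` is the 0-based position within the sentence; ``start``/``end``
    are character offsets into the document text (half-open).
    """

    index: int
    surface: str
    lemma: str
    pos: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise SpanError(f"token char span [{self.start},{self.end}) is empty")


@dataclass(frozen=True)
class PasArc:
    """A predicate-argument / dependency link inside one sentence.

    ``head`` and ``dep`` are token indices; ``label`` is the role name
    (e.g. ARG1, aux).
    """

    head: int
    dep: int
    label: str


@dataclass
class Sentence:
    """An ordered token sequence with its parse and dependency arcs."""

    index: int
    tokens: list[Token]
    tree: Optional["object"] = None  # ConstituencyTree; untyped to avoid cycle
    arcs: tuple[PasArc, ...] = ()

    def __post_init__(self):
        for i, t in enumerate(self.tokens):
            if t.index != i:
                raise SpanError(
                    f"sentence {self.index}: token index {t.index} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def start(self) -> int:
        return self.tokens[0].start

    @property
    def end(self) -> int:
        return self.tokens[-1].end

    def arcs_with_head(self, index: int) -> list[PasArc]:
        return [a for a in self.arcs if a.head == index]

    def arcs_with_dep(self, index: int) -> list[PasArc]:
        return [a for a in self.arcs if a.dep == index]


@dataclass(frozen=True, order=True)
class Span:
    """A contiguous token span inside one sentence (inclusive indices)."""

    sentence: int
    first: int
    last: int

    def __post_init__(self):
        if self.first > self.last:
            raise SpanError(f"span first {self.first} > last {self.last}")
        if self.first < 0:
            raise SpanError(f"span first {self.first} < 0")

    def __len__(self) -> int:
        return self.last - self.first + 1

    def tokens(self) -> Iterator[int]:
        return iter(range(self.first, self.last + 1))

    def contains(self, sentence: int, index: int) -> bool:
        return sentence == self.sentence and self.first <= index <= self.last

    def overlaps(self, other: "Span") -> bool:
        return (
            self.sentence == other.sentence
            and self.first <= other.last
            and other.first <= self.last
        )


@dataclass(frozen=True)
class TypedSpan:
    """A span carrying a semantic type (named entity or event trigger)."""

    span: Span
    type: str


@dataclass
class CausalRelation:
    """Trigger + dependent/independent argument + position class + direction."""

    trigger: Span
    dep_arg: Span
    ind_arg: Span
    position: str  # SS | DS
    direction: str  # CTE | ETC

    def __post_init__(self):
        if self.position not in (SS, DS):
            raise SpanError(f"position must be SS or DS, got {self.position!r}")
        if self.direction not in (CTE, ETC):
            raise SpanError(f"direction must be CTE or ETC, got {self.direction!r}")
        if self.position == SS:
            if not (
                self.dep_arg.sentence
                == self.ind_arg.sentence
                == self.trigger.sentence
            ):
                raise SpanError("SS relation with arguments outside trigger sentence")
        else:
            if self.ind_arg.sentence == self.trigger.sentence:
                raise SpanError("DS relation with independent argument in "
                                "the trigger sentence")

    @property
    def cause(self) -> Span:
        return self.dep_arg if self.direction == ETC else self.ind_arg

    @property
    def effect(self) -> Span:
        return self.dep_arg if self.direction == CTE else self.ind_arg


@dataclass
class SemanticLayer:
    """Typed spans plus dictionary providers.

    The two dictionary providers are total: lookups return ``None`` for
    unknown keys. ``hypernyms`` maps a lemma to its first-sense hypernym;
    ``concepts`` maps a lemma to a domain concept type.
    """

    entities: list[TypedSpan] = field(default_factory=list)
    events: list[TypedSpan] = field(default_factory=list)
    hypernyms: dict[str, str] = field(default_factory=dict)
    concepts: dict[str, str] = field(default_factory=dict)

    def entity_type_at(self, sentence: int, index: int) -> Optional[str]:
        for ts in self.entities:
            if ts.span.contains(sentence, index):
                return ts.type
        return None

    def event_type_at(self, sentence: int, index: int) -> Optional[str]:
        for ts in self.events:
            if ts.span.contains(sentence, index):
                return ts.type
        return None

    def hypernym(self, lemma: str) -> Optional[str]:
        return self.hypernyms.get(lemma)

    def concept(self, lemma: str) -> Optional[str]:
        return self.concepts.get(lemma)


@dataclass
class AnnotatedDocument:
    doc_id: str
    text: str
    sentences: list[Sentence]
    semantics: SemanticLayer = field(default_factory=SemanticLayer)
    relations: list[CausalRelation] = field(default_factory=list)

    def sentence(self, index: int) -> Sentence:
        if not 0 <= index < len(self.sentences):
            raise IndexError(f"sentence index {index} out of range "
                             f"(document has {len(self.sentences)} sentences)")
        return self.sentences[index]

    def span_text(self, span: Span) -> str:
        toks = self.slice(span)
        return self.text[toks[0].start:toks[-1].end]

    def slice(self, span: Span) -> list[Token]:
        """The tokens covered by ``span``, in order."""
        sent = self.sentence(span.sentence)
        if span.last >= len(sent.tokens):
            raise SpanError(
                f"span {span} exceeds sentence of length {len(sent.tokens)}"
            )
        return sent.tokens[span.first:span.last + 1]

    def sentence_window(self, index: int, before: int, after: int) -> list[Sentence]:
        """Up to ``before`` preceding and ``after`` following sentences,
        truncated at document edges; the sentence itself is excluded."""
        if before < 0 or after < 0:
            raise ValueError("before/after must be non-negative")
        self.sentence(index)  # validates the index
        lo = max(0, index - before)
        hi = min(len(self.sentences), index + after + 1)
        return self.sentences[lo:index] + self.sentences[index + 1:hi]

    def validate(self) -> None:
        """Check every structural invariant; raise SpanError on violation."""
        prev_end = -1
        for sent in self.sentences:
            for tok in sent.tokens:
                if self.text[tok.start:tok.end] != tok.surface:
                    raise SpanError(
                        f"{self.doc_id}: token {tok.surface!r} does not match "
                        f"text slice [{tok.start},{tok.end})"
                    )
                if tok.start <= prev_end - len(tok.surface):
                    raise SpanError(f"{self.doc_id}: overlapping token offsets")
            if sent.start <= prev_end:
                raise SpanError(f"{self.doc_id}: sentences overlap or unordered")
            prev_end = sent.end
            if sent.tree is not None:
                leaves = sent.tree.leaves
                if len(leaves) != len(sent.tokens):
                    raise SpanError(
                        f"{self.doc_id}: sentence {sent.index} parse has "
                        f"{len(leaves)} leaves for {len(sent.tokens)} tokens"
                    )
        for rel in self.relations:
            for span in (rel.trigger, rel.dep_arg, rel.ind_arg):
                self.slice(span)
        for ts in self.semantics.entities + self.semantics.events:
            self.slice(ts.span)
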