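"""Corpus serialisation: brat-style standoff, token layer, bracketed parses.

File layout per document (all plain text, shared basename):

* ``<id>.txt``   — raw text.
* ``<id>.ann``   — brat standoff. Text-bound ``T`` lines carry named
  entities (their semantic type), event triggers and causal triggers
  (type ``Causality``) and causal arguments (type ``Argument``);
  ``E`` lines bind them: ``E1\tCausality:T1 Cause:T2 Effect:T3`` for a
  causal relation, ``E2\t<EventType>:T4`` for a bare event trigger.
* ``<id>.tok``   — token layer, 4 tab-separated columns per token
  (surface, lemma, PoS, char start), blank line between sentences.
* ``<id>.parse`` — one bracketed constituency parse per line, one line per
  sentence.
* ``<id>.arcs``  — optional predicate-argument arcs, tab-separated
  (sentence index, head token index, dependent token index, role label).
* ``<id>.lex.json`` — optional dictionary providers
  (``{"hypernyms": {...}, "concepts": {...}}``).

Round-trips on ``.ann`` are byte-stable: writing, reading and re-writing
produces identical bytes.
"""

from __future__ import annotations

import json
from pathlib import Path

from .doc_model import (
    AnnotatedDocument,
    CausalRelation,
    CAUSE,
    CTE,
    DS,
    EFFECT,
    ETC,
    PasArc,
    Sentence,
    Span,
    SS,
    SemanticLayer,
    Token,
    TypedSpan,
)
from .errors import FormatError
from .tree_features import ConstituencyTree

TRIGGER_TYPE = "Causality"
ARGUMENT_TYPE = "Argument"


def read_bracketed_tree(text: str) -> ConstituencyTree:
    """Parse one Penn-Treebank-style bracketed tree."""
    if not text.strip():
        raise FormatError("empty parse line")
    return ConstituencyTree.from_string(text)


def write_bracketed_tree(tree: ConstituencyTree) -> str:
    return tree.to_string()


# ---------------------------------------------------------------------------
# Token layer
# ---------------------------------------------------------------------------

def parse_token_layer(text: str, raw_text: str) -> list[Sentence]:
    sentences: list[Sentence] = []
    current: list[Token] = []
    for lineno, line in enumerate(text.split("\n"), start=1):
        if not line.strip():
            if current:
                sentences.append(Sentence(index=len(sentences), tokens=current))
                current = []
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise FormatError(f"token line {lineno}: expected 4 columns, "
                              f"got {len(cols)}")
        surface, lemma, pos, start_s = cols
        start = int(start_s)
        end = start + len(surface)
        if raw_text[start:end] != surface:
            raise FormatError(
                f"token line {lineno}: surface {surface!r} does not match "
                f"text slice [{start},{end})"
            )
        current.append(Token(index=len(current), surface=surface,
                             lemma=lemma, pos=pos, start=start, end=end))
    if current:
        sentences.append(Sentence(index=len(sentences), tokens=current))
    return sentences


def write_token_layer(doc: AnnotatedDocument) -> str:
    blocks = []
    for sent in doc.sentences:
        blocks.append("\n".join(
            f"{t.surface}\t{t.lemma}\t{t.pos}\t{t.start}" for t in sent.tokens
        ))
    return "\n\n".join(blocks) + "\n"


def parse_arc_layer(text: str) -> dict[int, list[PasArc]]:
    arcs: dict[int, list[PasArc]] = {}
    for lineno, line in enumerate(text.split("\n"), start=1):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise FormatError(f"arc line {lineno}: expected 4 columns")
        si, head, dep, label = cols
        arcs.setdefault(int(si), []).append(
            PasArc(head=int(head), dep=int(dep), label=label)
        )
    return arcs


def write_arc_layer(doc: AnnotatedDocument) -> str:
    lines = []
    for sent in doc.sentences:
        for arc in sent.arcs:
            lines.append(f"{sent.index}\t{arc.head}\t{arc.dep}\t{arc.label}")
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Standoff annotations
# ---------------------------------------------------------------------------

def _char_span(doc: AnnotatedDocument, span: Span) -> tuple[int, int]:
    toks = doc.slice(span)
    return toks[0].start, toks[-1].end


def _token_span(doc: AnnotatedDocument, start: int, end: int,
                record_id: str) -> Span:
    """Map a character span back to a token span; must align with token
    boundaries."""
    for sent in doc.sentences:
        if sent.start <= start and end <= sent.end:
            first = last = None
            for tok in sent.tokens:
                if tok.start == start:
                    first = tok.index
                if tok.end == end:
                    last = tok.index
            if first is None or last is None or first > last:
                raise FormatError(
                    f"record {record_id}: char span [{start},{end}) does not "
                    f"align with token boundaries"
                )
            return Span(sentence=sent.index, first=first, last=last)
    raise FormatError(f"record {record_id}: char span [{start},{end}) crosses "
                      f"sentence boundaries or exceeds the document")


def _derive_relation(doc: AnnotatedDocument, trigger: Span, cause: Span,
                     effect: Span) -> CausalRelation:
    """Assemble a relation from role spans.

    Dependent argument: for DS the argument in the trigger's sentence; for
    SS the argument that starts after the trigger (or, failing that, the one
    closer to it). Direction: CTE iff the dependent argument is the Effect.
    """
    if cause.sentence == effect.sentence == trigger.sentence:
        position = SS
        after = [s for s in (cause, effect) if s.first > trigger.last]
        if len(after) == 1:
            dep = after[0]
        else:
            dep = min((cause, effect),
                      key=lambda s: min(abs(s.first - trigger.last),
                                        abs(trigger.first - s.last)))
    else:
        position = DS
        dep = cause if cause.sentence == trigger.sentence else effect
    ind = effect if dep is cause else cause
    direction = CTE if dep is effect else ETC
    return CausalRelation(trigger=trigger, dep_arg=dep, ind_arg=ind,
                          position=position, direction=direction)


def parse_ann(text: str, doc: AnnotatedDocument) -> tuple[
        list[CausalRelation], list[TypedSpan], list[TypedSpan]]:
    """Parse a .ann body into (relations, named entities, event triggers)."""
    tspans: dict[str, tuple[str, Span]] = {}
    elines: list[tuple[str, str, dict[str, str]]] = []
    for lineno, line in enumerate(text.split("\n"), start=1):
        if not line.strip():
            continue
        if line[0] == "T":
            try:
                tid, middle, covered = line.split("\t")
                type_label, start_s, end_s = middle.split(" ")
            except ValueError as exc:
                raise FormatError(f".ann line {lineno}: malformed T line") from exc
            start, end = int(start_s), int(end_s)
            if doc.text[start:end] != covered:
                raise FormatError(
                    f"record {tid}: covered text {covered!r} does not match "
                    f"document slice [{start},{end})"
                )
            tspans[tid] = (type_label, _token_span(doc, start, end, tid))
        elif line[0] == "E":
            eid, body = line.split("\t")
            parts = body.split(" ")
            head_type, head_ref = parts[0].split(":")
            roles = {}
            for part in parts[1:]:
                role, ref = part.split(":")
                roles[role] = ref
            elines.append((eid, head_ref, roles))
        else:
            raise FormatError(f".ann line {lineno}: unsupported record type "
                              f"{line[0]!r}")

    relations: list[CausalRelation] = []
    events: list[TypedSpan] = []
    referenced: set[str] = set()
    for eid, head_ref, roles in elines:
        if head_ref not in tspans:
            raise FormatError(f"record {eid}: dangling reference {head_ref}")
        referenced.add(head_ref)
        head_type, head_span = tspans[head_ref]
        if CAUSE in roles or EFFECT in roles:
            if CAUSE not in roles or EFFECT not in roles:
                raise FormatError(f"record {eid}: needs both Cause and Effect")
            for ref in roles.values():
                if ref not in tspans:
                    raise FormatError(f"record {eid}: dangling reference {ref}")
                referenced.add(ref)
            relations.append(_derive_relation(
                doc, head_span, tspans[roles[CAUSE]][1], tspans[roles[EFFECT]][1]
            ))
        else:
            events.append(TypedSpan(span=head_span, type=head_type))

    entities = [TypedSpan(span=span, type=type_label)
                for tid, (type_label, span) in tspans.items()
                if tid not in referenced]
    return relations, entities, events


def write_ann(doc: AnnotatedDocument) -> str:
    """Render relations, entities and events as a .ann body.

    Output order is canonical (entities, then events, then relations, each
    by offset), so write→read→write is byte-identical.
    """
    lines: list[str] = []
    tid = eid = 0

    def t_line(type_label: str, span: Span) -> str:
        nonlocal tid
        tid += 1
        start, end = _char_span(doc, span)
        lines.append(f"T{tid}\t{type_label} {start} {end}\t{doc.text[start:end]}")
        return f"T{tid}"

    def e_line(body: str) -> None:
        nonlocal eid
        eid += 1
        lines.append(f"E{eid}\t{body}")

    for ts in sorted(doc.semantics.entities, key=lambda ts: ts.span):
        t_line(ts.type, ts.span)
    for ts in sorted(doc.semantics.events, key=lambda ts: ts.span):
        ref = t_line(ts.type, ts.span)
        e_line(f"{ts.type}:{ref}")
    for rel in sorted(doc.relations, key=lambda r: (r.trigger, r.dep_arg)):
        trig_ref = t_line(TRIGGER_TYPE, rel.trigger)
        cause_ref = t_line(ARGUMENT_TYPE, rel.cause)
        effect_ref = t_line(ARGUMENT_TYPE, rel.effect)
        e_line(f"{TRIGGER_TYPE}:{trig_ref} {CAUSE}:{cause_ref} "
               f"{EFFECT}:{effect_ref}")
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Whole documents and corpora
# ---------------------------------------------------------------------------

EXTENSIONS = (".txt", ".ann", ".tok", ".parse")


def document_to_files(doc: AnnotatedDocument) -> dict[str, str]:
    """Render a document as a mapping extension → file content."""
    files = {
        ".txt": doc.text,
        ".ann": write_ann(doc),
        ".tok": write_token_layer(doc),
        ".parse": "\n".join(
            write_bracketed_tree(s.tree) for s in doc.sentences) + "\n",
    }
    arcs = write_arc_layer(doc)
    if arcs:
        files[".arcs"] = arcs
    if doc.semantics.hypernyms or doc.semantics.concepts:
        files[".lex.json"] = json.dumps(
            {"hypernyms": doc.semantics.hypernyms,
             "concepts": doc.semantics.concepts},
            indent=0, sort_keys=True) + "\n"
    return files


def document_from_files(doc_id: str, files: dict[str, str]) -> AnnotatedDocument:
    for ext in EXTENSIONS:
        if ext not in files:
            raise FormatError(f"{doc_id}: missing {ext} layer")
    text = files[".txt"]
    sentences = parse_token_layer(files[".tok"], text)
    parse_lines = [ln for ln in files[".parse"].split("\n") if ln.strip()]
    if len(parse_lines) != len(sentences):
        raise FormatError(
            f"{doc_id}: {len(parse_lines)} parses for {len(sentences)} sentences"
        )
    for sent, line in zip(sentences, parse_lines):
        tree = read_bracketed_tree(line)
        if len(tree.leaves) != len(sent.tokens):
            raise FormatError(
                f"{doc_id}: sentence {sent.index} parse leaf count "
                f"{len(tree.leaves)} != token count {len(sent.tokens)}"
            )
        tree.bind_tokens(sent.tokens)
        sent.tree = tree
    if ".arcs" in files:
        arc_map = parse_arc_layer(files[".arcs"])
        for sent in sentences:
            sent.arcs = tuple(arc_map.get(sent.index, []))
    semantics = SemanticLayer()
    if ".lex.json" in files:
        lex = json.loads(files[".lex.json"])
        semantics.hypernyms = dict(lex.get("hypernyms", {}))
        semantics.concepts = dict(lex.get("concepts", {}))
    doc = AnnotatedDocument(doc_id=doc_id, text=text, sentences=sentences,
                            semantics=semantics)
    relations, entities, events = parse_ann(files[".ann"], doc)
    doc.relations = relations
    semantics.entities = entities
    semantics.events = events
    doc.validate()
    return doc


def write_document(doc: AnnotatedDocument, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ext, content in document_to_files(doc).items():
        (directory / f"{doc.doc_id}{ext}").write_text(content)


def read_document(doc_id: str, directory: str | Path) -> AnnotatedDocument:
    directory = Path(directory)
    files = {}
    for ext in EXTENSIONS + (".arcs", ".lex.json"):
        path = directory / f"{doc_id}{ext}"
        if path.exists():
            files[ext] = path.read_text()
    return document_from_files(doc_id, files)


def write_corpus(docs: list[AnnotatedDocument], directory: str | Path) -> None:
    for doc in docs:
        write_document(doc, directory)


def read_corpus(directory: str | Path) -> list[AnnotatedDocument]:
    directory = Path(directory)
    return [read_document(p.stem, directory)
            for p in sorted(directory.glob("*.txt"))]
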