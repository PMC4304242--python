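# Methods

This note documents the modelling choices behind `causalpipe`: the task
decomposition, the feature algebra, the learners, the self-training loop,
the synthetic study corpus, and the numerical and design decisions made
where the problem left them open.

## Task decomposition

An explicit causal discourse relation is a trigger plus two arguments.
The pipeline mirrors the way such corpora are annotated: find the trigger
(TS), decide whether the arguments share its sentence (AP: SS vs DS),
locate the argument spans (AS), and assign the Cause/Effect roles (AR).
Stages can be scored in isolation on gold inputs or chained, in which case
trigger errors propagate: our chained scorer counts a gold relation whose
trigger was missed as a false negative for *every* downstream stage, so a
chained score can never exceed the gold-input score of the same stage.
Only the C-T-E and E-T-C argument orders are modelled; rarer orders are out
of scope. We define the direction label by the role of the dependent
argument (CTE ⇔ dependent argument = Effect). For mid-sentence triggers
this coincides with the linear reading; for the trigger-initial
*Since/Because* pattern (annotated T-DA-IA) the label is ETC because the
dependent clause is the Cause.

## Tree algebra

Trees are rooted, ordered, labelled; leaves are preterminals carrying the
lexical category, while the word PoS lives on the token layer (deep-parser
convention: *that* is PoS IN, category P). Feature conventions that
matter:

* the root path (X5) includes the preterminal (`S/VP/VP/V`); the
  position-encoded path (X7) covers only phrasal ancestors, prefixed
  B/I/E by the leaf's position among the ancestor's leaves and C when it
  is the sole leaf (`I-S/I-VP/B-CP/C-CX`);
* collapsed variants delete consecutive duplicate labels and are
  idempotent;
* ancestor features (X8) are padded with the sentinel `none` past the
  root; the left-neighbour LCA (X9/X10) uses the same sentinel at
  sentence starts, and the distance is the edge count from the token's
  leaf to the LCA node;
* command relations use the relaxed definition: X commands Y iff the
  first proper ancestor of X with the relevant property dominates Y, with
  no co-dominance restriction and X ≠ Y. The "relevant property" is
  *branching node* for plain c-command and *label = S / VP* for S-/VP-
  command. Dominance is reflexive, so a node may command its own
  dominators — a deliberate consequence of dropping co-dominance, and the
  same definition the brute-force dominance-set oracle in the test suite
  implements literally. The choice of "first branching node" for plain
  c-command is isolated behind a single predicate.

## Features and stage masks

Every feature carries a stage mask (TS/AP/AS/AR); vectors only contain
features their stage enables, and missing context is encoded with an
explicit `NONE` sentinel, never silently dropped. Neighbour windows are
±5 tokens and never cross sentence boundaries. The coarse position P3
uses sentence edges (first token = Beginning, last = End) by default, with
a thirds-based discretisation available (`p3_scheme="thirds"`); the
problem statement fixes only that P3 is three-valued. The main verb is
the verbal leaf of the shallowest VP under the root, found by a small
head-percolation rule (prefer a direct verbal preterminal, else recurse
into a nested VP). Voice is passive iff the span's verb is a past
participle with a be-lemma auxiliary among its dependency links (falling
back to the immediately preceding token when no arcs exist). The
dependency table lists one feature twice (argument forms and role
labels); we keep both as D1a/D1b. The duplicate-collapsed category string
X14 is computed over the trigger, symmetric with X13. Trigger
capitalisation (L5) applies to the trigger's first token.

## Learners

All classifiers sit behind two small contracts (instance classification
with a confidence in [0,1]; BIO sequence labelling with per-span
confidences), so the pipeline runs unchanged with any of them. Sequence
labelling is a windowed maximum-entropy per-token tagger: the feature
dicts already carry the ±5 neighbour windows, decoding is per-token
argmax with BIO repair (a stray I opens a new span), and span confidence
is the geometric mean of the chosen-tag marginals — monotone in token
certainty and scale-free in span length. Margin-based classifiers squash
their decision values through a logistic (binary) or softmax (multiclass);
the self-training loop only needs a score comparable against τ, not
calibrated probabilities. The Vote meta-classifier takes the majority of
five bases (naive Bayes, linear SVM, rule list, entropy decision tree,
random forest); ties break by the higher mean confidence of the agreeing
bases, then fixed base order, and the reported confidence is the mean of
the agreeing bases. The "rules" learner is a depth-limited decision tree
read as an ordered rule list. Logistic-regression components use balanced
class weights: at a 1:50 positive rarity an unweighted fit sacrifices
exactly the rare trigger types, which is also why the pipeline's default
AP learner is the Vote ensemble rather than naive Bayes — NB's
independence assumption lets the sentence-initial position feature
overrule the decisive lexeme on trigger-initial SS patterns
(*Since …, …*), reproducing a known failure mode of the approach.

## Self-training

Λ (labelled), Υ (unlabelled), model µ, threshold τ. Promotion is strict
(confidence > τ). A blocked loop falls back to a policy applied to the
top 5% of confidences, recomputed every loop: the trigger policy promotes
tokens satisfying ≥ 2 of 5 equally weighted rules — lemma in a lexicon
compiled from the trigger lemmas currently in Λ; an ancestor constituent
in {VP, NP, S}; c-commands a VP or NP; VP-commands a VP or NP; no
biomedical meaning (not a named entity, not an event, no concept type).
The four prose conditions expand to five rules by counting c-command and
VP-command separately. The argument-position policy labels
sentence-initial triggers DS, others SS. Stages with no stated policy
promote the single most confident instance — the minimal intervention
that preserves termination. A policy that selects nothing is a hard
error naming the loop. Invariants (tested): Λ∪Υ conservation, strictly
decreasing |Υ| hence ≤ |Υ₀| loops, τ-monotone promotion, and τ = 0
degenerating to one supervised pass. Seed sets take
round(fraction × positives) positives plus negatives at the requested
ratio ("natural" = the pool's own ratio), sampled without replacement
under a fixed RNG. The grid runner averages P/R/F and loop counts over
two label-stratified split-swap folds × repetitions.

## Synthetic study corpus

The generator emulates the statistics that make the task hard: trigger
rarity 1:50; 69% of triggers sentence-initial or comma-preceded; 45%
followed by a determiner or comma; half of relations cross-sentence with
the independent argument one sentence back half the time and a geometric
tail to ten; direction skew 7.54:1. Sentences come from a hand-written
template grammar (subject NP, verb, object NP, optional SBAR/CP
complements) so path and command features take non-trivial known values,
and every planted trigger constituent c-commands its dependent argument.
Ambiguity is planted on purpose: *and* is overwhelmingly a plain
conjunction and rarely causal; *suggesting/indicating* occur both as
triggers and in non-causal reduced relatives. Cross-sentence coherence is
lexical: the independent sentence shares a content noun with the
dependent clause, which is what the DS candidate ranker learns (distance,
length, noun overlap). Named entities and events are planted on noun/verb
tokens but never on triggers; dictionary providers map lemmas to
hypernyms and concept types.

Proportions are planned with largest-remainder quotas rather than
sampled independently, and rarity is balanced exactly by padding filler
sentences with extra conjuncts, so a generated corpus reproduces the
configured statistics almost exactly; the statistical tests still assert
the 95% binomial intervals. Study conditions, chosen once: 50 documents ×
25 sentences (~15k tokens, ~210 relations) for planted-recovery runs, and
100 × 300 (~5k relations) for the statistical-emulation checks;
ambiguity rate 0.15, named-entity rate 0.3, event rate 0.2, trigger-
initial SS share 0.05, causal-*and* share 0.02. A corruption operator
flips directions / shifts trigger spans for an exact count of relations,
for label-noise stress tests.

What passing on this corpus does *not* show: the grammar has none of the
length, attachment ambiguity, coordination depth or vocabulary drift of
real biomedical prose; parses are clean by construction, whereas real
pipelines consume noisy automatic parses; argument spans are clause-exact.
Scores here are planted-truth recovery rates, upper bounds on what the
same models achieve on real corpora — the published range for this task
on real data is roughly 74–95% F1 depending on the stage.

## Numerical and degenerate-input choices

Precision/recall with empty denominators are defined as 0. Overlapping
predicted triggers resolve by confidence, then leftmost-longest.
Fragmented same-type argument predictions are merged to their envelope
(arguments are contiguous by definition) and clipped against the trigger,
keeping the larger side; deterministic side-fallbacks guarantee two
disjoint spans in degenerate cases. A DS dependent argument with a
mid-sentence trigger keeps the larger contiguous side of the sentence.
One-sentence documents cannot host DS predictions and fall back to SS.
The DS candidate window is 10 sentences back, 1 forward. All stochastic
components take explicit seeds (default 13); end-to-end runs are
deterministic under a fixed seed, and the corpus generator is
byte-deterministic.

## Known limitations

Discontinuous spans, implicit (trigger-less) relations, coreference and
non-causal discourse senses are out of scope. The sequence labeller
decodes per token (no transition model), relying on BIO repair for
consistency. The Weka-style rule/tree learners are functional
equivalents, not replications. Absolute scores on licensed biomedical
corpora with automatic deep parses are not reproducible here and are not
claimed.
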