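# Methods

## The task and its contract

`cohortkit` treats cohort curation as supervised translation from a
free-text query to a *cohort filter*: a boolean tree of predicates over a
data dictionary, serialized as JSON in the GDC API dialect. Correctness is
judged by *denotation*, not text: two filters are equivalent when they
retrieve the same case set from the case index (selecting a program is the
same cohort as selecting all of its projects). All evaluation therefore
runs filters through the retrieval engine and compares case-ID sets.

## Filter dialect and canonical form

Group operators are `and` / `or` over a non-empty child list; leaf
operators are `in` (controlled-vocabulary membership), `>=` and `<=`
(numeric comparison; a closed range is a `>=`/`<=` pair). Negation,
"missing"-predicates, and cross-cohort set operations are out of scope.
The canonical form — the serialization the sampler emits, the model is
trained on, and the automaton accepts — sorts `in` value lists (dropping
duplicates), sorts sibling clauses by their serialized text, and wraps the
root in an `and` group. Sorting by serialized text rather than by a tuple
key makes sibling order something the decoder can enforce incrementally,
character by character. Integral numeric constants serialize as integers so
canonical text is stable.

Validation is two-level by design. *Structural* validation checks node
shapes only — this mirrors what a deployed JSON schema enforces. *Strict*
validation additionally closes the language over the dictionary: unknown
fields, out-of-vocabulary values, and out-of-range constants are reported
(never raised) with tree paths. The retrieval engine deliberately does not
raise on strict-invalid input either: an unknown field or misspelled value
simply matches nothing, the way a remote index responds to imprecise
machine-generated names; the evaluation layer maps *unusable* predictions
(unparseable text, truncation) to the empty case set.

## Retrieval semantics

A case matches an `in` leaf when any of its (possibly multiple) values for
the field is listed; numeric leaves likewise match existentially. Missing
properties never match and are not errors, so partially annotated cases
behave like a real index. `and` intersects, `or` unions. The engine
evaluates by set algebra per node; the test suite re-derives every result
with an independent per-case recursive oracle on randomized filter/store
draws, and checks monotonicity (adding an `and` clause never grows the
result, adding an `or` clause or an `in` value never shrinks it) and
invariance under canonicalization and sibling permutation.

## Synthetic data: what it emulates and what it does not

The sampler draws conjunctive filters the way portal users build them:
1–4 clauses (uniform by default), distinct fields per filter, 1–3 values
per `in` leaf (uniform), and with probability `p_numeric = 0.2` a numeric
range with both bounds drawn uniformly from the property's `[min, max]`.
These defaults are deliberately simple and fully exposed in
`SamplerConfig`; the method is the sampler, not its constants.

Reverse translation — producing the paired natural-language query — is a
deterministic template renderer so corpora are byte-reproducible. The
*verbose* style enumerates every value in canonical clause order ("gender
is female or male and project is TCGA-LUAD"); the *concise* style collapses
a leaf selecting all allowed values into "any ⟨label⟩" and bound pairs into
"between A and B", the register a human annotator uses. A prompt-builder
hook exposes the same interface for an instruction-tuned chat model.
Verbose phrasing follows canonical clause order on purpose: it keeps
template reverse-translation injective (distinct canonical filters yield
distinct queries, verified by enumeration) and query/target alignment
consistent.

The synthetic case store assigns each case one value per property, dropped
with `missing_rate = 0.05`, uniformly and independently. What this does
*not* emulate: correlated annotations (stage with site), multi-valued
properties, realistic marginals, or free-text noise. An optional `derive`
hook imposes semantic links (e.g. program determined by project) where a
test needs them. Consequently, passing tests show the pipeline's mechanics
and the translator's ability to ground mentioned fields, values, and
numbers — not robustness to the paraphrase diversity or annotation noise of
real user queries.

Evaluation splits keep only pairs whose filter retrieves at least one case
(metrics on an empty truth set are undefined) and whose query+filter
concatenation fits the sequence budget (default 1024 units).

## The constraint automaton

Constrained decoding uses a character-level finite-state acceptor compiled
from the dictionary. Its language is the canonical flat dialect the sampler
emits: a root `and` of leaf clauses in strictly increasing (op, field)
order, sorted deduplicated value lists, and non-negative integer numeric
literals with no leading zeros, interval-checked digit by digit (a digit is
allowed only if some in-range completion exists, and the closing brace only
when the emitted digits already lie in range). Field names and values are
trie-encoded verbatim, so a hallucinated field is rejected before its
closing quote. Sibling order is enforced by allowing a new clause only with
a key strictly above the previous one, and a list/clause separator only
when a continuation exists — this makes the automaton dead-end-free: every
reachable non-accepting state has at least one outgoing character, so
masked decoding always terminates in an accepting state (or hits the length
budget, which is reported as truncation and scored as unusable). States are
lazy hashable tuples; `allowed_next` and the per-character `try_step` are
implemented independently so the tests can cross-validate them, and bounded
exhaustive enumeration of the accepted language is exact on dictionaries
with small numeric ranges. Nested `or` filters remain fully supported by
the parser, validator, and engine; they are simply not decoding targets,
mirroring a decoder trained toward its training serialization.

## The translator backbone

The reference model is an autoregressive character-level maxent
(multinomial logistic) language model trained with a causal-LM objective on
`query + "\n" + filter` concatenations (loss on the filter+EOS region).
Its score for the next character is linear in three feature groups:

* a one-hot window over the last 16 generated characters (boilerplate and
  local syntax),
* a bag-of-words encoding of the query (vocabulary fixed at training),
* a small set of pointer/copy features shared across characters with
  learned scalar weights: continuation of the longest output suffix found
  verbatim in the query; next characters of dictionary-mentioned candidate
  clause heads and values (with "first candidate" variants, since canonical
  order makes the first mentioned candidate the right one); list/clause
  continuation indicators; and a 4×4 grid tying the j-th emitted numeric
  literal to the i-th number token in the query, which is what lets a
  linear model transcribe multi-digit bounds. Mention detection is
  word-boundary-aware and treats hyphens as token-internal, so "TCGA" is
  not counted as mentioned inside "TCGA-LUAD".

The copy features are computed from the decoding prefix by running the
automaton as a tracker; off-language prefixes (possible only in
unconstrained decoding) degrade gracefully to window+bag features. Training
is mini-batch Adam (default 14 epochs, batch 2048, learning rate 0.08, L2
1e-6) on sparse design matrices, seeded and deterministic; held-out
cross-entropy before and after training is logged into the model metadata.
Greedy decoding breaks ties by vocabulary order, so generation is exactly
reproducible; sampled decoding takes an explicit generator. This backbone
was chosen over a small transformer because it trains in about a minute on
one CPU, is bit-reproducible, and exposes the same next-token-scores
contract, so subword neural backbones can be plugged in behind `generate`
without touching the automaton.

## Evaluation and statistics

Per sample: TPR = |P∩A|/|A|, IoU = |P∩A|/|P∪A|, Exact = [P = A], with the
empty-prediction convention (0, 0, false); the truth set is never empty by
construction. Semantic similarity compares the query with the reverse
translation of the predicted filter; the default scorer is a deterministic
multiset F1 over lowercased, punctuation-stripped content tokens (a small
function-word stoplist), so word order and phrasing do not matter; an
embedding-based F1 (BERTScore-style) scorer plugs into the same
`scorer(a, b)` contract and reports are labeled with the scorer used.

System comparisons are paired: two-sided paired t-tests for TPR, IoU, and
semantic scores, McNemar's test on the Exact discordance table — exact
binomial when the discordant count is below 25 (configurable constant),
continuity-corrected chi-square otherwise — and Bonferroni correction with
the family equal to the comparisons performed in the call, recorded in the
output. Zero-variance differences (routine with oracle predictors) report
p = 1 with a degeneracy flag rather than raising.

## Problem sizes and numerical choices

The bundled toy dictionary has 6 properties (15 enumerated values plus an
age-at-diagnosis range of 0–32872 days). The end-to-end experiment defaults
to 2000 synthetic verbose training pairs, 200 held-out evaluation pairs,
and a 500-case store — sizes chosen so a full run (corpus, training,
constrained and unconstrained decoding, evaluation, significance testing)
completes in about 90 seconds on one CPU. Exhaustive automaton-language
checks use a 3-property dictionary with a 0–12 numeric range so bounded
enumeration is genuinely exhaustive (366 strings at ≤2 clauses). Master
seeds fan out into per-stage streams (sampler, store, training, decoding)
recorded in the run manifest; identical config and seeds reproduce corpora
byte-for-byte and evaluation summaries exactly.

## Known limitations

* Constrained greedy decoding can only differ from unconstrained greedy
  decoding at steps where the unconstrained argmax leaves the filter
  language. A backbone this well matched to template queries rarely leaves
  the language on in-distribution input, so the two modes often coincide
  there; the constraint's value shows on out-of-distribution registers
  (e.g. concise queries for a verbose-trained model), where unconstrained
  decoding can derail into unusable text while constrained decoding always
  returns a strict-valid filter.
* Template queries understate linguistic variety; results on them bound
  mechanics, not real-user performance.
* The decoding language is the flat conjunctive dialect; nested `or`
  targets would need an extended automaton.
* Numeric literals in the decoding language are non-negative integers;
  dictionaries with negative or non-integer bounds validate and retrieve
  fine but cannot be decoding targets as-is.
* The exact membership of a production portal's default ("core") property
  set is deployment-specific; the bundled dictionary is illustrative, and
  any dictionary in the documented JSON format can be supplied.
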