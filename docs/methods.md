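# Methods

## Task model

The unit of analysis is a *relation instance*: a document plus one
directed, typed entity pair (head → tail). All three supported relation
types are directed the same way — chemical → disease, gene → disease,
drug → adverse event — so no reverse pairs are enumerated. The decision
is binary: the relation holds or it does not. Two candidate-enumeration
modes exist: `all_pairs` (every head-type × tail-type combination,
positive iff a gold positive label exists — the convention for
document-level corpora with typed entity annotations) and
`annotated_only` (only pairs explicitly annotated — the convention for
pair-list corpora). For pair-list corpora the construction of negatives
is not standardized, so `annotated_only` optionally adds seeded
negative sampling at a configurable ratio; it is off by default and
nothing in the package asserts a particular ratio is "correct".

Spans are 0-based half-open in the canonical JSON dialect; the
DocRED-style converter translates token positions to character offsets
against space-joined sentences. The canonical surface form of an entity
(used to fill question slots) is its first mention's surface — a
deterministic choice; normalized-term rendering is possible by editing
the term mapping.

## Knowledge selection

Entity → term resolution prefers the controlled-vocabulary (MeSH) term
and falls back to the official symbol; an entity with neither is an
error rather than a silent skip. Article selection:

* co-occurrence hits present → all of them, capped at the **top 10** by
  relevance rank;
* none → the **top 5** per entity, merged head-entity-first with
  duplicate pmids dropped at first occurrence.

The merge order is fixed for determinism. Offline, "relevance" is an
explicit rank supplied with the store (or, absent an index entry, a
substring scan ordered by ascending pmid — deterministic and adequate
for fixtures); the live adapter requests the service's relevance sort
and records it. Whether co-occurrence should use MeSH field tags or
free-text title/abstract search is a service-level question the adapter
exposes as `field_tag` rather than hard-coding.

## Chunking

Three segmentation strategies, applied per abstract paragraph:
paragraph (I-as-a-whole), sentence, and sliding window. The window
groups k consecutive sentences and advances d at a time; defaults
k = 3, d = 2, giving a one-sentence overlap between adjacent windows.
The generic stride-d definition is implemented (overlap = k − d for any
valid 1 ≤ d ≤ k); d = 1 yields the dense enumeration c₁ = [s₁s₂s₃],
c₂ = [s₂s₃s₄], …, c_{N−2}, so both the stated parameters and the dense
variant are reachable from config. When the stride does not tile the
paragraph, one extra end-anchored window of the last k sentences is
appended so the final sentence is always covered; its overlap with the
preceding window is ≥ k − d and it is exempt from the exact-overlap
law. For N ≤ k the whole paragraph is a single window.

Sentence splitting is a deterministic rule set: a boundary is
sentence-final punctuation followed by whitespace unless the preceding
word is on a fixed abbreviation list (dosing abbreviations like "i.v.",
scholarly ones like "et al.", "Fig."). The list is intentionally small
and editable; recall on exotic abbreviations is a known limitation. The
splitter is substring-preserving, so the space-join of sentences equals
the whitespace-normalized paragraph.

Chunk identifiers are (pmid, strategy tag ∈ {P, S, W}, index); merging
strategies deduplicates whitespace-normalized texts keeping the
smallest identifier (P sorts before S before W), then sorts by
identifier. Dedup compares exact case-preserving text: punctuation and
case can be semantically meaningful in biomedical text, so only
whitespace is normalized.

## Retrieval

The retrieval query is the question text alone, not the query document:
the question already names both entities, and embedding the full
document would dilute the pair-specific signal. Similarity is computed
jointly over the chunks of all selected abstracts for the instance (one
store per instance). Ties break toward the smaller chunk id. `count=0`
is the no-knowledge ablation; `mode="bottom"` the low-similarity one.

The default offline encoder hashes lowercased word tokens (BLAKE2b) to
one of 256 signed buckets, accumulates counts, and L2-normalizes.
Properties that matter for the tests: determinism across processes,
unit norm, distinct profiles for distinct token multisets, and higher
cosine for texts sharing vocabulary. It is *not* a semantic model:
synonymy and paraphrase are invisible to it, which is precisely why the
fixture generator plants facts that share surface vocabulary with the
question. Conclusions about real-corpus retrieval quality require a
trained sentence encoder plugged in behind the same contract.
Embeddings are memoized in-process keyed by (backend name, normalized
text); a persistent on-disk cache was deliberately not built — all
supported offline encoders are cheap, and live-encoder users can
persist vectors at the application level.

## Prompting and parsing

Prompt section order is fixed: question, document, external knowledge
(numbered `[i]` blocks), reasoning steps (numbered from 1), the
zero-shot cue sentence (that kind only), output directive. Rendering is
a pure function of the prompt value, so prompt SHA-256 hashes in audit
logs identify content exactly.

Three kinds: `standard` (no knowledge, no steps), `zero_shot_cot`
(generic cue only), `augmented` (retrieved chunks and/or task-specific
steps). The augmented kind requires *at least one* of the two
enhancements rather than both, so the single-component configurations —
retrieval without reasoning steps ("w/o CoT") and reasoning steps
without retrieval ("w/o RAG") — are expressible as first-class prompts.

The answer protocol requires completions to end with
`My answer is: Yes|No`. Parsing takes the **last** case-insensitive
occurrence of the prefix (reasoning may quote the directive), then the
first alphabetic token after it; anything else is `unparseable`.
Unparseable outputs are mapped to the configured default label
(negative) *and* tallied separately, so recall is never silently
inflated; excluding them from the contingency is a config option.
Task-specific CoT wordings ship as editable numbered-step text assets
per dataset; only the chemical–disease wording has an external
reference point, the other two are this package's own phrasings.

## Evaluation

P, R, F1 with the zero-denominator convention P = R = 0 (F1 = 0 when
P + R = 0), computed from integer contingency counts. Aggregation over
n runs reports per-metric mean and sample (n−1) standard deviation,
std = 0 for n = 1; the default n_runs is 3. Grids share their base seed
across configurations so rows differ only in the ablated factor.

## The fixture generator

Defaults (the standard study conditions for all end-to-end tests): 20
documents, 1 chemical × 3 diseases each → 60 instances, positive
prevalence 0.5, 1 distractor record per entity. Each positive pair gets
one planted two-paragraph record whose findings paragraph opens with a
single-sentence statement of the relation ("X induces Y in treated
patients."); each entity gets a distractor record mentioning it alone.
Consequently co-occurrence search succeeds exactly for positive pairs
and negatives exercise the per-entity fallback merge. Entity names are
globally unique fixed-width tokens (`chem0000`, `dis0000`), which makes
questions unique (the mock backends key on them) and avoids substring
collisions in the scan index. Generation is a pure function of
(config, seed); suites serialize to corpus JSON + knowledge JSONL +
oracle TSV + manifest, byte-identically for equal seeds.

What the fixtures do **not** emulate: coreference and synonymy between
mention and knowledge text, multi-sentence evidence, noisy retrieval
rankings, label noise, long documents. Passing end-to-end tests
therefore demonstrates the pipeline's plumbing, determinism, and the
*direction* of the component ablations — not real-corpus effect sizes.

The knowledge-gated mock implements a three-clause decision rule:
without reasoning guidance in the prompt it answers yes to everything
(the over-predicting profile unguided zero-shot models tend to show:
high recall, low precision); with guidance it confirms a positive only
if the planted fact text appears in the prompt, and denies negatives.
This makes both component ablations strict on fixtures by construction;
it is a test instrument, not a model of LLM behavior.

## Numerical and engineering choices

* Cosine similarity is clipped to [−1, 1] against floating-point drift;
  zero vectors are an error, not a silent zero.
* Chunk indices render zero-padded to four digits so string and tuple
  orderings agree.
* The live literature adapter retries 3 times with exponential backoff
  and caches every fetched record into the offline-store format; the
  live generator pathway is a record/replay cassette (JSON keyed by
  prompt SHA-256) — recorded once, replayed deterministically forever.
* Default sampling temperature is 0; per-run seeds are base_seed + i.

## Known limitations

* The shipped encoder's bag-of-words geometry makes "semantic"
  similarity lexical overlap; see above.
* The sentence splitter's abbreviation list is finite; unknown
  abbreviations split early (chunks remain well-formed, windows absorb
  most damage).
* The pair-list reader synthesizes a minimal passage when no text
  column exists, so mention spans are placeholders in that case.
* Scores on the synthetic suites say nothing quantitative about
  benchmark corpora with hosted LLMs; the harness exists so that such
  runs, when made, are auditable and replayable.
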