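# litrex

Zero-shot **document-level biomedical relation extraction** with
retrieval-augmented generation (RAG) and chain-of-thought (CoT)
prompting — built so the whole pipeline runs and tests **offline**
behind pluggable encoder, generator, and literature backends.

## Who this is for

Biomedical text-mining researchers who want to evaluate
large-language-model relation extraction (chemical–disease,
gene–disease, drug–adverse-event) as a question-answering task, with
controlled external knowledge injection — without committing to one
hosted model, one embedding service, or live PubMed access during
development and CI.

## The method

For each typed entity pair (e₁, e₂) in a query document:

1. **Question reframing.** The binary relation decision becomes a
   question Q from the dataset's template, e.g.
   *"Does chemical e₁ induce disease e₂?"*.
2. **Knowledge selection.** Both entities resolve to controlled terms
   (MeSH term if mapped, official symbol otherwise). Articles where both
   terms co-occur in title or abstract are selected by relevance rank —
   at most the top **10**; if none co-occur, the top **5** per entity
   are merged (duplicates dropped, first occurrence kept).
3. **Chunking.** Each abstract is segmented three ways — per paragraph,
   per sentence, and by a sliding window of **k = 3** sentences with
   stride **d = 2** (adjacent windows share k − d = 1 sentence; a final
   end-anchored window guarantees the last sentence is covered). The
   merged store is deduplicated and ordered by composite chunk id
   `PMID:STRATEGY:INDEX`.
4. **Retrieval.** Q and every chunk are embedded by a sentence encoder;
   cosine similarity cos(q, c) = q·c / (‖q‖‖c‖) selects the top (or,
   for the low-similarity ablation, bottom) chunk(s).
5. **Prompting + generation.** A standard prompt (question + document),
   a zero-shot-CoT prompt (+ *"Let's think step by step."*), or an
   augmented prompt (+ retrieved chunk + task-specific numbered
   reasoning steps) is sent to the generator, which must end with
   `My answer is: Yes/No`.
6. **Evaluation.** Parsed answers are scored as a binary contingency:
   P = tp/(tp+fp), R = tp/(tp+fn), F1 = 2PR/(P+R) (zero-denominator
   convention: 0), aggregated as mean ± sample std over repeated runs.

Everything model-shaped is a contract: `Encoder` (production:
sentence-transformer; shipped: deterministic hashed bag-of-words),
`LlmBackend` (live chat API, record/replay cassettes, or the
deterministic mocks), `KnowledgeBackend` (E-utilities adapter or a local
offline store with explicit relevance ranks).

## Worked example

```bash
litrex fixtures /tmp/demo-suite --seed 7
# wrote suite to /tmp/demo-suite: 20 documents, 60 instances, 114 knowledge records

litrex ablate /tmp/demo-suite --backend gated --n-runs 3
# config    metric     mean  std  n
#   full precision 1.000000  0.0  3
#   full    recall 1.000000  0.0  3
#   full        f1 1.000000  0.0  3
# wo_rag precision 0.000000  0.0  3
# wo_rag    recall 0.000000  0.0  3
# wo_rag        f1 0.000000  0.0  3
# wo_cot precision 0.566667  0.0  3
# wo_cot    recall 1.000000  0.0  3
# wo_cot        f1 0.723404  0.0  3
```

The fixture suite plants, for every positive pair, one knowledge record
whose findings paragraph states the relation in a single sentence;
negative pairs have only single-entity distractor records. The `gated`
mock backend answers from evidence only when the prompt carries both the
retrieved fact and reasoning guidance, so the ablation separates the two
components: the full configuration is perfect; removing retrieval
(`wo_rag`) leaves positives unconfirmable (recall 0); removing the
reasoning steps (`wo_cot`) makes the mock over-predict (recall 1,
precision = the suite's positive prevalence 0.567, F1 0.723). With the
`oracle` backend (answers always correct) any configuration scores
F1 = 1.000 ± 0.000 over 3 runs — the harness's upper-bound sanity check.

The same pipeline runs against real corpora via `read_dataset`
(canonical JSON, DocRED-style JSON, TSV pair lists), a live PubMed
backend (`litrex.pubmed`, requires biopython + network), a
sentence-transformer plugged in behind `Encoder`, and a chat LLM behind
`LlmBackend`.

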