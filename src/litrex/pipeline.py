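"""End-to-end orchestration: question -> retrieval -> prompt -> answer -> score.

:func:`run_pipeline` executes one configuration over a corpus;
:func:`run_ablation_grid` runs several configurations with shared seeds
so rows differ only in the ablated factor (retrieval on/off, reasoning
steps on/off, chunking strategy, retrieved-chunk count/polarity).
Every instance leaves an audit record (question, selected article ids,
chosen chunk ids, prompt hash, raw completions, parsed labels) so runs
can be diffed byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import pandas as pd

from .backends import LlmBackend, SamplingConfig, generate_answer
from .chunking import DEFAULT_WINDOW_SIZE, DEFAULT_WINDOW_STRIDE, build_chunk_store
from .evaluation import METRIC_NAMES, MetricsReport, RunAggregate, aggregate_runs, score_predictions
from .io import corpus_instances
from .knowledge import (
    FALLBACK_TOP_K,
    PMID_CAP,
    KnowledgeBackend,
    TermMapping,
    fetch_records,
    resolve_entity_term,
    select_pmids,
)
from .prompting import PromptKind, build_prompt, build_question
from .retrieval import Encoder, EncoderCache, select_relevant_chunks
from .templates import CotTemplate, load_cot_template
from .types import BinaryLabel, Document, Prediction, RelationSchema

logger = logging.getLogger(__name__)

# Roman labels for the chunking-strategy ablation
CHUNKING_STRATEGY_SETS: dict[str, tuple[str, ...]] = {
    "I": ("sentence",),
    "II": ("window",),
    "III": ("paragraph",),
    "IV": ("sentence", "window", "paragraph"),
}


@dataclass(frozen=True)
class AblationConfig:
    """One pipeline configuration.

    ``chunk_strategy`` is a Roman label (I sentence, II window,
    III paragraph, IV hybrid).  ``prompt_kind`` is derived from the two
    enable flags unless given explicitly (zero-shot-CoT runs set it).
    """

    label: str = "full"
    rag_enabled: bool = True
    cot_enabled: bool = True
    prompt_kind: Optional[PromptKind] = None
    chunk_strategy: str = "IV"
    chunk_mode: Literal["top", "bottom"] = "top"
    chunk_count: int = 1
    window_k: int = DEFAULT_WINDOW_SIZE
    window_d: int = DEFAULT_WINDOW_STRIDE
    pmid_cap: int = PMID_CAP
    fallback_k: int = FALLBACK_TOP_K
    n_runs: int = 3
    base_seed: int = 0
    default_label: BinaryLabel = "negative"
    exclude_unparseable: bool = False

    def __post_init__(self) -> None:
        if self.chunk_strategy not in CHUNKING_STRATEGY_SETS:
            raise ValueError(f"chunk_strategy must be one of {sorted(CHUNKING_STRATEGY_SETS)}")
        if not self.rag_enabled and self.chunk_count != 0:
            raise ValueError("rag_enabled=False requires chunk_count=0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.chunk_count < 0:
            raise ValueError("chunk_count must be >= 0")

    @property
    def effective_kind(self) -> PromptKind:
        if self.prompt_kind is not None:
            return self.prompt_kind
        if self.rag_enabled or self.cot_enabled:
            return "augmented"
        return "standard"

    def run_seeds(self) -> list[int]:
        return [self.base_seed + i for i in range(self.n_runs)]


@dataclass
class PipelineBackends:
    """Everything pluggable: generator, encoder, literature store, terms."""

    llm: LlmBackend
    encoder: Encoder
    knowledge: Optional[KnowledgeBackend] = None
    term_mapping: Optional[TermMapping] = None


@dataclass
class PipelineResult:
    aggregate: RunAggregate
    audit: list[dict]

    def write_audit(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for rec in self.audit:
                fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=True) + "\n")


def _retrieve_for_question(
    question_text: str,
    head,
    tail,
    config: AblationConfig,
    backends: PipelineBackends,
    encoder: Encoder,
) -> tuple[list[str], list[str], list[str]]:
    """Knowledge stage for one instance: terms -> pmids -> chunks.

    Returns (chunk texts, selected pmids, chosen chunk ids).
    """
    if backends.knowledge is None or backends.term_mapping is None:
        raise ValueError("retrieval is enabled but no knowledge backend/term mapping given")
    term1 = resolve_entity_term(head, backends.term_mapping, symbol=head.canonical_surface)
    term2 = resolve_entity_term(tail, backends.term_mapping, symbol=tail.canonical_surface)
    pmids = select_pmids(
        backends.knowledge.cooccurrence_query(term1, term2),
        backends.knowledge.single_term_query(term1),
        backends.knowledge.single_term_query(term2),
        cap=config.pmid_cap,
        fallback_k=config.fallback_k,
    )
    records = fetch_records(pmids, backends.knowledge)
    if not records:
        logger.info("no knowledge records for pair (%s, %s)", term1, term2)
        return [], pmids, []
    store = build_chunk_store(
        records,
        strategies=CHUNKING_STRATEGY_SETS[config.chunk_strategy],
        k=config.window_k,
        d=config.window_d,
    )
    results = select_relevant_chunks(
        question_text, store, encoder, mode=config.chunk_mode, count=config.chunk_count
    )
    return (
        [r.chunk.text for r in results],
        pmids,
        [str(r.chunk.chunk_id) for r in results],
    )


def run_pipeline(
    corpus: Sequence[Document],
    schema: RelationSchema,
    config: AblationConfig,
    backends: PipelineBackends,
    cot_template: Optional[CotTemplate] = None,
) -> PipelineResult:
    """Run one configuration over every candidate pair of the corpus."""
    if config.cot_enabled and cot_template is None:
        if schema.cot_template_ref is None:
            raise ValueError("cot_enabled but schema declares no cot_template_ref")
        cot_template = load_cot_template(schema.cot_template_ref)

    encoder = EncoderCache(backends.encoder)
    instances = corpus_instances(corpus, schema)
    seeds = config.run_seeds()

    audit: list[dict] = []
    per_run_predictions: list[list[Prediction]] = [[] for _ in seeds]

    for inst in instances:
        question = build_question(inst, schema)
        retrieved: list[str] = []
        pmids: list[str] = []
        chunk_ids: list[str] = []
        if config.rag_enabled and config.chunk_count > 0:
            retrieved, pmids, chunk_ids = _retrieve_for_question(
                question.text, inst.head, inst.tail, config, backends, encoder
            )
        kind = config.effective_kind
        prompt = build_prompt(
            question,
            next(d for d in corpus if d.doc_id == inst.doc_id),
            retrieved=retrieved if kind == "augmented" else (),
            cot=cot_template if (config.cot_enabled and kind == "augmented") else None,
            kind=kind,
        )
        prompt_text = prompt.render()
        runs = []
        for run_idx, seed in enumerate(seeds):
            output = generate_answer(prompt, backends.llm, SamplingConfig(seed=seed))
            predicted: BinaryLabel = (
                "positive" if output.parsed == "yes"
                else "negative" if output.parsed == "no"
                else config.default_label
            )
            per_run_predictions[run_idx].append(
                Prediction(
                    instance=inst,
                    predicted=predicted,
                    parse_status="parsed" if output.parsed != "unparseable" else "unparseable",
                    raw_output_ref=output.raw,
                )
            )
            runs.append({"seed": seed, "raw": output.raw, "parsed": output.parsed})
        audit.append(
            {
                "doc_id": inst.doc_id,
                "head": inst.head.entity_id,
                "tail": inst.tail.entity_id,
                "gold": inst.gold,
                "question": question.text,
                "pmids": pmids,
                "chunk_ids": chunk_ids,
                "prompt_sha256": hashlib.sha256(prompt_text.encode("utf-8")).hexdigest(),
                "runs": runs,
            }
        )

    reports = [
        score_predictions(
            preds, instances, run_id=f"{config.label}/run{i}",
            exclude_unparseable=config.exclude_unparseable,
        )
        for i, preds in enumerate(per_run_predictions)
    ]
    return PipelineResult(aggregate=aggregate_runs(reports), audit=audit)


def run_ablation_grid(
    corpus: Sequence[Document],
    schema: RelationSchema,
    configs: Sequence[AblationConfig],
    backends: PipelineBackends,
) -> tuple[pd.DataFrame, dict[str, PipelineResult]]:
    """One row per (config, metric); configs share their declared seeds."""
    if not configs:
        raise ValueError("no configurations to run")
    rows = []
    results: dict[str, PipelineResult] = {}
    for config in configs:
        result = run_pipeline(corpus, schema, config, backends)
        results[config.label] = result
        for m in METRIC_NAMES:
            rows.append(
                {
                    "config": config.label,
                    "metric": m,
                    "mean": result.aggregate.mean[m],
                    "std": result.aggregate.std[m],
                    "n": result.aggregate.n,
                }
            )
    return pd.DataFrame(rows), results


def write_results_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")
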