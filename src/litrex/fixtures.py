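"""Synthetic fixture suites: a miniature corpus plus literature store.

A suite emulates the study conditions end to end without any download:
documents with typed entity mentions and binary gold labels, and a
knowledge store in which every positive pair has a planted record whose
findings paragraph states the relation in one sentence ("X induces Y in
treated patients."), while negative pairs are covered only by
single-entity distractor records.  Co-occurrence search therefore
succeeds exactly for positive pairs, and the fallback merge path is
exercised by the negatives.

Generation is a pure function of (config, seed): equal seeds give
byte-identical serializations.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .io import document_from_dict, document_to_dict, enumerate_candidate_pairs
from .knowledge import KnowledgeRecord, OfflineStore, TermMapping
from .templates import default_schema
from .types import Document, Entity, EntityMention, RelationInstance, RelationSchema


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for a synthetic suite.

    Defaults give 20 documents with one chemical and three diseases each
    (60 candidate pairs) at 0.5 positive prevalence.
    """

    n_docs: int = 20
    heads_per_doc: int = 1
    tails_per_doc: int = 3
    prevalence: float = 0.5
    distractors_per_entity: int = 1

    def __post_init__(self) -> None:
        if self.n_docs < 1 or self.heads_per_doc < 1 or self.tails_per_doc < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must lie in (0, 1), got {self.prevalence}")


def _mention(passage: str, surface: str, passage_index: int) -> EntityMention:
    start = passage.index(surface)
    return EntityMention(surface=surface, start=start, end=start + len(surface), passage_index=passage_index)


@dataclass
class FixtureSuite:
    """Documents + knowledge store + oracle for offline pipeline runs."""

    documents: list[Document]
    knowledge_store: OfflineStore
    oracle: dict[tuple[str, str, str], bool]  # (doc_id, head_id, tail_id) -> gold
    facts: dict[tuple[str, str, str], Optional[str]]  # planted evidence sentence per positive
    term_mapping: TermMapping
    schema: RelationSchema
    seed: int

    def instances(self) -> list[RelationInstance]:
        out: list[RelationInstance] = []
        for doc in self.documents:
            out.extend(enumerate_candidate_pairs(doc, self.schema, mode="all_pairs"))
        return out

    def answers_by_question(self) -> dict[str, bool]:
        """Gold answers keyed by rendered question text (for mock backends)."""
        out = {}
        for inst in self.instances():
            q = self.schema.question_template.format(
                head=inst.head.canonical_surface, tail=inst.tail.canonical_surface
            )
            out[q] = self.oracle[inst.key]
        return out

    def facts_by_question(self) -> dict[str, Optional[str]]:
        out = {}
        for inst in self.instances():
            q = self.schema.question_template.format(
                head=inst.head.canonical_surface, tail=inst.tail.canonical_surface
            )
            out[q] = self.facts[inst.key]
        return out

    # --- serialization: corpus JSON + store JSONL + oracle TSV + manifest ---

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        corpus = {"documents": [document_to_dict(d) for d in self.documents]}
        (directory / "corpus.json").write_text(
            json.dumps(corpus, indent=1, ensure_ascii=False, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        self.knowledge_store.save(directory / "knowledge.jsonl")
        oracle_lines = [
            f"{doc_id}\t{head}\t{tail}\t{'yes' if ans else 'no'}\t{self.facts[(doc_id, head, tail)] or ''}"
            for (doc_id, head, tail), ans in sorted(self.oracle.items())
        ]
        (directory / "oracle.tsv").write_text("\n".join(oracle_lines) + "\n", encoding="utf-8")
        self.term_mapping.to_tsv(directory / "terms.tsv")
        (directory / "manifest.json").write_text(
            json.dumps({"seed": self.seed, "dataset": self.schema.dataset_name}, sort_keys=True) + "\n",
            encoding="utf-8",
        )

    @classmethod
    def load(cls, directory: str | Path) -> "FixtureSuite":
        directory = Path(directory)
        corpus = json.loads((directory / "corpus.json").read_text(encoding="utf-8"))
        documents = [document_from_dict(rec, i) for i, rec in enumerate(corpus["documents"])]
        store = OfflineStore.load(directory / "knowledge.jsonl")
        oracle: dict[tuple[str, str, str], bool] = {}
        facts: dict[tuple[str, str, str], Optional[str]] = {}
        for line in (directory / "oracle.tsv").read_text(encoding="utf-8").splitlines():
            doc_id, head, tail, ans, fact = line.split("\t")
            oracle[(doc_id, head, tail)] = ans == "yes"
            facts[(doc_id, head, tail)] = fact or None
        manifest = json.loads((directory / "manifest.json").read_text(encoding="utf-8"))
        return cls(
            documents=documents,
            knowledge_store=store,
            oracle=oracle,
            facts=facts,
            term_mapping=TermMapping.from_tsv(directory / "terms.tsv"),
            schema=default_schema(manifest["dataset"]),
            seed=manifest["seed"],
        )


def generate_fixture_suite(config: FixtureConfig = FixtureConfig(), seed: int = 0) -> FixtureSuite:
    """Generate a deterministic suite under the given seed."""
    rng = random.Random(seed)
    schema = default_schema("cdr")

    documents: list[Document] = []
    records: list[KnowledgeRecord] = []
    oracle: dict[tuple[str, str, str], bool] = {}
    facts: dict[tuple[str, str, str], Optional[str]] = {}
    mapping: dict[str, str] = {}

    chem_counter = 0
    dis_counter = 0
    planted_counter = 0

    all_terms: list[str] = []

    for doc_idx in range(config.n_docs):
        doc_id = f"doc{doc_idx:03d}"
        chems = [f"chem{chem_counter + i:04d}" for i in range(config.heads_per_doc)]
        chem_counter += config.heads_per_doc
        diseases = [f"dis{dis_counter + i:04d}" for i in range(config.tails_per_doc)]
        dis_counter += config.tails_per_doc
        all_terms.extend(chems)
        all_terms.extend(diseases)

        passages: list[str] = []
        entities: list[Entity] = []
        for chem in chems:
            passage = f"Patients in this cohort received {chem} at the standard dosage."
            passages.append(passage)
            entities.append(
                Entity(chem, schema.head_type, (_mention(passage, chem, len(passages) - 1),))
            )
            mapping[chem] = chem
        for dis in diseases:
            passage = f"Several subjects developed {dis} during the follow-up period."
            passages.append(passage)
            entities.append(
                Entity(dis, schema.tail_type, (_mention(passage, dis, len(passages) - 1),))
            )
            mapping[dis] = dis

        gold: set[tuple[str, str, str]] = set()
        for chem in chems:
            for dis in diseases:
                key = (doc_id, chem, dis)
                positive = rng.random() < config.prevalence
                oracle[key] = positive
                if positive:
                    gold.add((chem, dis, schema.positive_label))
                    fact = f"{chem} induces {dis} in treated patients."
                    facts[key] = fact
                    pmid = f"8{planted_counter:07d}"
                    planted_counter += 1
                    records.append(
                        KnowledgeRecord(
                            pmid=pmid,
                            title=f"Association of {chem} with {dis}: a cohort study.",
                            paragraphs=(
                                f"The safety profile of {chem} was assessed in a multicenter cohort. "
                                "Adverse outcomes were recorded systematically. "
                                "Baseline characteristics were balanced across groups.",
                                f"{fact} Dose dependence was observed across exposure strata. "
                                "Symptoms resolved after discontinuation of therapy. "
                                "These findings were consistent across sensitivity analyses.",
                            ),
                        )
                    )
                else:
                    gold.add((chem, dis, schema.negative_label))
                    facts[key] = None

        documents.append(
            Document(
                doc_id=doc_id,
                title=f"Observational report {doc_idx:03d}.",
                passages=tuple(passages),
                entities=tuple(entities),
                gold_labels=frozenset(gold),
            )
        )

    distractor_counter = 0
    for term in all_terms:
        for _ in range(config.distractors_per_entity):
            pmid = f"9{distractor_counter:07d}"
            distractor_counter += 1
            records.append(
                KnowledgeRecord(
                    pmid=pmid,
                    title=f"Review of {term}.",
                    paragraphs=(
                        f"{term} remains an active area of investigation. "
                        "Prior reports describe heterogeneous findings. "
                        "Further controlled studies are warranted.",
                    ),
                )
            )

    return FixtureSuite(
        documents=documents,
        knowledge_store=OfflineStore(records),
        oracle=oracle,
        facts=facts,
        term_mapping=TermMapping(mapping),
        schema=schema,
        seed=seed,
    )
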