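"""Corpus readers/writers and candidate-pair enumeration.

The canonical dialect is a documented JSON layout owned by this package
(one object per document: doc_id/title/passages/entities/gold_labels,
spans 0-based half-open, UTF-8).  Converters bridge the two common public
distributions: DocRED-style JSON (tokenized sentences plus vertexSet
entity clusters and h/t/r label triples) and a flat TSV pair list for
corpora that annotate relations directly on short texts.
"""

from __future__ import annotations

import csv
import json
import random
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .types import (
    BinaryLabel,
    Document,
    Entity,
    EntityMention,
    RelationInstance,
    RelationSchema,
)

Dialect = Literal["canonical", "docred_json", "pair_list"]


# ---------------------------------------------------------------------------
# canonical dialect

def document_to_dict(doc: Document) -> dict:
    return {
        "doc_id": doc.doc_id,
        "title": doc.title,
        "passages": list(doc.passages),
        "entities": [
            {
                "entity_id": e.entity_id,
                "type": e.type,
                "mentions": [
                    {
                        "surface": m.surface,
                        "start": m.start,
                        "end": m.end,
                        "passage_index": m.passage_index,
                    }
                    for m in e.mentions
                ],
            }
            for e in doc.entities
        ],
        "gold_labels": sorted(list(t) for t in doc.gold_labels),
    }


def document_from_dict(rec: dict, index: int = 0) -> Document:
    try:
        entities = tuple(
            Entity(
                entity_id=e["entity_id"],
                type=e["type"],
                mentions=tuple(
                    EntityMention(
                        surface=m["surface"],
                        start=int(m["start"]),
                        end=int(m["end"]),
                        passage_index=int(m["passage_index"]),
                    )
                    for m in e["mentions"]
                ),
            )
            for e in rec["entities"]
        )
        return Document(
            doc_id=rec["doc_id"],
            title=rec.get("title", ""),
            passages=tuple(rec["passages"]),
            entities=entities,
            gold_labels=frozenset((h, t, r) for h, t, r in rec["gold_labels"]),
        )
    except KeyError as exc:
        raise ValueError(f"record {index}: missing field {exc.args[0]!r}") from exc


def write_dataset(documents: Sequence[Document], path: str | Path) -> None:
    payload = {"documents": [document_to_dict(d) for d in documents]}
    Path(path).write_text(
        json.dumps(payload, indent=1, ensure_ascii=False, sort_keys=True) + "\n",
        encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# converters

def _docred_document(rec: dict, index: int, schema: RelationSchema) -> Document:
    """Convert one DocRED-style record (sents as token lists, vertexSet
    entity clusters, h/t/r labels) into the canonical model.

    Each sentence becomes a passage whose text is the space-join of its
    tokens; token positions translate to character spans accordingly.
    """
    try:
        sents: list[list[str]] = rec["sents"]
        vertex_set: list[list[dict]] = rec["vertexSet"]
    except KeyError as exc:
        raise ValueError(f"record {index}: missing field {exc.args[0]!r}") from exc

    passages = tuple(" ".join(tokens) for tokens in sents)
    # char offset of each token within its space-joined sentence
    offsets: list[list[int]] = []
    for tokens in sents:
        pos, off = 0, []
        for tok in tokens:
            off.append(pos)
            pos += len(tok) + 1
        offsets.append(off)

    entities = []
    for ei, cluster in enumerate(vertex_set):
        if not cluster:
            raise ValueError(f"record {index}: vertexSet[{ei}] is empty")
        mentions = []
        for m in cluster:
            sent_id = int(m["sent_id"])
            tok_start, tok_end = int(m["pos"][0]), int(m["pos"][1])
            start = offsets[sent_id][tok_start]
            end = offsets[sent_id][tok_end - 1] + len(sents[sent_id][tok_end - 1])
            mentions.append(
                EntityMention(
                    surface=m.get("name", passages[sent_id][start:end]),
                    start=start,
                    end=end,
                    passage_index=sent_id,
                )
            )
        entities.append(
            Entity(
                entity_id=cluster[0].get("id", f"E{ei}"),
                type=cluster[0].get("type", ""),
                mentions=tuple(mentions),
            )
        )

    gold = set()
    for lab in rec.get("labels", []):
        code = lab["r"]
        if code not in schema.label_codes:
            raise ValueError(f"record {index}: unknown label code {code!r}")
        gold.add((entities[int(lab["h"])].entity_id, entities[int(lab["t"])].entity_id, code))

    return Document(
        doc_id=rec.get("title", f"doc{index}"),
        title=rec.get("title", ""),
        passages=passages,
        entities=tuple(entities),
        gold_labels=frozenset(gold),
    )


def _pair_list_documents(path: Path, schema: RelationSchema) -> list[Document]:
    """Read a TSV pair list: doc_id, head, tail, label[, text].

    Rows sharing a doc_id are grouped into one document.  When no text
    column is present, a minimal passage naming both entities is
    synthesized per pair so mention spans stay well-defined.
    """
    groups: dict[str, list[tuple[str, str, str, str]]] = {}
    with path.open(encoding="utf-8", newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t")):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 4:
                raise ValueError(f"record {i}: pair_list row needs >= 4 columns, got {len(row)}")
            doc_id, head, tail, label = row[0], row[1], row[2], row[3]
            if label not in schema.label_codes:
                raise ValueError(f"record {i}: unknown label code {label!r}")
            text = row[4] if len(row) > 4 else ""
            groups.setdefault(doc_id, []).append((head, tail, label, text))

    docs = []
    for doc_id, rows in groups.items():
        passages: list[str] = []
        entities: dict[str, Entity] = {}
        gold = set()
        for head, tail, label, text in rows:
            passage = text if text else f"{head} and {tail}."
            if passage in passages:
                pidx = passages.index(passage)
            else:
                passages.append(passage)
                pidx = len(passages) - 1
            for surface, etype in ((head, schema.head_type), (tail, schema.tail_type)):
                if surface in entities:
                    continue
                start = passage.find(surface)
                if start < 0:  # surface absent from supplied text: anchor at 0
                    start, end = 0, len(surface) if len(surface) <= len(passage) else len(passage)
                else:
                    end = start + len(surface)
                entities[surface] = Entity(
                    entity_id=surface,
                    type=etype,
                    mentions=(EntityMention(surface=surface, start=start, end=end, passage_index=pidx),),
                )
            gold.add((head, tail, label))
        docs.append(
            Document(
                doc_id=doc_id,
                title="",
                passages=tuple(passages),
                entities=tuple(entities.values()),
                gold_labels=frozenset(gold),
            )
        )
    return docs


# ---------------------------------------------------------------------------
# public reader

def read_dataset(path: str | Path, dialect: Dialect, schema: RelationSchema) -> list[Document]:
    """Read a corpus file in the named dialect into canonical documents.

    All documents are validated on read: spans within passages, gold
    labels referencing declared entities, label codes in the schema.
    """
    path = Path(path)
    if dialect == "canonical":
        payload = json.loads(path.read_text(encoding="utf-8"))
        docs = [document_from_dict(rec, i) for i, rec in enumerate(payload["documents"])]
    elif dialect == "docred_json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        records = payload if isinstance(payload, list) else payload["documents"]
        docs = [_docred_document(rec, i, schema) for i, rec in enumerate(records)]
    elif dialect == "pair_list":
        docs = _pair_list_documents(path, schema)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for doc in docs:
        doc.validate_labels(schema)
    return docs


# ---------------------------------------------------------------------------
# candidate pairs

def enumerate_candidate_pairs(
    document: Document,
    schema: RelationSchema,
    mode: Literal["all_pairs", "annotated_only"] = "all_pairs",
    negative_sampling_ratio: float | None = None,
    rng: random.Random | None = None,
) -> list[RelationInstance]:
    """Enumerate the relation instances a document contributes.

    all_pairs: every (head_type, tail_type) entity combination, positive
    iff a gold positive label exists for the pair.  annotated_only: only
    pairs present in gold_labels (the pair-list convention), optionally
    extended with ``negative_sampling_ratio`` x positives sampled
    negatives drawn from unannotated typed pairs (requires ``rng``).
    """
    heads = document.entities_of_type(schema.head_type)
    tails = document.entities_of_type(schema.tail_type)
    positives = {
        (h, t) for h, t, r in document.gold_labels if r == schema.positive_label
    }

    def gold_of(h: Entity, t: Entity) -> BinaryLabel:
        return "positive" if (h.entity_id, t.entity_id) in positives else "negative"

    if mode == "all_pairs":
        return [
            RelationInstance(document.doc_id, h, t, gold_of(h, t))
            for h in heads
            for t in tails
        ]
    if mode != "annotated_only":
        raise ValueError(f"unknown mode {mode!r}")

    by_id = {e.entity_id: e for e in document.entities}
    instances = [
        RelationInstance(
            document.doc_id,
            by_id[h],
            by_id[t],
            "positive" if r == schema.positive_label else "negative",
        )
        for h, t, r in sorted(document.gold_labels)
    ]
    if negative_sampling_ratio:
        if rng is None:
            raise ValueError("negative sampling requires an rng")
        annotated = {(h, t) for h, t, _ in document.gold_labels}
        pool = sorted(
            (h.entity_id, t.entity_id)
            for h in heads
            for t in tails
            if (h.entity_id, t.entity_id) not in annotated
        )
        n_neg = min(len(pool), round(negative_sampling_ratio * sum(i.gold == "positive" for i in instances)))
        for h_id, t_id in rng.sample(pool, n_neg):
            instances.append(RelationInstance(document.doc_id, by_id[h_id], by_id[t_id], "negative"))
    return instances


def corpus_instances(
    documents: Iterable[Document],
    schema: RelationSchema,
    mode: Literal["all_pairs", "annotated_only"] = "all_pairs",
) -> list[RelationInstance]:
    out: list[RelationInstance] = []
    for doc in documents:
        out.extend(enumerate_candidate_pairs(doc, schema, mode))
    return out
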