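"""External knowledge-base construction.

For each entity pair we resolve both entities to controlled vocabulary
terms (MeSH term if mapped, official symbol otherwise), query a
literature backend for articles where both terms co-occur in the title
or abstract, and fall back to merging per-entity hits when no article
mentions both.  Backends are pluggable behind a small contract so the
whole stage runs against a deterministic local store; relevance order
("Best Match") is represented by explicit ranks.
"""

from __future__ import annotations

import json
import logging
from abc import ABC, abstractmethod
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .types import Entity

logger = logging.getLogger(__name__)

PMID_CAP = 10  # keep at most this many co-occurrence hits
FALLBACK_TOP_K = 5  # per-entity hits taken when no co-occurrence exists


@dataclass(frozen=True)
class RankedHit:
    """One search hit; rank 1 is the most relevant."""

    pmid: str
    rank: int

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")


@dataclass(frozen=True)
class KnowledgeRecord:
    """An abstract: identifier plus ordered paragraphs."""

    pmid: str
    paragraphs: tuple[str, ...]
    title: str = ""

    def __post_init__(self) -> None:
        if not self.paragraphs or not any(p.strip() for p in self.paragraphs):
            raise ValueError(f"record {self.pmid!r} has no non-empty paragraphs")

    @property
    def text(self) -> str:
        return "\n".join((self.title, *self.paragraphs)) if self.title else "\n".join(self.paragraphs)


class TermMapping:
    """entity_id -> controlled term (MeSH term or official symbol)."""

    def __init__(self, mapping: Mapping[str, str]):
        for eid, term in mapping.items():
            if not term or not term.strip():
                raise ValueError(f"empty term for entity {eid!r}")
        self._map = dict(mapping)

    def get(self, entity_id: str) -> Optional[str]:
        return self._map.get(entity_id)

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TermMapping":
        mapping = {}
        for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines()):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"term mapping line {i}: expected 2 columns, got {len(parts)}")
            mapping[parts[0]] = parts[1]
        return cls(mapping)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{eid}\t{term}" for eid, term in sorted(self._map.items())]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


class KnowledgeBackend(ABC):
    """Contract every literature backend satisfies.

    The offline store is exactly deterministic; live adapters must cache
    their responses so runs can be replayed.
    """

    @abstractmethod
    def cooccurrence_query(self, term1: str, term2: str) -> list[RankedHit]:
        """Articles where both terms appear in the title or abstract."""

    @abstractmethod
    def single_term_query(self, term: str) -> list[RankedHit]:
        """Articles mentioning one term, best first."""

    @abstractmethod
    def fetch(self, pmid: str) -> Optional[KnowledgeRecord]:
        """The abstract record for a pmid, or None when unresolvable."""


class OfflineStore(KnowledgeBackend):
    """A local literature store: records plus an optional explicit rank index.

    When an index entry exists for a query it supplies the ranking;
    otherwise hits are computed by case-insensitive substring scan over
    title+abstract, ranked by pmid (ascending) for determinism.
    """

    def __init__(
        self,
        records: Sequence[KnowledgeRecord],
        index: Optional[Mapping[tuple[str, ...], Sequence[str]]] = None,
    ):
        self._records = {r.pmid: r for r in records}
        if len(self._records) != len(records):
            raise ValueError("duplicate pmids in store")
        self._index = {tuple(k): tuple(v) for k, v in (index or {}).items()}

    def __len__(self) -> int:
        return len(self._records)

    @property
    def records(self) -> list[KnowledgeRecord]:
        return [self._records[p] for p in sorted(self._records)]

    def _scan(self, terms: tuple[str, ...]) -> list[str]:
        needles = [t.lower() for t in terms]
        return [
            pmid
            for pmid in sorted(self._records)
            if all(n in self._records[pmid].text.lower() for n in needles)
        ]

    def _hits(self, key: tuple[str, ...]) -> list[RankedHit]:
        pmids = self._index.get(key)
        if pmids is None and len(key) == 2:
            pmids = self._index.get((key[1], key[0]))
        if pmids is None:
            pmids = self._scan(key)
        return [RankedHit(pmid=p, rank=i) for i, p in enumerate(pmids, start=1)]

    def cooccurrence_query(self, term1: str, term2: str) -> list[RankedHit]:
        return self._hits((term1, term2))

    def single_term_query(self, term: str) -> list[RankedHit]:
        return self._hits((term,))

    def fetch(self, pmid: str) -> Optional[KnowledgeRecord]:
        return self._records.get(pmid)

    # --- serialization: JSON lines of records + TSV query index ---

    def save(self, records_path: str | Path, index_path: str | Path | None = None) -> None:
        with Path(records_path).open("w", encoding="utf-8") as fh:
            for rec in self.records:
                fh.write(
                    json.dumps(
                        {"pmid": rec.pmid, "title": rec.title, "paragraphs": list(rec.paragraphs)},
                        ensure_ascii=False,
                        sort_keys=True,
                    )
                    + "\n"
                )
        if index_path is not None:
            with Path(index_path).open("w", encoding="utf-8") as fh:
                for key in sorted(self._index):
                    fh.write("|".join(key) + "\t" + ",".join(self._index[key]) + "\n")

    @classmethod
    def load(cls, records_path: str | Path, index_path: str | Path | None = None) -> "OfflineStore":
        records = []
        for line in Path(records_path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            rec = json.loads(line)
            records.append(
                KnowledgeRecord(
                    pmid=rec["pmid"],
                    title=rec.get("title", ""),
                    paragraphs=tuple(rec["paragraphs"]),
                )
            )
        index = {}
        if index_path is not None and Path(index_path).exists():
            for line in Path(index_path).read_text(encoding="utf-8").splitlines():
                if not line.strip():
                    continue
                key_part, pmid_part = line.split("\t")
                index[tuple(key_part.split("|"))] = tuple(p for p in pmid_part.split(",") if p)
        return cls(records, index)


# ---------------------------------------------------------------------------
# operations

def resolve_entity_term(
    entity: Entity,
    mapping: TermMapping,
    symbol: Optional[str] = None,
) -> str:
    """The controlled term for an entity: its MeSH mapping if present,
    else the supplied official symbol, else an error."""
    term = mapping.get(entity.entity_id)
    if term is not None:
        return term
    if symbol:
        return symbol
    raise KeyError(
        f"entity {entity.entity_id!r} has no term mapping and no official symbol"
    )


def _check_ranked(hits: Sequence[RankedHit], label: str) -> None:
    ranks = [h.rank for h in hits]
    if ranks != list(range(1, len(hits) + 1)):
        raise ValueError(f"{label} hits are not rank-sorted 1..n: {ranks}")


def select_pmids(
    cooccurrence_hits: Sequence[RankedHit],
    entity1_hits: Sequence[RankedHit],
    entity2_hits: Sequence[RankedHit],
    cap: int = PMID_CAP,
    fallback_k: int = FALLBACK_TOP_K,
) -> list[str]:
    """Choose article identifiers for the knowledge base.

    Co-occurrence hits, when any exist, are taken directly — all of them
    up to ``cap``, best rank first.  Otherwise the best ``fallback_k``
    hits from each per-entity list are merged (entity 1's first),
    dropping duplicate pmids on first occurrence.
    """
    if not (cap >= fallback_k >= 1):
        raise ValueError(f"need cap >= fallback_k >= 1, got cap={cap}, fallback_k={fallback_k}")
    _check_ranked(cooccurrence_hits, "co-occurrence")
    _check_ranked(entity1_hits, "entity1")
    _check_ranked(entity2_hits, "entity2")

    if cooccurrence_hits:
        return [h.pmid for h in cooccurrence_hits[:cap]]

    merged: list[str] = []
    seen: set[str] = set()
    for h in (*entity1_hits[:fallback_k], *entity2_hits[:fallback_k]):
        if h.pmid not in seen:
            seen.add(h.pmid)
            merged.append(h.pmid)
    if not merged:
        logger.info("no literature hits for either entity; empty knowledge base")
    return merged


def fetch_records(
    pmids: Sequence[str],
    backend: KnowledgeBackend,
) -> list[KnowledgeRecord]:
    """Fetch abstract records in input order; unresolvable pmids are
    skipped with a warning rather than failing the pair."""
    records = []
    skipped = 0
    for pmid in pmids:
        rec = backend.fetch(pmid)
        if rec is None:
            skipped += 1
            logger.warning("pmid %s could not be fetched; skipping", pmid)
            continue
        records.append(rec)
    if skipped:
        logger.info("fetched %d/%d records (%d skipped)", len(records), len(pmids), skipped)
    return records
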