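"""Live PubMed adapter over NCBI E-utilities (esearch/efetch semantics).

Optional: requires biopython and network access, neither of which the
offline test suite touches.  Queries request relevance ("Best Match")
sort; both terms are searched in title-or-abstract fields, matching the
co-occurrence rule the knowledge stage implements.  Every response is
cached into the offline-store layout so a live run can be replayed
later as a deterministic :class:`~litrex.knowledge.OfflineStore`.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Optional

from .knowledge import KnowledgeBackend, KnowledgeRecord, OfflineStore, RankedHit

logger = logging.getLogger(__name__)

_RETRIES = 3
_BACKOFF_S = 2.0


class PubMedBackend(KnowledgeBackend):
    """E-utilities literature backend with retry and local caching.

    ``field_tag`` controls how terms are scoped ("tiab" searches
    title/abstract free text; "mh" would use MeSH field tags instead —
    the service's exact behavior differs and both are supported).
    """

    def __init__(
        self,
        email: str,
        api_key: Optional[str] = None,
        retmax: int = 50,
        field_tag: str = "tiab",
        cache_dir: Optional[str | Path] = None,
    ):
        try:
            from Bio import Entrez
        except ImportError as exc:  # pragma: no cover
            raise ImportError("the live PubMed backend requires biopython") from exc
        self._entrez = Entrez
        Entrez.email = email
        if api_key:
            Entrez.api_key = api_key
        self.retmax = retmax
        self.field_tag = field_tag
        self.cache_dir = Path(cache_dir) if cache_dir else None
        self._record_cache: dict[str, KnowledgeRecord] = {}

    def _with_retries(self, fn, what: str):
        last: Exception | None = None
        for attempt in range(_RETRIES):
            try:
                return fn()
            except Exception as exc:  # transport errors only
                last = exc
                wait = _BACKOFF_S * 2**attempt
                logger.warning("%s failed (attempt %d): %s; retrying in %.0fs", what, attempt + 1, exc, wait)
                time.sleep(wait)
        raise RuntimeError(f"{what} failed after {_RETRIES} attempts") from last

    def _search(self, query: str) -> list[RankedHit]:
        logger.info("esearch query: %s", query)

        def go():
            handle = self._entrez.esearch(db="pubmed", term=query, sort="relevance", retmax=self.retmax)
            result = self._entrez.read(handle)
            handle.close()
            return result

        result = self._with_retries(go, f"esearch({query!r})")
        return [RankedHit(pmid=p, rank=i) for i, p in enumerate(result["IdList"], start=1)]

    def cooccurrence_query(self, term1: str, term2: str) -> list[RankedHit]:
        return self._search(f"({term1}[{self.field_tag}]) AND ({term2}[{self.field_tag}])")

    def single_term_query(self, term: str) -> list[RankedHit]:
        return self._search(f"{term}[{self.field_tag}]")

    def fetch(self, pmid: str) -> Optional[KnowledgeRecord]:
        if pmid in self._record_cache:
            return self._record_cache[pmid]

        def go():
            handle = self._entrez.efetch(db="pubmed", id=pmid, rettype="abstract", retmode="xml")
            result = self._entrez.read(handle)
            handle.close()
            return result

        result = self._with_retries(go, f"efetch({pmid})")
        articles = result.get("PubmedArticle", [])
        if not articles:
            return None
        citation = articles[0]["MedlineCitation"]["Article"]
        title = str(citation.get("ArticleTitle", ""))
        abstract = citation.get("Abstract", {}).get("AbstractText", [])
        paragraphs = tuple(str(p) for p in abstract if str(p).strip())
        if not paragraphs:
            return None
        record = KnowledgeRecord(pmid=pmid, title=title, paragraphs=paragraphs)
        self._record_cache[pmid] = record
        if self.cache_dir is not None:
            self.cache_dir.mkdir(parents=True, exist_ok=True)
            OfflineStore(list(self._record_cache.values())).save(self.cache_dir / "knowledge.jsonl")
        return record
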