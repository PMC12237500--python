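"""Segmentation of abstracts into retrievable chunks.

Three strategies are supported, singly or combined:

* paragraph — each abstract paragraph is one chunk;
* sentence — each sentence is one chunk;
* window — k consecutive sentences per chunk, advancing d sentences at a
  time (defaults k=3, d=2, i.e. adjacent windows share one sentence),
  with a final end-anchored window whenever the stride would leave the
  last sentence uncovered.

Chunks carry composite identifiers (pmid, strategy tag, index); merging
strategies deduplicates identical texts (keeping the smallest id) and
sorts by identifier, so the store is a deterministic function of its
input records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .knowledge import KnowledgeRecord

DEFAULT_WINDOW_SIZE = 3
DEFAULT_WINDOW_STRIDE = 2

STRATEGY_TAGS = {"paragraph": "P", "sentence": "S", "window": "W"}

# Common biomedical/scholarly abbreviations that end with a period but do
# not terminate a sentence.  Compared lowercase, trailing period stripped.
_ABBREVIATIONS = frozenset(
    {
        "al", "approx", "b.i.d", "ca", "cf", "dr", "e.g", "eq", "et", "et al",
        "etc", "fig", "figs", "i.e", "i.m", "i.p", "i.v", "inc", "mr", "mrs",
        "ms", "no", "p.o", "prof", "q.d", "ref", "resp", "s.c", "sp", "spp",
        "subsp", "t.i.d", "vs",
    }
)

_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s)")
_TRAILING_WORD_RE = re.compile(r"[\w.]+$")


def split_sentences(paragraph: str) -> list[str]:
    """Split a paragraph into sentences with a deterministic rule set.

    A boundary is sentence-final punctuation followed by whitespace,
    unless the preceding word (period-stripped, lowercased) is a known
    abbreviation.  Sentences are substrings of the input, so their
    space-join reproduces the paragraph up to inter-sentence whitespace.
    """
    if not paragraph or not paragraph.strip():
        raise ValueError("cannot split an empty paragraph")

    cuts = []
    for m in _BOUNDARY_RE.finditer(paragraph):
        before = paragraph[: m.end()].rstrip(".!?")
        word = _TRAILING_WORD_RE.search(before)
        token = word.group(0).lower().rstrip(".") if word else ""
        if token in _ABBREVIATIONS or before.lower().endswith("et al"):
            continue
        cuts.append(m.end())

    sentences = []
    start = 0
    for cut in cuts:
        piece = paragraph[start:cut].strip()
        if piece:
            sentences.append(piece)
        start = cut
    tail = paragraph[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def window_segments(
    sentences: Sequence[str],
    k: int = DEFAULT_WINDOW_SIZE,
    d: int = DEFAULT_WINDOW_STRIDE,
) -> list[tuple[str, ...]]:
    """Group sentences into sliding windows of k with stride d.

    Consecutive windows share k-d sentences.  If N <= k the whole
    sequence is the single window; if the stride leaves the final
    sentence uncovered, one extra window of the last k sentences is
    appended so coverage is total.
    """
    if k < 1:
        raise ValueError(f"window size k must be >= 1, got {k}")
    if not (1 <= d <= k):
        raise ValueError(f"stride d must satisfy 1 <= d <= k, got d={d}, k={k}")
    if not sentences:
        raise ValueError("cannot window an empty sentence sequence")

    n = len(sentences)
    if n <= k:
        return [tuple(sentences)]

    windows = [tuple(sentences[s : s + k]) for s in range(0, n - k + 1, d)]
    last_covered = ((n - k) // d) * d + k  # end of the last full stride window
    if last_covered < n:
        windows.append(tuple(sentences[n - k :]))
    return windows


@dataclass(frozen=True, order=True)
class ChunkId:
    """Composite chunk identifier ordering by (pmid, strategy tag, index)."""

    pmid: str
    strategy: str  # one of P, S, W
    index: int

    def __str__(self) -> str:
        return f"{self.pmid}:{self.strategy}:{self.index:04d}"


@dataclass(frozen=True)
class Provenance:
    pmid: str
    paragraph_index: int
    sentence_range: tuple[int, int]  # half-open, within the paragraph


@dataclass(frozen=True)
class Chunk:
    chunk_id: ChunkId
    text: str
    provenance: Provenance

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError(f"chunk {self.chunk_id} has empty text")


def normalize_text(text: str) -> str:
    """Whitespace-collapsed, end-stripped, case-preserving."""
    return " ".join(text.split())


@dataclass(frozen=True)
class ChunkStore:
    """A deduplicated chunk collection, totally ordered by chunk id."""

    chunks: tuple[Chunk, ...]
    strategies: frozenset[str]
    source_record_count: int

    def __len__(self) -> int:
        return len(self.chunks)

    def texts(self) -> list[str]:
        return [c.text for c in self.chunks]

    def save_jsonl(self, path) -> None:
        import json
        from pathlib import Path

        with Path(path).open("w", encoding="utf-8") as fh:
            for c in self.chunks:
                fh.write(
                    json.dumps(
                        {
                            "chunk_id": str(c.chunk_id),
                            "text": c.text,
                            "provenance": {
                                "pmid": c.provenance.pmid,
                                "paragraph_index": c.provenance.paragraph_index,
                                "sentence_range": list(c.provenance.sentence_range),
                            },
                        },
                        ensure_ascii=False,
                        sort_keys=True,
                    )
                    + "\n"
                )


def build_chunk_store(
    records: Iterable[KnowledgeRecord],
    strategies: Iterable[str] = ("sentence", "window", "paragraph"),
    k: int = DEFAULT_WINDOW_SIZE,
    d: int = DEFAULT_WINDOW_STRIDE,
) -> ChunkStore:
    """Apply the selected strategies to every record and merge.

    Duplicate texts (after whitespace normalization) keep only the chunk
    with the smallest identifier; the result is sorted by identifier.
    """
    records = list(records)
    strategy_set = frozenset(strategies)
    if not records:
        raise ValueError("no records to chunk")
    unknown = strategy_set - STRATEGY_TAGS.keys()
    if unknown or not strategy_set:
        raise ValueError(f"strategies must be a non-empty subset of {sorted(STRATEGY_TAGS)}, got {sorted(strategy_set)}")

    chunks: list[Chunk] = []
    for rec in records:
        counters = {tag: 0 for tag in STRATEGY_TAGS.values()}

        def add(tag: str, text: str, p_idx: int, s_range: tuple[int, int]) -> None:
            norm = normalize_text(text)
            if not norm:
                return
            chunks.append(
                Chunk(
                    chunk_id=ChunkId(rec.pmid, tag, counters[tag]),
                    text=norm,
                    provenance=Provenance(rec.pmid, p_idx, s_range),
                )
            )
            counters[tag] += 1

        for p_idx, paragraph in enumerate(rec.paragraphs):
            if not paragraph.strip():
                continue
            sentences = split_sentences(paragraph)
            if "paragraph" in strategy_set:
                add("P", paragraph, p_idx, (0, len(sentences)))
            if "sentence" in strategy_set:
                for s_idx, sent in enumerate(sentences):
                    add("S", sent, p_idx, (s_idx, s_idx + 1))
            if "window" in strategy_set:
                start = 0
                for win in window_segments(sentences, k=k, d=d):
                    # recover the window's start for provenance
                    w_start = _window_start(len(sentences), k, d, start)
                    add("W", " ".join(win), p_idx, (w_start, w_start + len(win)))
                    start += 1

    chunks.sort(key=lambda c: c.chunk_id)
    deduped: list[Chunk] = []
    seen_texts: set[str] = set()
    for c in chunks:
        if c.text in seen_texts:
            continue
        seen_texts.add(c.text)
        deduped.append(c)

    return ChunkStore(
        chunks=tuple(deduped),
        strategies=strategy_set,
        source_record_count=len(records),
    )


def _window_start(n: int, k: int, d: int, ordinal: int) -> int:
    """Start sentence index of the ordinal-th window over n sentences."""
    if n <= k:
        return 0
    n_stride = (n - k) // d + 1
    if ordinal < n_stride:
        return ordinal * d
    return n - k  # end-anchored final window
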