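"""Generator backends: the contract, deterministic mocks, and cassettes.

Live chat-completion services plug in behind :class:`LlmBackend`.  The
mocks make the full pipeline testable offline:

* :class:`OracleBackend` — answers every question correctly (upper-bound
  sanity check: the harness should score a perfect backend at F1 = 1);
* :class:`ConstantBackend` — returns a fixed completion (always-yes,
  always-empty, ...);
* :class:`KnowledgeGatedBackend` — a caricature of a grounded, guided
  model: it answers from evidence only when the prompt both shows the
  supporting fact and provides reasoning guidance; without guidance it
  over-predicts positives (high recall, low precision), and with
  guidance but no supporting evidence it cannot confirm a positive.
  Retrieval and reasoning ablations therefore separate cleanly.
* :class:`ReplayBackend` — record/replay cassette wrapper so live runs
  can be captured once and re-run byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from .prompting import ANSWER_PREFIX, ZERO_SHOT_COT_CUE, GenerationOutput, Prompt, parse_answer, split_reasoning


@dataclass(frozen=True)
class SamplingConfig:
    temperature: float = 0.0
    seed: Optional[int] = None


class LlmBackend(ABC):
    """Contract for text generators: (prompt text, sampling) -> raw text."""

    name: str = "llm"

    @abstractmethod
    def complete(self, prompt_text: str, sampling: SamplingConfig) -> str: ...


def _question_of(prompt_text: str) -> str:
    """The question line a rendered prompt opens with."""
    first = prompt_text.split("\n", 1)[0]
    prefix = "Question: "
    if not first.startswith(prefix):
        raise ValueError("prompt does not start with a question line")
    return first[len(prefix) :]


class OracleBackend(LlmBackend):
    """Answers each fixture question with its gold label."""

    name = "oracle-mock"

    def __init__(self, answers_by_question: Mapping[str, bool]):
        self._answers = dict(answers_by_question)

    def complete(self, prompt_text: str, sampling: SamplingConfig) -> str:
        question = _question_of(prompt_text)
        if question not in self._answers:
            raise KeyError(f"oracle has no answer for question {question!r}")
        verdict = "Yes" if self._answers[question] else "No"
        return f"Consulting the gold annotation for this pair. {ANSWER_PREFIX} {verdict}."


class ConstantBackend(LlmBackend):
    """Returns the same completion for every prompt."""

    def __init__(self, completion: str, name: str = "constant-mock"):
        self.completion = completion
        self.name = name

    def complete(self, prompt_text: str, sampling: SamplingConfig) -> str:
        return self.completion


def always_yes_backend() -> ConstantBackend:
    return ConstantBackend(f"{ANSWER_PREFIX} Yes.", name="always-yes-mock")


def always_empty_backend() -> ConstantBackend:
    return ConstantBackend("", name="always-empty-mock")


_GUIDANCE_MARKERS = ("Reasoning steps:", ZERO_SHOT_COT_CUE)


class KnowledgeGatedBackend(LlmBackend):
    """Deterministic mock whose accuracy depends on prompt content.

    ``facts_by_question`` maps each fixture question to the planted
    evidence sentence for positive pairs, or None for negative pairs.
    Decision rule:

    * no reasoning guidance in the prompt -> always "Yes" (an unguided
      model over-predicting the relation);
    * guidance present, pair positive -> "Yes" iff the planted fact text
      appears in the prompt, else "No" (cannot confirm without
      evidence);
    * guidance present, pair negative -> "No".
    """

    name = "knowledge-gated-mock"

    def __init__(self, facts_by_question: Mapping[str, Optional[str]]):
        self._facts = dict(facts_by_question)

    def complete(self, prompt_text: str, sampling: SamplingConfig) -> str:
        question = _question_of(prompt_text)
        if question not in self._facts:
            raise KeyError(f"gated mock knows nothing about question {question!r}")
        guided = any(marker in prompt_text for marker in _GUIDANCE_MARKERS)
        if not guided:
            return f"The relation seems plausible. {ANSWER_PREFIX} Yes."
        fact = self._facts[question]
        if fact is None:
            return f"Working through the steps, no supporting statement exists. {ANSWER_PREFIX} No."
        norm_prompt = " ".join(prompt_text.split())
        if " ".join(fact.split()) in norm_prompt:
            return f"The provided knowledge states the relation directly. {ANSWER_PREFIX} Yes."
        return f"No retrieved evidence confirms the relation. {ANSWER_PREFIX} No."


class ReplayBackend(LlmBackend):
    """Cassette wrapper: record completions from an inner backend, or
    replay a stored cassette with no backend at all.

    Cassette format: JSON mapping SHA-256(prompt text) -> completion.
    """

    name = "replay"

    def __init__(self, cassette_path: str | Path, inner: Optional[LlmBackend] = None):
        self.path = Path(cassette_path)
        self.inner = inner
        self._cassette: dict[str, str] = (
            json.loads(self.path.read_text(encoding="utf-8")) if self.path.exists() else {}
        )

    @staticmethod
    def _key(prompt_text: str) -> str:
        return hashlib.sha256(prompt_text.encode("utf-8")).hexdigest()

    def complete(self, prompt_text: str, sampling: SamplingConfig) -> str:
        key = self._key(prompt_text)
        if key in self._cassette:
            return self._cassette[key]
        if self.inner is None:
            raise KeyError(f"cassette {self.path} has no recording for this prompt")
        completion = self.inner.complete(prompt_text, sampling)
        self._cassette[key] = completion
        self.path.write_text(
            json.dumps(self._cassette, indent=1, sort_keys=True), encoding="utf-8"
        )
        return completion


def generate_answer(prompt: Prompt, backend: LlmBackend, sampling: SamplingConfig = SamplingConfig()) -> GenerationOutput:
    """Run one completion and parse it.

    The raw completion is kept verbatim; an empty completion parses as
    unparseable rather than raising.
    """
    try:
        raw = backend.complete(prompt.render(), sampling)
    except (KeyError, ValueError):
        raise
    except Exception as exc:  # pragma: no cover - live transport failures
        raise RuntimeError(f"generator backend {backend.name!r} failed: {exc}") from exc
    return GenerationOutput(raw=raw, reasoning=split_reasoning(raw), parsed=parse_answer(raw))
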