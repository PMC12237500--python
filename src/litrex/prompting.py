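"""Question construction, prompt assembly, and answer parsing.

Each relation decision is reframed as a yes/no question built from the
schema's template and the two entity surface forms.  Three prompt kinds
exist:

* standard — question + full query document + output directive;
* zero_shot_cot — standard plus the generic cue "Let's think step by
  step." before the directive;
* augmented — standard extended with retrieved knowledge chunks and/or
  task-specific numbered reasoning steps.

Completions must end with the fixed prefix "My answer is:" followed by
Yes or No; :func:`parse_answer` extracts the decision from the last
occurrence of the prefix so reasoning that quotes the directive cannot
confuse it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from .templates import CotTemplate
from .types import Document, RelationInstance, RelationSchema

ANSWER_PREFIX = "My answer is:"
ZERO_SHOT_COT_CUE = "Let's think step by step."
OUTPUT_DIRECTIVE = (
    "Answer the question with Yes or No. State your final answer on the last "
    f'line, prefixed with "{ANSWER_PREFIX}".'
)

PromptKind = Literal["standard", "zero_shot_cot", "augmented"]
Answer = Literal["yes", "no", "unparseable"]


@dataclass(frozen=True)
class Question:
    text: str
    instance: RelationInstance

    def __post_init__(self) -> None:
        for surface in (self.instance.head.canonical_surface, self.instance.tail.canonical_surface):
            if surface not in self.text:
                raise ValueError(f"question text must contain entity surface {surface!r}")


def build_question(instance: RelationInstance, schema: RelationSchema) -> Question:
    """Fill the schema's question template with the pair's surface forms."""
    instance.check_types(schema)
    text = schema.question_template.format(
        head=instance.head.canonical_surface,
        tail=instance.tail.canonical_surface,
    )
    return Question(text=text, instance=instance)


@dataclass(frozen=True)
class Prompt:
    """An assembled instruction ready for a generator backend.

    standard prompts carry no retrieved text and no reasoning steps; an
    augmented prompt carries at least one of the two (retrieved
    knowledge, task-specific CoT), which also covers the single-component
    ablations.
    """

    kind: PromptKind
    question: Question
    document_text: str
    retrieved: tuple[str, ...] = ()
    cot: Optional[CotTemplate] = None

    def __post_init__(self) -> None:
        if self.kind in ("standard", "zero_shot_cot") and (self.retrieved or self.cot):
            raise ValueError(f"{self.kind} prompts carry no retrieved chunks and no CoT")
        if self.kind == "augmented" and not self.retrieved and self.cot is None:
            raise ValueError("augmented prompts need retrieved chunks or a CoT template")

    def render(self) -> str:
        """Deterministic plain-text rendering with a fixed section order:
        question, document, external knowledge, reasoning steps,
        zero-shot cue, output directive."""
        parts = [
            f"Question: {self.question.text}",
            f"Document:\n{self.document_text}",
        ]
        if self.retrieved:
            block = "\n".join(f"[{i}] {text}" for i, text in enumerate(self.retrieved, start=1))
            parts.append(f"External knowledge:\n{block}")
        if self.cot is not None:
            head = self.question.instance.head.canonical_surface
            tail = self.question.instance.tail.canonical_surface
            parts.append(f"Reasoning steps:\n{self.cot.render(head, tail)}")
        if self.kind == "zero_shot_cot":
            parts.append(ZERO_SHOT_COT_CUE)
        parts.append(OUTPUT_DIRECTIVE)
        return "\n\n".join(parts)


def build_prompt(
    question: Question,
    document: Document,
    retrieved: Sequence[str] = (),
    cot: Optional[CotTemplate] = None,
    kind: PromptKind = "standard",
) -> Prompt:
    return Prompt(
        kind=kind,
        question=question,
        document_text=document.full_text,
        retrieved=tuple(retrieved),
        cot=cot,
    )


# ---------------------------------------------------------------------------
# answer parsing

_PREFIX_RE = re.compile(re.escape(ANSWER_PREFIX), re.IGNORECASE)
_FIRST_WORD_RE = re.compile(r"[A-Za-z]+")


def parse_answer(raw: str) -> Answer:
    """Extract the yes/no decision from a completion.

    Finds the last case-insensitive occurrence of the answer prefix; the
    first alphabetic token after it, lowercased, must be "yes" or "no".
    Anything else — including a missing prefix — is unparseable.
    """
    matches = list(_PREFIX_RE.finditer(raw))
    if not matches:
        return "unparseable"
    tail = raw[matches[-1].end() :]
    word = _FIRST_WORD_RE.search(tail)
    if word is None:
        return "unparseable"
    token = word.group(0).lower()
    return token if token in ("yes", "no") else "unparseable"  # type: ignore[return-value]


@dataclass(frozen=True)
class GenerationOutput:
    """A backend completion with its parsed decision.

    ``reasoning`` is everything before the final answer prefix — the
    chain-of-thought trace when the model produced one.
    """

    raw: str
    reasoning: str
    parsed: Answer


def split_reasoning(raw: str) -> str:
    matches = list(_PREFIX_RE.finditer(raw))
    return raw[: matches[-1].start()].strip() if matches else raw.strip()
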