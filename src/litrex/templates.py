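"""Question and chain-of-thought template assets.

Wordings live as editable plain-text files under ``litrex/assets/``:
one question template and one numbered CoT step list per dataset.  The
CDR wording asks whether the chemical induces the disease; GDA and ADE
wordings follow the same pattern for their relation types.  All templates
use ``{head}``/``{tail}`` slots filled with entity surface forms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

from .types import RelationSchema

_STEP_RE = re.compile(r"^(\d+)\.\s*(.*\S)\s*$")


@dataclass(frozen=True)
class CotTemplate:
    """An ordered list of task-specific reasoning instructions.

    Steps are numbered consecutively from 1; at least two are required so
    the template actually decomposes the task.
    """

    dataset_tag: str
    steps: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.steps) < 2:
            raise ValueError("a CoT template needs at least 2 steps")

    def render(self, head: str, tail: str) -> str:
        lines = [
            f"{i}. " + step.format(head=head, tail=tail)
            for i, step in enumerate(self.steps, start=1)
        ]
        return "\n".join(lines)


def _read_asset(kind: str, name: str) -> str:
    ref = resources.files("litrex.assets").joinpath(kind).joinpath(f"{name}.txt")
    try:
        return ref.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise KeyError(f"no {kind} asset named {name!r}") from None


def load_question_template(name: str) -> str:
    return _read_asset("questions", name).strip()


def load_cot_template(name: str) -> CotTemplate:
    """Parse a numbered-step asset file into a :class:`CotTemplate`."""
    steps: list[str] = []
    for line in _read_asset("cot", name).splitlines():
        if not line.strip():
            continue
        m = _STEP_RE.match(line)
        if m is None:
            raise ValueError(f"CoT asset {name!r}: unnumbered line {line!r}")
        if int(m.group(1)) != len(steps) + 1:
            raise ValueError(f"CoT asset {name!r}: steps not numbered consecutively from 1")
        steps.append(m.group(2))
    return CotTemplate(dataset_tag=name, steps=tuple(steps))


def default_schema(dataset: str) -> RelationSchema:
    """Built-in schemas for the three benchmark relation types."""
    if dataset == "cdr":
        return RelationSchema(
            dataset_name="cdr",
            head_type="Chemical",
            tail_type="Disease",
            positive_label="1:CID:2",
            negative_label="1:NR:2",
            question_template=load_question_template("cdr"),
            cot_template_ref="cdr",
        )
    if dataset == "gda":
        return RelationSchema(
            dataset_name="gda",
            head_type="Gene",
            tail_type="Disease",
            positive_label="1:GDA:2",
            negative_label="1:NR:2",
            question_template=load_question_template("gda"),
            cot_template_ref="gda",
        )
    if dataset == "ade":
        return RelationSchema(
            dataset_name="ade",
            head_type="Drug",
            tail_type="AdverseEvent",
            positive_label="Drug-ADE",
            negative_label=None,
            question_template=load_question_template("ade"),
            cot_template_ref="ade",
        )
    raise KeyError(f"unknown dataset {dataset!r} (expected cdr, gda, or ade)")
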