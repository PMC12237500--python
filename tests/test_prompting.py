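"""Question building, prompt assembly, answer parsing, and generation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litrex import (
    ANSWER_PREFIX,
    ConstantBackend,
    OracleBackend,
    ReplayBackend,
    SamplingConfig,
    always_empty_backend,
    build_prompt,
    build_question,
    generate_answer,
    parse_answer,
)
from litrex.prompting import OUTPUT_DIRECTIVE, ZERO_SHOT_COT_CUE
from litrex.templates import CotTemplate, default_schema, load_cot_template
from litrex.types import Entity, EntityMention, RelationInstance

from conftest import make_document


@pytest.fixture
def instance(doc_2x3):
    head = next(e for e in doc_2x3.entities if e.entity_id == "c0")
    tail = next(e for e in doc_2x3.entities if e.entity_id == "d0")
    return RelationInstance(doc_2x3.doc_id, head, tail, "positive")


class TestBuildQuestion:
    def test_cdr_wording(self, cdr_schema, instance):
        q = build_question(instance, cdr_schema)
        assert q.text == "Does chemical c0 induce disease d0?"

    def test_gda_wording(self):
        gda = default_schema("gda")
        gene = Entity("G", "Gene", (EntityMention("G", 0, 1, 0),))
        dis = Entity("D", "Disease", (EntityMention("D", 0, 1, 0),))
        q = build_question(RelationInstance("x", gene, dis, "negative"), gda)
        assert q.text == "Is gene G related to disease D?"

    def test_type_mismatch_errors(self, cdr_schema, instance):
        swapped = RelationInstance(instance.doc_id, instance.tail, instance.head, "positive")
        with pytest.raises(ValueError, match="do not match schema"):
            build_question(swapped, cdr_schema)

    def test_canonical_surface_is_first_mention(self, cdr_schema):
        head = Entity(
            "c9", "Chemical",
            (EntityMention("Aspirin", 0, 7, 0), EntityMention("aspirin", 0, 7, 0)),
        )
        tail = Entity("d9", "Disease", (EntityMention("rash", 0, 4, 0),))
        doc = make_document()  # unused surfaces; question only needs the pair
        q = build_question(RelationInstance(doc.doc_id, head, tail, "negative"), cdr_schema)
        assert "Aspirin" in q.text and "aspirin rash" not in q.text


class TestBuildPrompt:
    def test_standard_layout(self, cdr_schema, doc_2x3, instance):
        q = build_question(instance, cdr_schema)
        text = build_prompt(q, doc_2x3, kind="standard").render()
        assert text.startswith(f"Question: {q.text}")
        assert doc_2x3.passages[0] in text
        assert "External knowledge:" not in text and "Reasoning steps:" not in text
        assert text.endswith(OUTPUT_DIRECTIVE)

    def test_zero_shot_cot_contains_cue(self, cdr_schema, doc_2x3, instance):
        q = build_question(instance, cdr_schema)
        text = build_prompt(q, doc_2x3, kind="zero_shot_cot").render()
        assert ZERO_SHOT_COT_CUE in text

    def test_augmented_contains_chunk_and_numbered_steps(self, cdr_schema, doc_2x3, instance):
        q = build_question(instance, cdr_schema)
        cot = load_cot_template("cdr")
        text = build_prompt(
            q, doc_2x3, retrieved=["c0 induces d0 in treated patients."], cot=cot, kind="augmented"
        ).render()
        assert "[1] c0 induces d0 in treated patients." in text
        assert "1. Define the concept of chemically induced diseases clearly." in text
        assert "2. Determine whether chemical entity c0 induces the occurrence of disease entity d0." in text

    def test_kind_argument_consistency_enforced(self, cdr_schema, doc_2x3, instance):
        q = build_question(instance, cdr_schema)
        with pytest.raises(ValueError):
            build_prompt(q, doc_2x3, retrieved=["x"], kind="standard")
        with pytest.raises(ValueError):
            build_prompt(q, doc_2x3, kind="augmented")  # neither chunks nor steps

    def test_directive_appears_exactly_once(self, cdr_schema, doc_2x3, instance):
        q = build_question(instance, cdr_schema)
        for kind, kwargs in [
            ("standard", {}),
            ("zero_shot_cot", {}),
            ("augmented", {"retrieved": ["some evidence."]}),
        ]:
            text = build_prompt(q, doc_2x3, kind=kind, **kwargs).render()
            assert text.count(OUTPUT_DIRECTIVE) == 1

    def test_rendering_is_pure(self, cdr_schema, doc_2x3, instance):
        q = build_question(instance, cdr_schema)
        p = build_prompt(q, doc_2x3, kind="standard")
        assert p.render() == p.render()


class TestCotTemplate:
    def test_requires_two_steps(self):
        with pytest.raises(ValueError, match="2 steps"):
            CotTemplate("x", ("only one",))

    def test_asset_steps_render_numbered(self):
        cot = load_cot_template("cdr")
        rendered = cot.render("X", "Y")
        assert rendered.splitlines()[0].startswith("1. ")
        assert "X" in rendered and "Y" in rendered

    def test_unknown_asset_errors(self):
        with pytest.raises(KeyError):
            load_cot_template("nonexistent")


class TestParseAnswer:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("…therefore induction is supported. My answer is: Yes.", "yes"),
            ("MY ANSWER IS:no", "no"),
            ("The relation likely holds.", "unparseable"),
            ("My answer is: maybe", "unparseable"),
            ("My answer is:", "unparseable"),
            ("", "unparseable"),
            ('I will end with "My answer is:" as asked. My answer is: No.', "no"),
            ("my answer is:\n  YES, definitely", "yes"),
        ],
    )
    def test_prefix_protocol(self, raw, expected):
        assert parse_answer(raw) == expected

    def test_last_occurrence_wins(self):
        raw = "My answer is: no — wait, reconsidering the evidence. My answer is: Yes."
        assert parse_answer(raw) == "yes"

    @given(
        reasoning=st.text(
            alphabet=st.characters(codec="ascii", exclude_characters=":"), max_size=80
        ),
        verdict=st.sampled_from(["Yes", "no", "YES", "No"]),
        pad=st.sampled_from(["", " ", "  ", "\n"]),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_compliant_completions_never_unparseable(self, reasoning, verdict, pad):
        raw = f"{reasoning} {ANSWER_PREFIX}{pad}{verdict}."
        assert parse_answer(raw) == verdict.lower()


class TestGenerateAnswer:
    def test_oracle_backend_answers_match_fixture_gold(self, suite, cdr_schema, doc_2x3):
        backend = OracleBackend(suite.answers_by_question())
        inst = suite.instances()[0]
        q = build_question(inst, cdr_schema)
        doc = next(d for d in suite.documents if d.doc_id == inst.doc_id)
        out = generate_answer(build_prompt(q, doc, kind="standard"), backend)
        assert (out.parsed == "yes") == suite.oracle[inst.key]

    def test_empty_backend_is_unparseable(self, cdr_schema, doc_2x3, instance):
        q = build_question(instance, cdr_schema)
        out = generate_answer(build_prompt(q, doc_2x3, kind="standard"), always_empty_backend())
        assert out.parsed == "unparseable" and out.raw == ""

    def test_reasoning_is_text_before_final_prefix(self, cdr_schema, doc_2x3, instance):
        backend = ConstantBackend("Step 1 held. Step 2 held. My answer is: Yes.")
        q = build_question(instance, cdr_schema)
        out = generate_answer(build_prompt(q, doc_2x3, kind="standard"), backend)
        assert out.reasoning == "Step 1 held. Step 2 held."

    def test_replay_cassette_reproduces_recordings(self, tmp_path, cdr_schema, doc_2x3, instance):
        cassette = tmp_path / "cassette.json"
        inner = ConstantBackend("Recorded live. My answer is: Yes.")
        q = build_question(instance, cdr_schema)
        prompt = build_prompt(q, doc_2x3, kind="standard")

        recorded = generate_answer(prompt, ReplayBackend(cassette, inner=inner))
        replayed = generate_answer(prompt, ReplayBackend(cassette))  # no inner backend
        assert replayed == recorded

        other = build_prompt(
            build_question(instance, cdr_schema), doc_2x3, kind="zero_shot_cot"
        )
        with pytest.raises(KeyError, match="no recording"):
            generate_answer(other, ReplayBackend(cassette))
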