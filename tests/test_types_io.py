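"""Domain types, corpus dialects, and candidate-pair enumeration."""

import json
import random

import pytest

from litrex import (
    Document,
    Entity,
    EntityMention,
    RelationSchema,
    enumerate_candidate_pairs,
    read_dataset,
    write_dataset,
)
from litrex.io import corpus_instances

from conftest import make_document


class TestTypes:
    def test_schema_rejects_equal_labels(self):
        with pytest.raises(ValueError, match="differ"):
            RelationSchema("x", "A", "B", "same", "q {head} {tail}?", negative_label="same")

    @pytest.mark.parametrize(
        "template", ["no slots", "{head} only", "{tail} {tail} {head}", "{head} {head} {tail}"]
    )
    def test_schema_requires_exactly_one_slot_each(self, template):
        with pytest.raises(ValueError, match="slot"):
            RelationSchema("x", "A", "B", "pos", template)

    def test_mention_span_must_be_forward(self):
        with pytest.raises(ValueError, match="span"):
            EntityMention("x", 5, 5, 0)

    def test_entity_requires_mentions(self):
        with pytest.raises(ValueError, match="no mentions"):
            Entity("e1", "Chemical", ())

    def test_document_rejects_dangling_gold_label(self):
        ent = Entity("c0", "Chemical", (EntityMention("c0", 0, 2, 0),))
        with pytest.raises(ValueError, match="undeclared"):
            Document("d", "t", ("c0 text",), (ent,), frozenset({("c0", "ghost", "1:CID:2")}))

    def test_document_rejects_out_of_range_span(self):
        ent = Entity("c0", "Chemical", (EntityMention("c0", 0, 99, 0),))
        with pytest.raises(ValueError, match="exceeds passage length"):
            Document("d", "t", ("short",), (ent,), frozenset())


class TestCanonicalDialect:
    def test_round_trip_is_field_exact(self, tmp_path, cdr_schema, doc_2x3):
        path = tmp_path / "corpus.json"
        write_dataset([doc_2x3], path)
        docs = read_dataset(path, "canonical", cdr_schema)
        assert docs == [doc_2x3]

    def test_positive_and_negative_label_codes(self, tmp_path, cdr_schema):
        for label, expect in [("1:CID:2", "positive"), ("1:NR:2", "negative")]:
            doc = make_document(positives=[]) if label == "1:NR:2" else make_document(positives=[("c0", "d0")])
            if label == "1:NR:2":
                doc = Document(
                    doc.doc_id, doc.title, doc.passages, doc.entities,
                    frozenset({("c0", "d0", "1:NR:2")}),
                )
            path = tmp_path / "one.json"
            write_dataset([doc], path)
            (read_doc,) = read_dataset(path, "canonical", cdr_schema)
            (inst,) = enumerate_candidate_pairs(read_doc, cdr_schema)
            assert inst.gold == expect

    def test_unknown_label_code_is_named_in_error(self, tmp_path, cdr_schema):
        doc = make_document(positives=[("c0", "d0")])
        path = tmp_path / "bad.json"
        write_dataset([doc], path)
        payload = json.loads(path.read_text())
        payload["documents"][0]["gold_labels"] = [["c0", "d0", "1:BOGUS:2"]]
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="1:BOGUS:2"):
            read_dataset(path, "canonical", cdr_schema)

    def test_malformed_record_names_index_and_field(self, tmp_path, cdr_schema):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"documents": [{"doc_id": "d"}]}))
        with pytest.raises(ValueError, match="record 0: missing field"):
            read_dataset(path, "canonical", cdr_schema)


class TestDocredDialect:
    DOCRED = {
        "title": "doc_a",
        "sents": [
            ["Aspirin", "was", "given", "."],
            ["Severe", "rash", "followed", "aspirin", "use", "."],
        ],
        "vertexSet": [
            [
                {"name": "Aspirin", "sent_id": 0, "pos": [0, 1], "type": "Chemical"},
                {"name": "aspirin", "sent_id": 1, "pos": [3, 4], "type": "Chemical"},
            ],
            [
                {"name": "Severe rash", "sent_id": 1, "pos": [0, 2], "type": "Disease"},
                {"name": "rash", "sent_id": 1, "pos": [1, 2], "type": "Disease"},
            ],
        ],
        "labels": [{"h": 0, "t": 1, "r": "1:CID:2"}],
    }

    def test_hand_converted_record_matches_field_by_field(self, tmp_path, cdr_schema):
        path = tmp_path / "docred.json"
        path.write_text(json.dumps([self.DOCRED]))
        (doc,) = read_dataset(path, "docred_json", cdr_schema)

        assert doc.passages == ("Aspirin was given .", "Severe rash followed aspirin use .")
        assert [len(e.mentions) for e in doc.entities] == [2, 2]
        chem, dis = doc.entities
        # spans computed by hand from the space-joined sentences
        assert chem.mentions[0] == EntityMention("Aspirin", 0, 7, 0)
        assert chem.mentions[1] == EntityMention("aspirin", 21, 28, 1)
        assert dis.mentions[0] == EntityMention("Severe rash", 0, 11, 1)
        assert dis.mentions[1] == EntityMention("rash", 7, 11, 1)
        assert doc.gold_labels == frozenset({("E0", "E1", "1:CID:2")})
        for ent in doc.entities:
            for m in ent.mentions:
                assert doc.passages[m.passage_index][m.start : m.end] == m.surface

    def test_unknown_relation_code_rejected(self, tmp_path, cdr_schema):
        rec = dict(self.DOCRED, labels=[{"h": 0, "t": 1, "r": "bogus"}])
        path = tmp_path / "docred.json"
        path.write_text(json.dumps([rec]))
        with pytest.raises(ValueError, match="bogus"):
            read_dataset(path, "docred_json", cdr_schema)


class TestPairListDialect:
    def test_rows_group_into_documents(self, tmp_path):
        from litrex.templates import default_schema

        ade = default_schema("ade")
        path = tmp_path / "pairs.tsv"
        path.write_text(
            "r1\tibuprofen\tnausea\tDrug-ADE\tPatient on ibuprofen reported nausea.\n"
            "r1\tibuprofen\tdizziness\tDrug-ADE\tLater, ibuprofen use preceded dizziness.\n"
            "r2\twarfarin\tbleeding\tDrug-ADE\tWarfarin-treated patient had bleeding.\n"
        )
        docs = read_dataset(path, "pair_list", ade)
        assert sorted(d.doc_id for d in docs) == ["r1", "r2"]
        (r1,) = [d for d in docs if d.doc_id == "r1"]
        insts = enumerate_candidate_pairs(r1, ade, mode="annotated_only")
        assert len(insts) == 2 and all(i.gold == "positive" for i in insts)

    def test_annotated_only_with_negative_sampling(self, tmp_path):
        from litrex.templates import default_schema

        ade = default_schema("ade")
        path = tmp_path / "pairs.tsv"
        path.write_text(
            "r1\tdrugA\tev1\tDrug-ADE\tdrugA then ev1 and ev2 and ev3.\n"
            "r1\tdrugA\tev2\tDrug-ADE\tdrugA then ev1 and ev2 and ev3.\n"
        )
        (doc,) = read_dataset(path, "pair_list", ade)
        # no unannotated typed pair exists here, so sampling adds nothing
        insts = enumerate_candidate_pairs(
            doc, ade, mode="annotated_only", negative_sampling_ratio=1.0, rng=random.Random(0)
        )
        assert sum(i.gold == "positive" for i in insts) == 2


class TestEnumerate:
    def test_all_pairs_is_cartesian_product(self, cdr_schema, doc_2x3):
        insts = enumerate_candidate_pairs(doc_2x3, cdr_schema, mode="all_pairs")
        assert len(insts) == 6  # 2 chemicals x 3 diseases
        assert {(i.head.entity_id, i.tail.entity_id) for i in insts} == {
            (f"c{h}", f"d{t}") for h in range(2) for t in range(3)
        }

    def test_exactly_the_gold_pair_is_positive(self, cdr_schema, doc_2x3):
        insts = enumerate_candidate_pairs(doc_2x3, cdr_schema)
        positives = [i for i in insts if i.gold == "positive"]
        assert len(positives) == 1
        assert positives[0].key == ("d1", "c0", "d0")

    def test_missing_entity_type_yields_empty(self, cdr_schema):
        doc = make_document(n_chem=0, n_dis=2)
        assert enumerate_candidate_pairs(doc, cdr_schema) == []

    def test_all_pairs_count_law_over_corpus(self, cdr_schema, suite):
        for doc in suite.documents:
            n_h = len(doc.entities_of_type(cdr_schema.head_type))
            n_t = len(doc.entities_of_type(cdr_schema.tail_type))
            assert len(enumerate_candidate_pairs(doc, cdr_schema)) == n_h * n_t
        assert len(corpus_instances(suite.documents, cdr_schema)) == 60
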