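"""Candidate generation, entity masking and position features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdpre import (DEFAULT_SCHEMA, EntityType, RelationLabel, SynthConfig,
                   generate_candidates, generate_corpus, load_instances,
                   mask_entities, position_features, prepare_instances,
                   save_instances)
from sdpre.corpus_io import AnnotatedSentence, EntityMention, IntegrityError
from sdpre.preprocess import masked_sentence, project_graph


class TestCandidates:
    def test_example_yields_two_treatment_problem_pairs(self, example):
        sentence, _ = example
        cands = generate_candidates(sentence)
        pairs = {(m1.surface, m2.surface) for m1, m2, _ in cands}
        assert pairs == {("an epidural", "pain control"), ("pca", "pain control")}
        labels = {(m1.surface, m2.surface): lab for m1, m2, lab in cands}
        assert labels[("an epidural", "pain control")] == RelationLabel.TrAP
        assert labels[("pca", "pain control")] == RelationLabel.NONE

    def test_single_mention_sentence_has_no_candidates(self):
        s = AnnotatedSentence("d", 0, ["fever", "today"], [
            EntityMention("m1", 0, 0, 0, EntityType.PROBLEM, "fever")])
        assert generate_candidates(s) == []

    def test_counts_match_brute_force_type_filter(self, small_corpus):
        sentences, _ = small_corpus
        for s in sentences:
            expected = 0
            for i, m1 in enumerate(s.mentions):
                for m2 in s.mentions[i + 1:]:
                    if DEFAULT_SCHEMA.admissible(m1.entity_type, m2.entity_type) is not None:
                        expected += 1
            assert len(generate_candidates(s)) == expected

    def test_labels_respect_schema(self, small_corpus):
        sentences, _ = small_corpus
        for s in sentences:
            for m1, m2, label in generate_candidates(s):
                admissible = DEFAULT_SCHEMA.admissible(m1.entity_type, m2.entity_type)
                assert label in admissible

    def test_inadmissible_gold_label_is_integrity_error(self):
        mentions = [EntityMention("a", 0, 0, 0, EntityType.PROBLEM, "rash"),
                    EntityMention("b", 0, 2, 2, EntityType.PROBLEM, "fever")]
        s = AnnotatedSentence("d", 0, ["rash", "and", "fever"], mentions,
                              [("a", "b", RelationLabel.TrAP)])
        with pytest.raises(IntegrityError, match="not admissible"):
            generate_candidates(s)


class TestMasking:
    def test_worked_example_masking(self, example):
        sentence, _ = example
        targets = (sentence.mentions[0], sentence.mentions[2])
        masked, e1, e2, _ = mask_entities(sentence, targets)
        assert masked == ["She", "was", "maintained", "on", "tar_treatment",
                          "and", "ent_treatment", "for", "tar_problem"]
        assert (e1, e2) == (4, 8)

    def test_two_token_sentence_all_targets(self):
        mentions = [EntityMention("a", 0, 0, 0, EntityType.TEST, "x"),
                    EntityMention("b", 0, 1, 1, EntityType.PROBLEM, "y")]
        s = AnnotatedSentence("d", 0, ["x", "y"], mentions)
        masked, e1, e2, _ = mask_entities(s, (mentions[0], mentions[1]))
        assert masked == ["tar_test", "tar_problem"]

    def test_length_arithmetic_over_random_sentences(self, small_corpus):
        sentences, _ = small_corpus
        for s in sentences:
            if len(s.mentions) < 2:
                continue
            cands = generate_candidates(s)
            if not cands:
                continue
            m1, m2, _ = cands[0]
            masked, _, _, _ = mask_entities(s, (m1, m2))
            collapsed = sum(m.token_end - m.token_start for m in s.mentions)
            assert len(masked) == len(s.tokens) - collapsed

    def test_masking_is_idempotent(self, small_corpus):
        sentences, _ = small_corpus
        for s in sentences:
            cands = generate_candidates(s)
            if not cands:
                continue
            m1, m2, _ = cands[0]
            once, targets = masked_sentence(s, (m1, m2))
            twice, _ = masked_sentence(once, targets)
            assert once.tokens == twice.tokens

    def test_overlapping_mentions_longer_span_wins(self, caplog):
        mentions = [EntityMention("long", 0, 1, 2, EntityType.PROBLEM, "severe rash"),
                    EntityMention("short", 0, 2, 2, EntityType.PROBLEM, "rash"),
                    EntityMention("t", 0, 4, 4, EntityType.TREATMENT, "cream")]
        s = AnnotatedSentence("d", 0, "a severe rash needs cream".split(), mentions)
        with caplog.at_level("WARNING", logger="sdpre.preprocess"):
            masked, e1, e2, _ = mask_entities(s, (mentions[0], mentions[2]))
        assert masked == ["a", "tar_problem", "needs", "tar_treatment"]
        assert "overlaps" in caplog.text


class TestPositionFeatures:
    def test_worked_example_distances(self, example):
        sentence, _ = example
        targets = (sentence.mentions[0], sentence.mentions[2])
        masked, e1, e2, _ = mask_entities(sentence, targets)
        pos1, pos2 = position_features(masked, e1, e2)
        assert pos1[0] == -4 and pos2[0] == -8  # "She"

    def test_distance_to_self_is_zero_and_difference_constant(self, small_instances):
        for inst in small_instances:
            assert inst.pos1[inst.e1_index] == 0
            assert inst.pos2[inst.e2_index] == 0
            diffs = {a - b for a, b in zip(inst.pos1, inst.pos2)}
            assert diffs == {inst.e2_index - inst.e1_index}

    def test_invalid_target_index_rejected(self):
        with pytest.raises(ValueError):
            position_features(["a", "b"], 0, 5)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(2, 60), st.data())
    def test_distance_identities_hold_for_any_targets(self, n, data):
        e1 = data.draw(st.integers(0, n - 1))
        e2 = data.draw(st.integers(0, n - 1).filter(lambda x: x != e1))
        pos1, pos2 = position_features(["w"] * n, e1, e2)
        assert pos1[e1] == 0 and pos2[e2] == 0
        assert all(a - b == e2 - e1 for a, b in zip(pos1, pos2))
        assert pos1 == sorted(pos1)  # distances increase left to right


class TestPreparedInstances:
    def test_every_instance_has_two_distinct_target_tokens(self, small_instances):
        for inst in small_instances:
            assert inst.e1_index != inst.e2_index
            assert inst.masked_tokens[inst.e1_index].startswith("tar_")
            assert inst.masked_tokens[inst.e2_index].startswith("tar_")

    def test_projected_graphs_remain_trees(self, small_corpus):
        sentences, graphs = small_corpus
        for s, g in zip(sentences, graphs):
            for m1, m2, _ in generate_candidates(s):
                masked, _, _, imap = mask_entities(s, (m1, m2))
                projected = project_graph(g, imap, len(masked))
                assert projected.is_tree()

    def test_sdp_endpoints_are_the_targets(self, small_instances):
        for inst in small_instances:
            if inst.sdp is not None:
                assert inst.sdp.nodes[0] == inst.e1_index
                assert inst.sdp.nodes[-1] == inst.e2_index

    def test_jsonl_round_trip(self, tmp_path, small_instances):
        path = tmp_path / "instances.jsonl"
        save_instances(small_instances, path)
        loaded = load_instances(path)
        assert len(loaded) == len(small_instances)
        for a, b in zip(small_instances, loaded):
            assert a.masked_tokens == b.masked_tokens
            assert (a.e1_index, a.e2_index, a.label) == (b.e1_index, b.e2_index, b.label)
            assert a.pos1 == b.pos1 and a.pos2 == b.pos2
            assert a.sdp == b.sdp

    def test_sentence_only_preparation_has_no_sdp(self, small_corpus):
        sentences, _ = small_corpus
        instances = prepare_instances(sentences, None)
        assert all(i.sdp is None for i in instances)

    def test_live_parser_hook_supplies_graphs(self, small_corpus):
        sentences, graphs = small_corpus
        lookup = {tuple(s.tokens): g for s, g in zip(sentences, graphs)}
        via_hook = prepare_instances(sentences, None,
                                     parser=lambda toks: lookup[tuple(toks)])
        via_list = prepare_instances(sentences, graphs)
        assert [i.sdp for i in via_hook] == [i.sdp for i in via_list]

    def test_graph_sentence_mismatch_is_integrity_error(self, small_corpus):
        sentences, graphs = small_corpus
        with pytest.raises(IntegrityError):
            prepare_instances(sentences, graphs[:-1])
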