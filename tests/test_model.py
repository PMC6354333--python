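"""The dual-branch network: embeddings, convolution, pooling, classifier head."""

import numpy as np
import pytest

from sdpre import (EmbeddingTable, ModelConfig, RelationClassifier, Vocabulary,
                   make_batch, position_bucket, sdp_convolution)
from sdpre._autodiff import softmax
from sdpre.model import LABEL_TO_INDEX


@pytest.fixture()
def tiny_model(tiny_model_config, small_vocab):
    return RelationClassifier(tiny_model_config, small_vocab, seed=1)


class TestEmbedSentence:
    def test_default_token_vector_dimension_is_200(self, small_instances, small_vocab):
        model = RelationClassifier(ModelConfig(), small_vocab, seed=0)
        vecs = model.embed_sentence(small_instances[0])
        assert vecs.shape == (len(small_instances[0].masked_tokens), 200)

    def test_target_token_gets_zero_distance_embedding(self, small_instances, tiny_model):
        inst = small_instances[0]
        vecs = tiny_model.embed_sentence(inst)
        c = tiny_model.config
        zero_row = tiny_model.params["pos1_emb"].value[position_bucket(0, c.max_dist)]
        np.testing.assert_array_equal(
            vecs[inst.e1_index, c.word_dim:c.word_dim + c.position_dim], zero_row)

    def test_changing_pos2_only_changes_last_block(self, small_instances, tiny_model):
        inst = small_instances[0]
        before = tiny_model.embed_sentence(inst)
        shifted = [d + 1 for d in inst.pos2]
        shifted[inst.e2_index] = inst.pos2[inst.e2_index]  # keep the self-distance 0
        inst2 = type(inst)(**{**inst.__dict__, "pos2": shifted})
        after = tiny_model.embed_sentence(inst2)
        c = tiny_model.config
        head = c.word_dim + c.position_dim
        np.testing.assert_array_equal(before[:, :head], after[:, :head])
        assert np.any(before[:, head:] != after[:, head:])

    def test_position_bucket_clips_to_shared_out_of_range_row(self):
        assert position_bucket(0, 60) == 60
        assert position_bucket(-60, 60) == 0
        assert position_bucket(60, 60) == 120
        assert position_bucket(61, 60) == 121
        assert position_bucket(-200, 60) == 121


class TestSdpConvolution:
    def test_identity_transform_concatenates_neighbors(self):
        M = np.eye(2)
        out = sdp_convolution(np.array([[1.0, 0.0], [0.0, 1.0]]), M)
        np.testing.assert_array_equal(out, [[1.0, 0.0, 0.0, 1.0]])

    def test_output_count_is_m_minus_one(self):
        P = np.arange(12.0).reshape(3, 4)  # the two-step example path has m=3
        out = sdp_convolution(P, np.ones((4, 5)))
        assert out.shape == (2, 10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_per_pair_matmul(self, seed):
        rng = np.random.default_rng(seed)
        m, n1, n2 = int(rng.integers(2, 8)), int(rng.integers(2, 7)), int(rng.integers(2, 7))
        P = rng.normal(size=(m, n1))
        M = rng.normal(size=(n1, n2))
        out = sdp_convolution(P, M)
        for i in range(m - 1):
            block = np.stack([P[i], P[i + 1]]) @ M
            np.testing.assert_allclose(out[i], block.flatten(), atol=1e-6)

    def test_single_word_path_rejected(self):
        with pytest.raises(ValueError, match="length"):
            sdp_convolution(np.ones((1, 4)), np.ones((4, 2)))


class TestClassifierHead:
    def test_zero_logit_head_gives_uniform_ninth(self, tiny_model):
        tiny_model.params["out_W"].value[:] = 0.0
        tiny_model.params["out_b"].value[:] = 0.0
        h = 2 * tiny_model.config.hidden
        probs = tiny_model.classify(np.ones(h), np.ones(h))
        np.testing.assert_allclose(probs, np.full(9, 1 / 9), atol=1e-12)

    def test_probabilities_form_a_distribution(self, tiny_model, small_instances):
        probs = tiny_model.predict_proba(small_instances[:20])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_softmax_shift_invariance(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(8, 9))
        np.testing.assert_allclose(softmax(logits), softmax(logits + 123.4), atol=1e-12)


class TestAblationFlags:
    def test_sentence_only_is_bit_independent_of_sdp_inputs(self, small_vocab,
                                                            small_instances):
        cfg = ModelConfig(word_dim=8, position_dim=4, deprel_dim=4, hidden=6,
                          dropout_rate=0.0, use_sdp_words=False,
                          use_sdp_relations=False)
        model = RelationClassifier(cfg, small_vocab, seed=2)
        batch = make_batch(small_instances[:8], small_vocab, cfg)
        ref = model.forward(batch).value
        rng = np.random.default_rng(0)
        batch["sdp_words"] = rng.integers(0, 5, size=batch["sdp_words"].shape)
        batch["deprels"] = rng.integers(0, 2, size=batch["deprels"].shape)
        batch["has_sdp"] = 1.0 - batch["has_sdp"]
        np.testing.assert_array_equal(model.forward(batch).value, ref)

    def test_without_relation_channel_output_ignores_deprels(self, small_vocab,
                                                             small_instances):
        cfg = ModelConfig(word_dim=8, position_dim=4, deprel_dim=4, hidden=6,
                          dropout_rate=0.0, use_sdp_relations=False)
        model = RelationClassifier(cfg, small_vocab, seed=2)
        batch = make_batch(small_instances[:8], small_vocab, cfg)
        ref = model.forward(batch).value
        batch["deprels"] = np.zeros_like(batch["deprels"])
        np.testing.assert_array_equal(model.forward(batch).value, ref)

    def test_relations_without_words_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(use_sdp_words=False, use_sdp_relations=True)

    def test_unknown_deprel_label_maps_to_unk(self, small_vocab):
        for label in ("xcomp:weird", "", "made-up-rel"):
            assert small_vocab.deprel_index(label) == small_vocab.deprels["<unk>"]


class TestEncoder:
    def test_single_token_sentence_pooled_equals_only_state(self, small_vocab,
                                                            tiny_model_config):
        model = RelationClassifier(tiny_model_config, small_vocab, seed=3)
        import sdpre._autodiff as ad
        rng = np.random.default_rng(0)
        x = [ad.Tensor(rng.normal(size=(1, tiny_model_config.word_dim
                                        + 2 * tiny_model_config.position_dim)))]
        mask = np.ones((1, 1))
        pooled = model._bilstm(x, mask, "sent")
        hf, _ = model._lstm_pass(x, mask, "sent_f", reverse=False)
        hb, _ = model._lstm_pass(x, mask, "sent_b", reverse=True)
        expected = np.concatenate([hf[0].value, hb[0].value], axis=1)
        np.testing.assert_allclose(pooled.value, expected, atol=1e-12)

    def test_bilstm_output_dimension_doubles_hidden(self, small_vocab, small_instances):
        cfg = ModelConfig(word_dim=8, position_dim=4, deprel_dim=4, hidden=200,
                          dropout_rate=0.0)
        model = RelationClassifier(cfg, small_vocab, seed=0)
        batch = make_batch(small_instances[:2], small_vocab, cfg)
        assert model._encode_sentence(batch).value.shape == (2, 400)

    def test_reversed_input_swaps_forward_backward_states(self, small_vocab,
                                                          tiny_model_config):
        model = RelationClassifier(tiny_model_config, small_vocab, seed=4)
        for part in ("Wx", "Wh", "b"):  # tie the two directions
            model.params[f"sent_b_{part}"].value = model.params[f"sent_f_{part}"].value.copy()
        import sdpre._autodiff as ad
        rng = np.random.default_rng(1)
        T = 5
        dim = tiny_model_config.word_dim + 2 * tiny_model_config.position_dim
        xs = [ad.Tensor(rng.normal(size=(1, dim))) for _ in range(T)]
        mask = np.ones((1, T))
        hf, _ = model._lstm_pass(xs, mask, "sent_f", reverse=False)
        hb_rev, _ = model._lstm_pass(xs[::-1], mask, "sent_b", reverse=True)
        for t in range(T):
            np.testing.assert_allclose(hf[t].value, hb_rev[T - 1 - t].value, atol=1e-12)

    def test_pooled_encoding_invariant_to_padding(self, small_vocab, small_instances,
                                                  tiny_model_config):
        model = RelationClassifier(tiny_model_config, small_vocab, seed=5)
        by_len = sorted(small_instances, key=lambda i: len(i.masked_tokens))
        short, long = by_len[0], by_len[-1]
        assert len(short.masked_tokens) < len(long.masked_tokens)
        alone = model.forward(make_batch([short], small_vocab, tiny_model_config)).value
        padded = model.forward(make_batch([short, long], small_vocab,
                                          tiny_model_config)).value
        np.testing.assert_allclose(padded[0], alone[0], atol=1e-10)


class TestParameters:
    def test_parameter_count_matches_closed_form(self, small_vocab, small_instances):
        cfg = ModelConfig(word_dim=8, position_dim=4, deprel_dim=4, hidden=6,
                          dropout_rate=0.0)
        model = RelationClassifier(cfg, small_vocab, seed=0)
        V, R = len(small_vocab.words), len(small_vocab.deprels)
        H, P = cfg.hidden, cfg.n_position_buckets
        sent_in = cfg.word_dim + 2 * cfg.position_dim
        sdp_in = 2 * H + cfg.deprel_dim
        lstm = lambda d: d * 4 * H + H * 4 * H + 4 * H
        expected = (V * cfg.word_dim + 2 * P * cfg.position_dim + R * cfg.deprel_dim
                    + 2 * lstm(sent_in) + 2 * lstm(sdp_in)
                    + cfg.word_dim * H + 2 * H  # conv transform + no-path vector
                    + 4 * H * cfg.fc_size + cfg.fc_size
                    + cfg.fc_size * 9 + 9)
        assert model.parameter_count() == expected

    def test_pretrained_vectors_are_copied_into_the_word_table(self, small_instances,
                                                               small_vocab):
        cfg = ModelConfig(word_dim=3, position_dim=2, deprel_dim=2, hidden=4,
                          dropout_rate=0.0)
        token = small_instances[0].masked_tokens[0]
        table = EmbeddingTable(vocabulary={token: 0},
                               vectors=np.array([[9.0, 8.0, 7.0]]), dimension=3)
        model = RelationClassifier(cfg, small_vocab, seed=0, pretrained=table)
        row = model.params["word_emb"].value[small_vocab.word_index(token)]
        np.testing.assert_array_equal(row, [9.0, 8.0, 7.0])

    def test_checkpoint_round_trip_preserves_predictions(self, tmp_path, tiny_model,
                                                         small_instances):
        path = tmp_path / "model.npz"
        tiny_model.save(str(path))
        reloaded = RelationClassifier.load(str(path))
        a = tiny_model.predict_proba(small_instances[:10])
        b = reloaded.predict_proba(small_instances[:10])
        np.testing.assert_array_equal(a, b)

    def test_label_indexing_covers_all_nine_classes(self):
        assert len(LABEL_TO_INDEX) == 9
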