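"""Multitask model: feedback wiring, prediction contracts, persistence."""

import numpy as np
import pytest

from drugner.config import RunConfig
from drugner.corpus import bio_violations
from drugner.model import MultitaskModel
from drugner.nn.core import Parameter
from drugner.pipeline import build_model
from drugner.synthetic import correlated_spec, generate_corpus


@pytest.fixture(scope="module")
def corpus():
    return generate_corpus(correlated_spec(n_sentences=30, seed=8))


@pytest.fixture
def model_and_corpus(corpus, tiny_config):
    return build_model(corpus, tiny_config)


class TestFeedbackInput:
    def test_zero_feedback_is_duplicated_representation(self, model_and_corpus, rng):
        model, _ = model_and_corpus
        v = rng.normal(size=(4, model.encoder.output_dim))
        y = np.zeros((4, model.k_nen))
        out, _ = model.feedback_input(v, y, model.U)
        np.testing.assert_array_equal(out, np.concatenate([v, v], axis=1))

    def test_none_feedback_keeps_width_contract(self, model_and_corpus, rng):
        model, _ = model_and_corpus
        v = rng.normal(size=(3, model.encoder.output_dim))
        out, _ = model.feedback_input(v, None, model.U)
        assert out.shape == (3, 2 * model.encoder.output_dim)

    def test_one_hot_with_basis_row_adds_that_row(self, model_and_corpus, rng):
        model, _ = model_and_corpus
        width = model.encoder.output_dim
        v = rng.normal(size=(2, width))
        M = Parameter("M", np.zeros((model.k_nen, width)))
        M.value[3] = np.arange(width, dtype=float)
        y = np.zeros((2, model.k_nen))
        y[:, 3] = 1.0
        out, _ = model.feedback_input(v, y, M)
        np.testing.assert_allclose(out[:, width:], v + M.value[3])
        np.testing.assert_allclose(out[:, :width], v)

    def test_matches_explicit_computation(self, model_and_corpus, rng):
        model, _ = model_and_corpus
        width = model.encoder.output_dim
        v = rng.normal(size=(5, width))
        y = rng.normal(size=(5, model.k_nen))
        M = Parameter("M", rng.normal(size=(model.k_nen, width)))
        out, _ = model.feedback_input(v, y, M)
        np.testing.assert_allclose(out, np.concatenate([v, v + y @ M.value], axis=1), atol=1e-12)

    def test_width_mismatch_rejected(self, model_and_corpus, rng):
        model, _ = model_and_corpus
        v = rng.normal(size=(2, model.encoder.output_dim))
        with pytest.raises(ValueError, match="width"):
            model.feedback_input(v, rng.normal(size=(2, model.k_nen + 1)), model.U)


class TestPrediction:
    def test_untrained_output_is_legal_and_aligned(self, model_and_corpus):
        model, encoded = model_and_corpus
        for sentence in list(encoded)[:5]:
            pred = model.predict(sentence)
            assert len(pred.ner_labels) == len(sentence)
            assert len(pred.norm_labels) == len(sentence)
            assert not bio_violations(pred.ner_labels)
            assert all(l in model.norm_labels for l in pred.norm_labels)

    def test_prediction_deterministic(self, model_and_corpus):
        model, encoded = model_and_corpus
        s = list(encoded)[0]
        a = model.predict(s)
        b = model.predict(s)
        assert a.ner_labels == b.ner_labels and a.norm_labels == b.norm_labels

    def test_channel_order_fixed_regardless_of_declaration(self, corpus):
        cfg1 = RunConfig(task="dner", feedback=False, state_size=6, word_dim=8,
                         char_dim=4, num_filters=5, channels=("word", "char"), seed=1)
        cfg2 = RunConfig(task="dner", feedback=False, state_size=6, word_dim=8,
                         char_dim=4, num_filters=5, channels=("char", "word"), seed=1)
        m1, enc = build_model(corpus, cfg1)
        m2, _ = build_model(corpus, cfg2)
        s = list(enc)[0]
        v1, _ = m1.encode(s)
        v2, _ = m2.encode(s)
        np.testing.assert_array_equal(v1, v2)  # concat order is canonical

    def test_full_width_1154_concatenation(self, corpus):
        cfg = RunConfig(task="multitask", state_size=4, word_dim=100, char_dim=30,
                        num_filters=30, elmo_dim=1024, channels=("word", "char", "elmo"),
                        seed=0)
        model, enc = build_model(corpus, cfg)
        assert model.encoder.fwd.input_dim == 100 + 30 + 1024


class TestCheckpoint:
    def test_save_load_reproduces_predictions_exactly(self, corpus, tiny_config, tmp_path):
        model, encoded = build_model(corpus, tiny_config)
        path = str(tmp_path / "model.json")
        model.save(path)
        clone = MultitaskModel.load(path)
        for sentence in list(encoded)[:5]:
            a = model.predict(sentence)
            b = clone.predict(sentence)
            assert a.ner_labels == b.ner_labels
            assert a.norm_labels == b.norm_labels

    def test_unknown_format_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError, match="format"):
            MultitaskModel.load(str(path))


def test_config_validation_errors():
    with pytest.raises(ValueError, match="feedback"):
        RunConfig(task="dner", feedback=True)
    with pytest.raises(ValueError, match="channel"):
        RunConfig(channels=())
    with pytest.raises(ValueError, match="invalid config keys"):
        RunConfig.from_dict({"learning_rate_typo": 1.0})


def test_defaults_mirror_hyperparameter_table():
    cfg = RunConfig()
    assert (cfg.window_size, cfg.num_filters) == (3, 30)
    assert (cfg.state_size, cfg.dropout_rate, cfg.batch_size) == (200, 0.5, 10)
    assert (cfg.initial_lr, cfg.gradient_clip, cfg.decay_rate) == (0.015, 5.0, 0.05)
    assert cfg.labeling_schema == "BIO" and cfg.elmo_dim == 1024
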