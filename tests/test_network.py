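import numpy as np
import pytest

from semgnet.cbam import CBAM1d
from semgnet.network import (
    ABLATION_LABELS,
    ModelConfig,
    TrainOptions,
    ablation_config,
    build_model,
    classify_scores,
    evaluate_confusion,
    load_checkpoint,
    run_ablation,
    save_checkpoint,
    train_model,
)
from semgnet.nn import cross_entropy
from .conftest import stratified_subset

SMALL = ModelConfig(
    n_semg_streams=6, use_acc=False, n_classes=5, window_samples=200,
    conv_blocks=((8, 3, 2),), pool_factors=(5,), gru_hidden=16, fc_dim=32,
    cbam_r=4, dropout_p=0.3,
)


# ---- softmax / decision contracts -------------------------------------------


class TestClassScores:
    def test_uniform_for_equal_logits(self):
        scores = classify_scores(np.zeros(3))
        np.testing.assert_allclose(scores.p, 1 / 3)
        assert scores.p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_argmax_decision(self):
        scores = classify_scores(np.array([0.1, 2.5, 0.3]))
        assert scores.m0 == 2

    def test_probabilities_normalize_and_positive(self, rng):
        for _ in range(20):
            scores = classify_scores(rng.standard_normal(8) * 5)
            assert scores.p.sum() == pytest.approx(1.0, abs=1e-6)
            assert np.all(scores.p > 0)

    def test_shift_invariance(self, rng):
        g = rng.standard_normal(6)
        np.testing.assert_allclose(
            classify_scores(g).p, classify_scores(g + 17.3).p, rtol=1e-9
        )

    def test_tie_break_lowest_index(self):
        assert classify_scores(np.array([1.0, 1.0, 0.0])).m0 == 1


# ---- structure ---------------------------------------------------------------


class TestStructure:
    def test_ablation_topologies_differ_only_in_stated_components(self):
        names = {
            e: {n for n, _ in build_model(ablation_config(e, SMALL)).named_parameters()}
            for e in range(1, 6)
        }
        def only(prefixes, diff):
            return all(any(p in n for p in prefixes) for n in diff)

        assert only(("bns.",), names[2] - names[1]) and names[1] <= names[2]
        assert only(("gru.",), names[3] - names[2]) and names[2] <= names[3]
        assert only(("cbams.",), names[4] - names[2]) and names[2] <= names[4]
        assert names[5] == names[3] | names[4]

    def test_parameter_count_closed_form(self):
        cfg = ModelConfig(
            n_semg_streams=2, use_acc=False, n_classes=3, window_samples=40,
            conv_blocks=((8, 3, 1),), pool_factors=(4,), gru_hidden=6,
            fc_dim=10, cbam_r=4,
        )
        model = build_model(cfg)
        conv = 8 * 1 * 3 + 8
        bn = 2 * 8
        cbam = 2 * 8 * 8 // 4 + 7
        gru = 3 * (8 * 6 + 6 * 6 + 6)
        per_stream = conv + bn + cbam + gru
        head = (2 * 6) * 10 + 10 + 10 * 3 + 3
        assert model.n_parameters() == 2 * per_stream + head

    def test_forward_on_zeros_is_finite(self):
        model = build_model(SMALL).eval()
        logits = model.forward(np.zeros((2, 6, 200)))
        assert np.all(np.isfinite(logits.data))

    def test_eval_forward_deterministic(self, rng):
        model = build_model(SMALL).eval()
        x = rng.standard_normal((3, 6, 200))
        a = model.forward(x).data
        b = model.forward(x).data
        np.testing.assert_array_equal(a, b)

    def test_wrong_stream_count_rejected(self, rng):
        model = build_model(SMALL)
        with pytest.raises(ValueError):
            model.forward(rng.standard_normal((2, 4, 200)))

    def test_empty_aggregate_rejected(self):
        model = build_model(SMALL)
        with pytest.raises(ValueError):
            model.aggregate_and_classify([])

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(n_classes=1).validate()
        with pytest.raises(ValueError):
            ModelConfig(conv_blocks=((32, 4, 1),), pool_factors=(5,)).validate()
        with pytest.raises(ValueError):
            ModelConfig(window_samples=10).validate()  # pools eat the window

    def test_full_replication_config(self):
        """The full-scale configuration: 52-way head over 6 sEMG + 1 ACC."""
        cfg = ModelConfig()
        model = build_model(cfg)
        assert cfg.n_classes == 52
        assert len(model.streams) == 6
        assert model.acc_stream is not None
        assert model.head.weight.shape[1] == 52


# ---- attention-identity and ACC-fusion equivalences --------------------------


def _forced_identity_cbam(channels, r, rng):
    m = CBAM1d(channels, r, rng, mlp_bias=True)
    for t in (m.w0, m.w1, m.b0, m.t_kernel):
        t.data[...] = 0.0
    m.b1.data[...] = 50.0
    m.t_bias.data[...] = 50.0
    return m


class TestEquivalences:
    def test_disabled_cbam_equals_attention_forced_to_one(self, rng):
        cfg_on = ablation_config(5, SMALL)
        cfg_off = ablation_config(3, SMALL)
        m_on, m_off = build_model(cfg_on), build_model(cfg_off)
        shared = dict(m_off.named_parameters())
        for name, p in m_on.named_parameters():
            if "cbams." not in name:
                p.data[...] = shared[name].data
        frc = np.random.default_rng(0)
        for stream in m_on.streams:
            stream.cbams = [
                _forced_identity_cbam(c.channels, c.r, frc) for c in stream.cbams
            ]
        x = rng.standard_normal((3, 6, 200))
        m_on.eval(), m_off.eval()
        np.testing.assert_allclose(
            m_on.forward(x).data, m_off.forward(x).data, atol=1e-3
        )

    def test_zeroed_acc_branch_matches_semg_only_model(self, rng):
        cfg_acc = ModelConfig(
            n_semg_streams=3, use_acc=True, n_classes=4, window_samples=100,
            conv_blocks=((8, 3, 2),), pool_factors=(5,), gru_hidden=8,
            fc_dim=16, cbam_r=4, seed=3,
        )
        m_acc = build_model(cfg_acc).eval()
        for _, p in m_acc.acc_stream.named_parameters():
            p.data[...] = 0.0
        x = rng.standard_normal((2, 3, 100))
        out_zero = m_acc.forward(x, np.zeros((2, 3, 100))).data
        out_rand = m_acc.forward(x, rng.standard_normal((2, 3, 100)) * 9).data
        np.testing.assert_allclose(out_zero, out_rand, atol=1e-12)

        # an sEMG-only model carrying the same sEMG/head weights agrees
        m_semg = build_model(
            type(cfg_acc)(**{**vars(cfg_acc), "use_acc": False})
        ).eval()
        acc_params = dict(m_acc.named_parameters())
        semg_dim = cfg_acc.stream_out_dim * cfg_acc.n_semg_streams
        for name, p in m_semg.named_parameters():
            if name == "fc.weight":
                p.data[...] = acc_params[name].data[:semg_dim]
            elif "acc_stream" not in name:
                p.data[...] = acc_params[name].data
        np.testing.assert_allclose(m_semg.forward(x).data, out_zero, atol=1e-12)


# ---- training ----------------------------------------------------------------


@pytest.fixture(scope="module")
def tiny_trained(easy_window_data):
    """A small model overfit on 4 windows per class (20 total)."""
    tr = easy_window_data["train"]
    idx = stratified_subset(tr.y, 4)
    cfg = ModelConfig(
        n_semg_streams=6, use_acc=False, n_classes=5, window_samples=200,
        conv_blocks=((8, 3, 2),), pool_factors=(5,), gru_hidden=8, fc_dim=32,
        cbam_r=4, dropout_p=0.0, seed=1,
    )
    model = build_model(cfg)
    history = train_model(
        model, tr.x_semg[idx], tr.y[idx],
        opts=TrainOptions(epochs=30, lr=5e-3, batch_size=20, seed=1),
    )
    return model, history, tr.x_semg[idx], tr.y[idx]


class TestTraining:
    def test_loss_decreases_from_initialization(self, easy_window_data):
        tr = easy_window_data["train"]
        idx = stratified_subset(tr.y, 8)
        model = build_model(SMALL)
        model.eval()
        init_loss = float(
            cross_entropy(model.forward(tr.x_semg[idx]), tr.y[idx] - 1).data
        )
        history = train_model(
            model, tr.x_semg[idx], tr.y[idx],
            opts=TrainOptions(epochs=1, batch_size=32, seed=0),
        )
        assert history.loss[0] < init_loss

    def test_overfits_memorizable_windows(self, tiny_trained):
        model, history, x, y = tiny_trained
        acc, _ = evaluate_confusion(model, x, y)
        assert acc == 1.0

    def test_history_records_epochs(self, tiny_trained):
        _, history, _, _ = tiny_trained
        frame = history.to_frame()
        assert list(frame.columns[:3]) == ["epoch", "loss", "train_acc"]
        assert len(frame) == 30

    def test_missing_class_rejected(self, easy_window_data):
        tr = easy_window_data["train"]
        sel = tr.y != 5
        model = build_model(SMALL)
        with pytest.raises(ValueError, match="absent"):
            train_model(model, tr.x_semg[sel], tr.y[sel],
                        opts=TrainOptions(epochs=1))

    def test_seeded_training_reproducible(self, easy_window_data):
        tr = easy_window_data["train"]
        idx = stratified_subset(tr.y, 4)
        final = []
        for _ in range(2):
            model = build_model(SMALL)
            train_model(model, tr.x_semg[idx], tr.y[idx],
                        opts=TrainOptions(epochs=1, seed=5))
            final.append(model.state_dict())
        for key in final[0]:
            np.testing.assert_array_equal(final[0][key], final[1][key])


class TestEvaluation:
    def test_perfect_predictor_identity_confusion(self, tiny_trained):
        model, _, x, y = tiny_trained
        acc, confusion = evaluate_confusion(model, x, y)
        assert acc == 1.0
        assert np.all(confusion == np.diag(np.diag(confusion)))

    def test_row_sums_equal_class_counts(self, tiny_trained, easy_window_data):
        model, _, _, _ = tiny_trained
        te = easy_window_data["test"]
        _, confusion = evaluate_confusion(model, te.x_semg, te.y)
        np.testing.assert_array_equal(
            confusion.sum(axis=1), np.bincount(te.y - 1, minlength=5)
        )
        assert confusion.sum() == len(te.y)

    def test_accuracy_equals_mean_correctness(self, tiny_trained, easy_window_data):
        model, _, _, _ = tiny_trained
        te = easy_window_data["test"]
        acc, _ = evaluate_confusion(model, te.x_semg, te.y)
        pred = model.predict(te.x_semg)
        assert acc == pytest.approx(float(np.mean(pred == te.y)))


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tiny_trained, tmp_path):
        model, _, x, _ = tiny_trained
        save_checkpoint(model, tmp_path / "m.npz")
        back = load_checkpoint(tmp_path / "m.npz")
        np.testing.assert_array_equal(back.forward(x).data, model.forward(x).data)
        assert back.cfg == model.cfg


# ---- ablation ----------------------------------------------------------------


class TestAblation:
    def test_table_shape_and_order(self, easy_window_data):
        tr, te = easy_window_data["train"], easy_window_data["test"]
        idx = stratified_subset(tr.y, 6)
        table = run_ablation(
            tr.x_semg[idx], tr.y[idx], te.x_semg[:40], te.y[:40], SMALL,
            seeds=(0,), opts=TrainOptions(epochs=1, batch_size=32),
        )
        assert list(table["method"]) == list(ABLATION_LABELS)
        assert len(table) == 5

    def test_full_model_beats_bare_convolution_when_data_is_scarce(
        self, easy_window_data
    ):
        """Seed-averaged directional ordering of the ablation end points."""
        tr, te = easy_window_data["train"], easy_window_data["test"]
        idx = stratified_subset(tr.y, 30)
        table = run_ablation(
            tr.x_semg[idx], tr.y[idx], te.x_semg, te.y, SMALL,
            seeds=(0, 1, 2, 3, 4), opts=TrainOptions(epochs=2, batch_size=32),
        )
        acc = table.set_index("experiment")["accuracy"]
        assert acc[5] >= acc[1]

    def test_all_variants_clear_three_times_chance(self, easy_window_data):
        tr, te = easy_window_data["train"], easy_window_data["test"]
        idx = stratified_subset(tr.y, 60)
        table = run_ablation(
            tr.x_semg[idx], tr.y[idx], te.x_semg, te.y, SMALL,
            seeds=(0, 1, 2, 3, 4), opts=TrainOptions(epochs=4, batch_size=32),
        )
        chance = 1.0 / 5
        assert np.all(table["accuracy"] >= 3 * chance)
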