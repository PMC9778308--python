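import numpy as np
import pytest

from eegfst.features import Sample4D
from eegfst.model import (
    CNNConfig,
    FSTception,
    HeadParams,
    ONLSTMParams,
    classify,
    cnn_forward,
    conv_param_count,
    count_parameters,
    onlstm_gates,
    onlstm_param_count,
    onlstm_sequence,
    onlstm_step,
)


@pytest.fixture(scope="module")
def reduced_model():
    return FSTception(cnn=CNNConfig.reduced(), hidden=32, n_classes=2, seed=3)


class TestCNN:
    def test_output_shape_512_by_2t(self):
        model = FSTception(cnn=CNNConfig(), hidden=8, n_classes=2, seed=0)
        sample = Sample4D(
            tensor=np.random.default_rng(0).standard_normal((8, 9, 5, 6)), label=0
        )
        q = cnn_forward(sample, model)
        assert q.shape == (512, 6)

    def test_weight_sharing_across_slices(self, reduced_model, rng):
        x = rng.standard_normal((8, 9, 5, 6))
        x[..., 3] = x[..., 0]  # duplicate slice 0 at position 3
        q = cnn_forward(Sample4D(tensor=x, label=0), reduced_model)
        np.testing.assert_array_equal(q[:, 0], q[:, 3])

    def test_finite_output_on_finite_input(self, reduced_model, rng):
        q = cnn_forward(Sample4D(tensor=rng.standard_normal((8, 9, 5, 6)) * 50, label=0),
                        reduced_model)
        assert np.all(np.isfinite(q))

    def test_shape_mismatch_rejected(self, reduced_model, rng):
        with pytest.raises(ValueError, match="expects"):
            cnn_forward(Sample4D(tensor=rng.standard_normal((4, 9, 5, 6)), label=0),
                        reduced_model)


class TestONLSTMStep:
    def test_zero_everything_gives_zero_state(self):
        p = ONLSTMParams(input_size=8, hidden=4)
        h, c = onlstm_step(np.zeros(8), np.zeros(4), np.zeros(4), p)
        np.testing.assert_array_equal(h, np.zeros(4))
        np.testing.assert_array_equal(c, np.zeros(4))

    def test_master_gates_at_zero_weights_are_uniform_cumsums(self):
        p = ONLSTMParams(input_size=3, hidden=4)
        g = onlstm_gates(np.zeros(3), np.zeros(4), np.zeros(4), p)
        np.testing.assert_allclose(g["mf"], [0.25, 0.5, 0.75, 1.0], atol=1e-6)
        np.testing.assert_allclose(g["mi"], [1.0, 0.75, 0.5, 0.25], atol=1e-6)
        np.testing.assert_allclose(g["w"], [0.25, 0.375, 0.375, 0.25], atol=1e-6)

    def test_master_gate_monotonicity_and_range(self):
        rng = np.random.default_rng(0)
        p = ONLSTMParams.init(16, hidden=8, rng=rng)
        for _ in range(200):
            g = onlstm_gates(
                rng.standard_normal(16), rng.standard_normal(8) * 0.5,
                rng.standard_normal(8), p,
            )
            mf, mi, w = g["mf"], g["mi"], g["w"]
            assert np.all(np.diff(mf) >= -1e-6) and np.all(np.diff(mi) <= 1e-6)
            assert np.all((mf >= -1e-6) & (mf <= 1 + 1e-6))
            assert np.all((mi >= -1e-6) & (mi <= 1 + 1e-6))
            assert mf[-1] == pytest.approx(1.0, abs=1e-5)
            assert mi[0] == pytest.approx(1.0, abs=1e-5)
            assert np.all(w <= np.minimum(mf, mi) + 1e-6)

    def test_non_finite_input_rejected(self):
        p = ONLSTMParams(input_size=4, hidden=4)
        with pytest.raises(ValueError, match="finite"):
            onlstm_step(np.full(4, np.nan), np.zeros(4), np.zeros(4), p)

    def test_canonical_variant_clamped_reduces_to_standard_lstm(self):
        from scipy.special import expit

        rng = np.random.default_rng(5)
        p = ONLSTMParams.init(6, hidden=5, variant="canonical", rng=rng)
        q = rng.standard_normal(6)
        h0 = rng.standard_normal(5) * 0.3
        c0 = rng.standard_normal(5)
        _, c1 = onlstm_step(q, h0, c0, p, clamp_master=True)
        # standard LSTM cell update computed from the same gate weights
        q32, h32, c32 = (v.astype(np.float32) for v in (q, h0, c0))
        pre = lambda g: q32 @ p.W[g].data + h32 @ p.U[g].data + p.b[g].data
        f, i = expit(pre("f")), expit(pre("i"))
        chat = np.tanh(pre("c"))
        np.testing.assert_allclose(c1, f * c32 + i * chat, atol=1e-5)

    def test_chunked_master_gates_repeat_blocks(self):
        rng = np.random.default_rng(2)
        p = ONLSTMParams.init(4, hidden=6, chunk=2, rng=rng)
        g = onlstm_gates(rng.standard_normal(4), np.zeros(6), np.zeros(6), p)
        mf = g["mf"]
        assert mf.shape == (6,)
        np.testing.assert_allclose(mf[0::2], mf[1::2], atol=1e-6)


class TestONLSTMSequence:
    def test_output_dimension(self):
        rng = np.random.default_rng(0)
        p = ONLSTMParams.init(512, hidden=128, rng=rng)
        y = onlstm_sequence(rng.standard_normal((512, 6)), p)
        assert y.shape == (128,)

    def test_length_one_equals_single_step(self):
        rng = np.random.default_rng(1)
        p = ONLSTMParams.init(8, hidden=4, rng=rng)
        q = rng.standard_normal((8, 1))
        y = onlstm_sequence(q, p)
        h, _ = onlstm_step(q[:, 0], np.zeros(4), np.zeros(4), p)
        np.testing.assert_allclose(y, h, atol=1e-7)

    def test_temporal_order_matters(self):
        rng = np.random.default_rng(2)
        p = ONLSTMParams.init(8, hidden=4, rng=rng)
        q = rng.standard_normal((8, 5))
        assert np.abs(onlstm_sequence(q, p) - onlstm_sequence(q[:, ::-1], p)).max() > 0

    def test_empty_sequence_rejected(self):
        p = ONLSTMParams(input_size=8, hidden=4)
        with pytest.raises(ValueError):
            onlstm_sequence(np.zeros((8, 0)), p)


class TestClassify:
    def test_zero_head_is_uniform(self):
        head = HeadParams(hidden=4, n_classes=3)
        np.testing.assert_allclose(classify(np.ones(4), head), np.full(3, 1 / 3), atol=1e-7)

    def test_two_logit_softmax_value(self):
        head = HeadParams(hidden=2, n_classes=2)
        head.A.data[:] = np.eye(2, dtype=np.float32)
        probs = classify(np.array([1.0, 0.0]), head)
        np.testing.assert_allclose(probs, [np.e / (1 + np.e), 1 / (1 + np.e)], atol=1e-6)

    def test_probabilities_normalized_and_open_interval(self, rng):
        head = HeadParams.init(16, 4, rng)
        for _ in range(50):
            p = classify(rng.standard_normal(16) * 3, head)
            assert p.sum() == pytest.approx(1.0, abs=1e-6)
            assert np.all((p > 0) & (p < 1))


class TestParameterCounting:
    def test_pointwise_conv_count(self):
        assert conv_param_count(1, 64, 1) == 128

    def test_onlstm_six_gate_count(self):
        assert onlstm_param_count(3, 4) == 6 * (3 * 4 + 4 * 4 + 4)

    def test_doubling_dense_units_doubles_dense_weights(self):
        cfg1, cfg2 = CNNConfig(dense_units=512), CNNConfig(dense_units=1024)
        base = CNNConfig()
        d1 = cfg1.flat_features * 512 + 512
        d2 = cfg2.flat_features * 1024 + 1024
        assert d2 == 2 * d1

    def test_analytic_count_matches_actual_model(self):
        cfg = CNNConfig.reduced()
        model = FSTception(cnn=cfg, hidden=64, n_classes=3, seed=0)
        analytic, flops = count_parameters(cfg, model.onlstm, model.head)
        assert analytic == model.n_parameters
        assert flops > 0


class TestTraining:
    def test_one_adam_step_reduces_loss_majority_of_seeds(self):
        from eegfst.nn import Adam, softmax_cross_entropy

        cfg = CNNConfig(
            conv1_filters=4, conv2_filters=4, pointwise_filters=8, dense_units=16,
        )
        rng = np.random.default_rng(0)
        x = rng.standard_normal((24, 8, 9, 5, 2)).astype(np.float32)
        y = (x[:, 0, 3, 0, :].mean(axis=-1) > 0).astype(int)
        wins = 0
        for seed in range(10):
            model = FSTception(cnn=cfg, hidden=8, n_classes=2, seed=seed)
            opt = Adam(model.parameters(), lr=1e-3)
            model.train()
            l0 = softmax_cross_entropy(model.forward(x), y)
            l0.backward()
            opt.step()
            opt.zero_grad()
            l1 = softmax_cross_entropy(model.forward(x), y)
            wins += float(l1.data) < float(l0.data)
        assert wins >= 6
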