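"""Per-sample gradient engine: replica contract, oracle equivalence,
clipping and noise calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

import privgrad as pg
from privgrad import nn
from privgrad.engine import EngineError
from conftest import ce_loss, random_cnn


def _linear_model(weights):
    m = nn.Sequential(nn.Linear(len(weights), 1))
    m.layers[0].params["weight"][...] = np.asarray(weights)[None, :]
    m.layers[0].params["bias"][...] = 0.0
    return m


def sq_loss(targets):
    """Per-sample squared error 0.5*(out - y)^2 on a 1-d output."""
    def loss_fn(out, within):
        d = out[:, 0] - targets[within]
        return 0.5 * d**2, d[:, None]
    return loss_fn


class TestWrap:
    def test_replicas_alias_one_parameter_store(self):
        model = random_cnn(0)
        before = {name: p for name, p in model.named_parameters()}
        w = pg.wrap(model, 4)
        assert len(w.replicas) == 4
        for rep in w.replicas:
            for name, p in rep.params.items():
                assert p is before[name]  # same ndarray object: zero-copy
        # parameter memory unchanged: unique buffers only
        nbytes = sum(p.nbytes for p in before.values())
        unique = {id(p) for rep in w.replicas for p in rep.params.values()}
        assert sum_bytes_of_ids(w) == nbytes
        assert len(unique) == len(before)

    def test_base_write_visible_through_every_replica(self):
        model = _linear_model([1.0, 1.0])
        w = pg.wrap(model, 4)
        model.layers[0].params["weight"][0, 0] = 5.0
        for rep in w.replicas:
            assert rep.params["0.Linear.weight"][0, 0] == 5.0

    def test_wrap_b1_identical_to_plain_model(self):
        model = random_cnn(1)
        x = np.random.default_rng(0).random((1, 1, 16, 16))
        plain = model.forward(x, train=False).copy()
        wrapped = pg.wrap(model, 1)
        out = pg.parallel_forward(wrapped, x, train=False)
        assert np.array_equal(out, plain)

    def test_wrap_refuses_unfixed_batch_norm(self):
        model = pg.tiny_cnn_bn(16, width=4, seed=0)
        with pytest.raises(pg.DPIncompatibilityError):
            pg.wrap(model, 4)


def sum_bytes_of_ids(wrapped):
    seen, total = set(), 0
    for rep in wrapped.replicas:
        for p in rep.params.values():
            if id(p) not in seen:
                seen.add(id(p))
                total += p.nbytes
    return total


class TestParallelForward:
    def test_linear_closed_form(self):
        model = _linear_model([1.0, 1.0])
        out = pg.parallel_forward(pg.wrap(model, 1), np.array([[1.0, 2.0]]))
        assert out[0, 0] == pytest.approx(3.0)

    def test_identical_samples_identical_outputs(self):
        model = random_cnn(2)
        x = np.tile(np.random.default_rng(1).random((1, 1, 16, 16)), (6, 1, 1, 1))
        out = pg.parallel_forward(pg.wrap(model, 6), x)
        assert np.allclose(out, out[0], atol=0)

    def test_matches_serial_per_sample_loop(self):
        model = random_cnn(3)
        x = np.random.default_rng(2).random((5, 1, 16, 16))
        batched = pg.parallel_forward(pg.wrap(model, 5), x)
        serial = np.concatenate([model.forward(x[i:i+1]) for i in range(5)])
        assert np.allclose(batched, serial, atol=1e-6)

    def test_batch_size_mismatch_raises(self):
        model = random_cnn(4)
        with pytest.raises(EngineError):
            pg.parallel_forward(pg.wrap(model, 4),
                                np.zeros((3, 1, 16, 16)))


class TestPerSampleGrads:
    def test_squared_error_closed_form(self):
        # 0.5*(w.x - y)^2 at w=(1,1), x=(1,2), y=0: dW = (w.x)*x = (3, 6)
        model = _linear_model([1.0, 1.0])
        w = pg.wrap(model, 1)
        out = pg.parallel_forward(w, np.array([[1.0, 2.0]]))
        losses, g = sq_loss(np.array([0.0]))(out, np.array([0]))
        psg = pg.per_sample_grads(w, g)
        assert np.allclose(psg.values[0, :2], [3.0, 6.0])
        assert losses[0] == pytest.approx(4.5)

    def test_constant_loss_zero_gradients(self):
        model = random_cnn(5)
        w = pg.wrap(model, 3)
        pg.parallel_forward(w, np.random.default_rng(3).random((3, 1, 16, 16)))
        psg = pg.per_sample_grads(w, np.zeros((3, 2)))
        assert np.all(psg.values == 0)
        assert np.all(psg.per_sample_norms == 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_serial_oracle(self, seed):
        rng = np.random.default_rng(seed)
        model = random_cnn(seed + 10)
        x = rng.random((8, 1, 16, 16))
        y = rng.integers(0, 2, 8)
        loss = ce_loss(y)
        w = pg.wrap(model, 8)
        out = pg.parallel_forward(w, x)
        _, g = loss(out, np.arange(8))
        psg = pg.per_sample_grads(w, g)
        oracle = pg.serial_oracle(model, x, loss)
        assert np.abs(psg.values - oracle.values).max() <= 1e-5
        assert np.allclose(psg.per_sample_norms,
                           np.linalg.norm(psg.values, axis=1))

    def test_reduced_loss_refused(self):
        model = random_cnn(6)
        w = pg.wrap(model, 2)
        pg.parallel_forward(w, np.zeros((2, 1, 16, 16)))
        with pytest.raises(EngineError):
            pg.per_sample_grads(w, np.float64(1.0))


class TestClip:
    def test_long_row_rescaled_direction_preserved(self):
        g = pg.PerSampleGradients.from_values(np.array([[3.0, 4.0]]))
        clipped, report = pg.clip(g, 1.0)
        assert np.allclose(clipped.values, [[0.6, 0.8]])
        assert report.clip_factors[0] == pytest.approx(0.2)

    def test_short_and_zero_rows_pass_through(self):
        g = pg.PerSampleGradients.from_values(
            np.array([[0.1, 0.0], [0.0, 0.0]]))
        clipped, report = pg.clip(g, 1.0)
        assert np.array_equal(clipped.values, g.values)
        assert np.all(report.clip_factors <= 1.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        values=arrays(np.float64, (8, 12),
                      elements=st.floats(-100, 100, allow_nan=False)),
        C=st.floats(0.01, 50.0),
    )
    def test_clip_invariants_property(self, values, C):
        """For any gradients and any C > 0: post-clip norms <= C (+tol),
        short rows untouched, clipping idempotent."""
        g = pg.PerSampleGradients.from_values(values)
        clipped, report = pg.clip(g, C)
        assert np.all(clipped.per_sample_norms <= C + 1e-6)
        short = g.per_sample_norms <= C
        assert np.allclose(clipped.values[short], values[short])
        again, _ = pg.clip(clipped, C)
        assert np.allclose(again.values, clipped.values)

    def test_idempotent_and_bounded(self):
        rng = np.random.default_rng(0)
        g = pg.PerSampleGradients.from_values(rng.normal(0, 10, (16, 50)))
        once, _ = pg.clip(g, 0.7)
        twice, _ = pg.clip(once, 0.7)
        assert np.all(once.per_sample_norms <= 0.7 + 1e-6)
        assert np.allclose(once.values, twice.values)


class TestAggregateAndNoise:
    def test_noiseless_mean(self):
        g = pg.PerSampleGradients.from_values(np.array([[1.0, 0.0], [0.0, 1.0]]))
        flat = pg.aggregate_and_noise(g, 1.0, 0.0, reduction="mean")
        assert np.allclose(flat, [0.5, 0.5])

    def test_sum_equals_mean_times_b(self):
        rng = np.random.default_rng(1)
        g = pg.PerSampleGradients.from_values(rng.normal(size=(4, 7)))
        s = pg.aggregate_and_noise(g, 1.0, 0.0, reduction="sum")
        m = pg.aggregate_and_noise(g, 1.0, 0.0, reduction="mean")
        assert np.allclose(s, m * 4)

    def test_noise_std_calibration(self):
        # sigma=1, C=1, B=1, zero gradients: output IS the noise; over 1e5
        # coordinates the sample std must be within 2% of sigma*C/B = 1
        g = pg.PerSampleGradients.from_values(np.zeros((1, 10**5)))
        src = pg.GaussianNoiseSource(secure=False, seed=99)
        flat = pg.aggregate_and_noise(g, 1.0, 1.0, noise_source=src)
        assert abs(flat.std() - 1.0) < 0.02

    def test_mismatched_noise_length_raises(self):
        g = pg.PerSampleGradients.from_values(np.zeros((2, 4)))
        with pytest.raises(EngineError):
            pg.aggregate_and_noise(g, 1.0, 1.0, noise=np.zeros(3))


class TestFullStep:
    def test_noiseless_unclipped_step_is_minibatch_gradient(self):
        """sigma=0, C=inf DP step == ordinary minibatch-mean gradient."""
        rng = np.random.default_rng(7)
        model = random_cnn(20)
        x = rng.random((6, 1, 16, 16))
        y = rng.integers(0, 2, 6)
        loss = ce_loss(y)
        w = pg.wrap(model, 6)
        _, flat = pg.dp_step(w, x, loss, clip_norm=math.inf, sigma=0.0)
        # reference: mean of per-sample rows from the serial oracle
        oracle = pg.serial_oracle(model, x, loss)
        assert np.abs(flat - oracle.values.mean(axis=0)).max() <= 1e-6

    def test_step_writes_optimiser_slots(self):
        model = random_cnn(21)
        x = np.random.default_rng(0).random((4, 1, 16, 16))
        y = np.array([0, 1, 0, 1])
        w = pg.wrap(model, 4)
        pg.dp_step(w, x, ce_loss(y), clip_norm=1.0, sigma=0.0)
        for layer in model.layers:
            for name in layer.params:
                assert name in layer.agg_grads
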