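"""Numerical correctness of the NumPy layer engine: forward passes against
naive references, gradients against central finite differences."""

import numpy as np
import pytest
from scipy.signal import correlate as sp_correlate

from deepernet.engine import (Adam, BatchNorm, Conv1d, ConvPoolBlock, Dense,
                              Dropout, LSTM, Param, bce_loss, orthogonal,
                              sigmoid_bce_with_grad, softmax_ce_with_grad,
                              F32)

RNG = lambda s=0: np.random.default_rng(s)  # noqa: E731
EPS = 1e-3


def _fd_check(loss_fn, param_arrays, grads, rng, n_probe=10, tol=2e-2):
    """Central finite differences on randomly probed entries."""
    for arr, g in zip(param_arrays, grads):
        flat, gflat = arr.ravel(), g.ravel()
        idxs = rng.choice(flat.size, size=min(n_probe, flat.size),
                          replace=False)
        for i in idxs:
            old = flat[i]
            flat[i] = old + EPS
            lp = loss_fn()
            flat[i] = old - EPS
            lm = loss_fn()
            flat[i] = old
            num = (lp - lm) / (2 * EPS)
            assert abs(num - gflat[i]) <= tol * max(1.0, abs(num)), \
                (num, gflat[i])


# ---------------------------------------------------------------------------
# ConvPoolBlock
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kernel,pool", [(6, 4), (5, 3), (8, 8)])
def test_fft_correlation_matches_scipy(kernel, pool):
    rng = RNG(1)
    blk = ConvPoolBlock(kernel=kernel, filters=3, pool=pool, rng=rng)
    x = rng.standard_normal((2, 41)).astype(F32)
    _, _, y = blk._correlate(x)
    for b in range(2):
        for f in range(3):
            padded = np.pad(x[b], (blk.pad_left, blk.k - 1 - blk.pad_left))
            ref = sp_correlate(padded, blk.w.v[f], mode="valid")
            np.testing.assert_allclose(y[b, f], ref, atol=1e-4)


@pytest.mark.parametrize("training", [True, False])
def test_convpool_forward_matches_naive(training):
    """Fused conv->BN->ReLU->maxpool equals the unfused reference, including
    filters whose BN scale is negative."""
    rng = RNG(2)
    blk = ConvPoolBlock(kernel=6, filters=4, pool=4, rng=rng)
    blk.bn.gamma.v = np.array([1.0, -0.7, 0.5, -1.2], dtype=F32)
    blk.bn.beta.v = rng.standard_normal(4).astype(F32)
    blk.bn.running_mean = rng.standard_normal(4).astype(F32)
    blk.bn.running_var = (rng.random(4) + 0.5).astype(F32)
    x = rng.standard_normal((3, 40)).astype(F32)

    _, _, y = blk._correlate(x)
    y = np.asarray(y, dtype=float)
    if training:
        mu, var = y.mean(axis=(0, 2)), y.var(axis=(0, 2))
    else:
        mu, var = blk.bn.running_mean, blk.bn.running_var
    inv = 1.0 / np.sqrt(var + 1e-3)
    z = (blk.bn.gamma.v[None, :, None] * (y - mu[None, :, None])
         * inv[None, :, None] + blk.bn.beta.v[None, :, None])
    ref = np.maximum(z, 0.0).reshape(3, 4, 10, 4).max(-1)

    out = blk.forward(x, training=training)
    np.testing.assert_allclose(out, ref, atol=1e-4)


def test_convpool_gradients_finite_difference():
    rng = RNG(3)
    blk = ConvPoolBlock(kernel=6, filters=3, pool=4, rng=rng)
    blk.always_cache = True
    blk.bn.gamma.v = np.array([1.0, -0.8, 0.6], dtype=F32)
    blk.bn.beta.v = rng.standard_normal(3).astype(F32)
    blk.bn.running_mean = rng.standard_normal(3).astype(F32)
    blk.bn.running_var = (rng.random(3) + 0.5).astype(F32)
    x = rng.standard_normal((2, 40)).astype(F32)

    def loss():
        return 0.5 * float(np.sum(blk.forward(x, False).astype(float) ** 2))

    out = blk.forward(x, False)
    for p in blk.params():
        p.zero_grad()
    sum_dx, sum_dx_x = blk.backward(out.copy())
    _fd_check(loss, [p.v for p in blk.params()], [p.g for p in blk.params()],
              rng, n_probe=12)

    # the two scalars handed to the upstream batch-norm equal the dense
    # finite-difference input gradient's sums
    gnum = np.zeros_like(x, dtype=float)
    for b in range(2):
        for t in range(40):
            old = x[b, t]
            x[b, t] = old + EPS
            lp = loss()
            x[b, t] = old - EPS
            lm = loss()
            x[b, t] = old
            gnum[b, t] = (lp - lm) / (2 * EPS)
    assert sum_dx == pytest.approx(gnum.sum(), rel=2e-2, abs=1e-2)
    assert sum_dx_x == pytest.approx(float((gnum * x).sum()), rel=2e-2,
                                     abs=1e-2)


# ---------------------------------------------------------------------------
# Conv1d / LSTM / Dense / BatchNorm
# ---------------------------------------------------------------------------

def test_conv1d_gradients():
    rng = RNG(4)
    conv = Conv1d(3, 4, 5, rng)
    x = rng.standard_normal((2, 3, 11)).astype(F32)

    def loss():
        return 0.5 * float(np.sum(conv.forward(x, False).astype(float) ** 2))

    out = conv.forward(x, False)
    conv.w.zero_grad()
    dx = conv.backward(out.copy())
    _fd_check(loss, [conv.w.v], [conv.w.g], rng, n_probe=20)
    for _ in range(12):
        b, c, t = rng.integers(2), rng.integers(3), rng.integers(11)
        old = x[b, c, t]
        x[b, c, t] = old + EPS
        lp = loss()
        x[b, c, t] = old - EPS
        lm = loss()
        x[b, c, t] = old
        num = (lp - lm) / (2 * EPS)
        assert abs(num - dx[b, c, t]) <= 2e-2 * max(1.0, abs(num))


@pytest.mark.parametrize("return_sequences", [True, False])
def test_lstm_gradients(return_sequences):
    rng = RNG(5)
    lstm = LSTM(4, 3, rng, return_sequences=return_sequences)
    x = rng.standard_normal((2, 5, 4)).astype(F32)

    def loss():
        return 0.5 * float(np.sum(lstm.forward(x, False).astype(float) ** 2))

    out = lstm.forward(x, False)
    for p in lstm.params():
        p.zero_grad()
    dx = lstm.backward(out.copy())
    _fd_check(loss, [p.v for p in lstm.params()],
              [p.g for p in lstm.params()], rng, n_probe=8)
    for _ in range(10):
        b, t, c = rng.integers(2), rng.integers(5), rng.integers(4)
        old = x[b, t, c]
        x[b, t, c] = old + EPS
        lp = loss()
        x[b, t, c] = old - EPS
        lm = loss()
        x[b, t, c] = old
        num = (lp - lm) / (2 * EPS)
        assert abs(num - dx[b, t, c]) <= 2e-2 * max(1.0, abs(num))


def test_lstm_forward_matches_naive_recurrence():
    """Step-by-step scalar recurrence reproduces the vectorised layer."""
    rng = RNG(6)
    lstm = LSTM(2, 2, rng, return_sequences=True)
    x = rng.standard_normal((1, 4, 2)).astype(F32)
    out = lstm.forward(x, False)

    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    W, U, b = lstm.w.v.astype(float), lstm.u.v.astype(float), \
        lstm.b.v.astype(float)
    h = np.zeros(2)
    c = np.zeros(2)
    H = 2
    for t in range(4):
        z = x[0, t].astype(float) @ W + h @ U + b
        i, f = sig(z[:H]), sig(z[H:2 * H])
        g, o = np.tanh(z[2 * H:3 * H]), sig(z[3 * H:])
        c = f * c + i * g
        h = o * np.tanh(c)
        np.testing.assert_allclose(out[0, t], h, atol=1e-5)


def test_dense_gradients():
    rng = RNG(7)
    dense = Dense(4, 3, rng)
    x = rng.standard_normal((5, 4)).astype(F32)

    def loss():
        return 0.5 * float(np.sum(dense.forward(x, False).astype(float) ** 2))

    out = dense.forward(x, False)
    for p in dense.params():
        p.zero_grad()
    dense.backward(out.copy())
    _fd_check(loss, [p.v for p in dense.params()],
              [p.g for p in dense.params()], rng, n_probe=8)


def test_batchnorm_eval_gradients_channelwise():
    """Frozen-statistics BN gradients are exact in evaluation mode, per
    channel of a (batch, channels, time) tensor."""
    rng = RNG(12)
    bn = BatchNorm(3)
    bn.running_mean = rng.standard_normal(3).astype(F32)
    bn.running_var = (rng.random(3) + 0.5).astype(F32)
    x = rng.standard_normal((4, 3, 7)).astype(F32)

    def loss():
        return 0.5 * float(np.sum(bn.forward(x, False).astype(float) ** 2))

    out = bn.forward(x, False)
    for p in bn.params():
        p.zero_grad()
    dx = bn.backward(out.copy())
    _fd_check(loss, [p.v for p in bn.params()],
              [p.g for p in bn.params()], rng, n_probe=6)
    for _ in range(8):
        b, c, t = rng.integers(4), rng.integers(3), rng.integers(7)
        old = x[b, c, t]
        x[b, c, t] = old + EPS
        lp = loss()
        x[b, c, t] = old - EPS
        lm = loss()
        x[b, c, t] = old
        num = (lp - lm) / (2 * EPS)
        assert abs(num - dx[b, c, t]) <= 2e-2 * max(1.0, abs(num))


def test_batchnorm_training_normalizes_and_tracks_running_stats():
    bn = BatchNorm(2)
    rng = RNG(8)
    x = (rng.standard_normal((64, 2, 10)) * 3.0 + 5.0).astype(F32)
    out = bn.forward(x, training=True)
    assert abs(out.mean()) < 1e-3
    assert out.std() == pytest.approx(1.0, abs=5e-2)
    # one update moves the running mean towards the batch mean
    assert np.all(bn.running_mean > 0.0)


# ---------------------------------------------------------------------------
# Dropout, losses, optimizer
# ---------------------------------------------------------------------------

def test_dropout_scaling_and_eval_identity():
    drop = Dropout(0.5)
    x = np.ones((200, 100), dtype=F32)
    out = drop.forward(x, training=True, rng=RNG(9))
    assert out.mean() == pytest.approx(1.0, abs=0.05)
    assert set(np.unique(out)) == {0.0, 2.0}
    np.testing.assert_array_equal(drop.forward(x, training=False), x)
    with pytest.raises(ValueError):
        drop.forward(x, training=True, rng=None)


def test_bce_loss_hand_values():
    assert bce_loss([1, 0], [0.5, 0.5]) == pytest.approx(np.log(2.0))
    assert bce_loss([1.0], [1.0 - 1e-7]) == pytest.approx(0.0, abs=1e-6)
    v = bce_loss([1.0], [0.0])  # clipped -> large but finite
    assert np.isfinite(v) and v > 10.0
    with pytest.raises(ValueError):
        bce_loss([1, 0], [0.5])


def test_fused_loss_gradients_match_finite_difference():
    rng = RNG(10)
    y = np.array([0, 1, 1, 0])
    z = rng.standard_normal((4, 1)).astype(F32)
    loss, grad = sigmoid_bce_with_grad(y, z)
    for i in range(4):
        zp = z.copy()
        zp[i] += EPS
        lp, _ = sigmoid_bce_with_grad(y, zp)
        zp[i] -= 2 * EPS
        lm, _ = sigmoid_bce_with_grad(y, zp)
        assert grad[i, 0] == pytest.approx((lp - lm) / (2 * EPS), abs=1e-4)

    y3 = np.array([0, 2, 1])
    z3 = rng.standard_normal((3, 3)).astype(F32)
    loss3, grad3 = softmax_ce_with_grad(y3, z3)
    zp = z3.copy()
    zp[1, 2] += EPS
    lp, _ = softmax_ce_with_grad(y3, zp)
    zp[1, 2] -= 2 * EPS
    lm, _ = softmax_ce_with_grad(y3, zp)
    assert grad3[1, 2] == pytest.approx((lp - lm) / (2 * EPS), abs=1e-4)


def test_adam_single_step_matches_hand_formula():
    p = Param(np.array([1.0, -2.0]), decay=True, name="w")
    opt = Adam([p], lr=0.01, weight_decay=0.0)
    p.g = np.array([0.5, -1.0], dtype=F32)
    v0 = p.v.copy()
    opt.step()
    g = np.array([0.5, -1.0])
    m_hat = (0.1 * g) / (1 - 0.9)
    s_hat = (0.001 * g * g) / (1 - 0.999)
    expect = v0 - 0.01 * m_hat / (np.sqrt(s_hat) + 1e-7)
    np.testing.assert_allclose(p.v, expect, rtol=1e-5)


def test_adam_weight_decay_only_on_kernel_params():
    pw = Param(np.array([1.0]), decay=True, name="w")
    pb = Param(np.array([1.0]), decay=False, name="b")
    opt = Adam([pw, pb], lr=0.01, weight_decay=0.1)
    pw.g = np.zeros(1, dtype=F32)
    pb.g = np.zeros(1, dtype=F32)
    opt.step()
    assert pw.v[0] < 1.0   # decayed despite zero gradient
    assert pb.v[0] == 1.0  # biases are not decayed


def test_orthogonal_init_is_orthogonal():
    q = orthogonal(RNG(11), 6, 6)
    np.testing.assert_allclose(q @ q.T, np.eye(6), atol=1e-8)
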