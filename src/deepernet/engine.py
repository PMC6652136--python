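"""Minimal NumPy neural-network engine for 1-D biosignal models.

Implements exactly the layer set the stress classifier needs — channel-wise
batch normalization, 1-D convolutions (stride 1, zero-padded to keep the
input length), non-overlapping max-pooling, LSTM, dense, dropout — together
with reverse-mode gradients, the Adam optimizer with decoupled-style L2
weight decay on kernels, and binary / categorical cross-entropy losses.

Two performance choices shape the code:

* The first convolution of each branch runs over tens of thousands of
  samples and is evaluated in the frequency domain (FFT correlation).
* That convolution is immediately followed by ReLU and a long
  non-overlapping max-pool, so the gradient arriving at the convolution
  output is non-zero only at the pooled argmax positions.  The fused
  :class:`ConvPoolBlock` exploits this: the backward pass gathers only the
  selected input windows instead of materialising a dense gradient.

Batch statistics of the normalization layers are treated as constants in
the backward pass (no gradient flows through the batch mean/variance); in
evaluation mode, where running statistics are used, this is exact.

Everything is deterministic given the ``numpy.random.Generator`` handed to
the stochastic pieces (initialization, dropout).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import next_fast_len

F32 = np.float32
BN_EPS = 1e-3
BN_MOMENTUM = 0.99
BCE_EPS = 1e-7


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("v", "g", "decay", "name")

    def __init__(self, value: np.ndarray, decay: bool, name: str):
        self.v = np.asarray(value, dtype=F32)
        self.g = np.zeros_like(self.v)
        self.decay = decay
        self.name = name

    def zero_grad(self) -> None:
        self.g[...] = 0.0


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    return q[:rows, :cols] if q.shape != (rows, cols) else q


# ---------------------------------------------------------------------------
# Batch normalization
# ---------------------------------------------------------------------------

class BatchNorm:
    """Channel-wise batch normalization.

    Accepts ``(B, T)`` input (a single channel) or ``(B, C, T)``; statistics
    are taken over the batch and time axes for each channel, matching the
    usual convention for 1-D convolutional stacks.
    """

    def __init__(self, channels: int, name: str = "bn"):
        self.channels = channels
        self.gamma = Param(np.ones(channels), decay=False, name=f"{name}.gamma")
        self.beta = Param(np.zeros(channels), decay=False, name=f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def _moments(self, x: np.ndarray, training: bool):
        axes = (0, 1) if x.ndim == 2 else (0, 2)
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = BN_MOMENTUM
            self.running_mean = (m * self.running_mean
                                 + (1 - m) * mu).astype(F32)
            self.running_var = (m * self.running_var
                                + (1 - m) * var).astype(F32)
        else:
            mu, var = self.running_mean, self.running_var
        return mu.astype(F32), var.astype(F32)

    def _expand(self, v: np.ndarray, ndim: int) -> np.ndarray:
        return v if ndim == 2 else v[None, :, None]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        mu, var = self._moments(x, training)
        inv = 1.0 / np.sqrt(var + BN_EPS)
        if x.ndim == 2:
            xhat = (x - mu) * inv
            out = self.gamma.v * xhat + self.beta.v
        else:
            xhat = (x - self._expand(mu, 3)) * self._expand(inv, 3)
            out = (self._expand(self.gamma.v, 3) * xhat
                   + self._expand(self.beta.v, 3))
        self._cache = (xhat, inv, x.ndim)
        return out.astype(F32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, ndim = self._cache
        axes = (0, 1) if ndim == 2 else (0, 2)
        self.gamma.g += np.sum(dout * xhat, axis=axes)
        self.beta.g += np.sum(dout, axis=axes)
        scale = self.gamma.v * inv
        return (dout * (scale if ndim == 2 else self._expand(scale, 3))
                ).astype(F32)

    def accumulate_grads_from_sums(self, sum_dout: float,
                                   sum_dout_times_out: float) -> None:
        """Gradients for a single-channel layer whose dense output gradient
        was never materialised: only ``sum(dout)`` and ``sum(dout * out)``
        are needed, since ``xhat = (out - beta) / gamma``."""
        g = float(self.gamma.v[0])
        b = float(self.beta.v[0])
        self.beta.g += sum_dout
        self.gamma.g += (sum_dout_times_out - b * sum_dout) / g


# ---------------------------------------------------------------------------
# Fused first stage: conv (FFT) -> batch norm -> ReLU -> max-pool
# ---------------------------------------------------------------------------

class ConvPoolBlock:
    """First convolution of a branch, fused with BN, ReLU and max-pool.

    Input ``(B, L)`` (one channel), output ``(B, F, P)`` where
    ``P = floor(L / pool)``.  The convolution is zero-padded to length L
    with ``pad_left = (k - 1) // 2``, stride 1, no bias (the batch-norm
    shift makes one redundant).

    Because BN is an increasing (or decreasing, if gamma < 0) affine map
    per filter and ReLU is monotone, the pooled maximum of
    ``relu(bn(conv))`` is determined by the windowed max (or min) of the
    raw convolution output — which is what the forward pass records, and
    what makes the backward pass sparse.
    """

    def __init__(self, kernel: int, filters: int, pool: int,
                 rng: np.random.Generator, name: str = "convpool"):
        self.k = int(kernel)
        self.f = int(filters)
        self.pool = int(pool)
        self.pad_left = (self.k - 1) // 2
        self.w = Param(glorot_uniform(rng, (filters, kernel),
                                      fan_in=kernel, fan_out=filters),
                       decay=True, name=f"{name}.w")
        self.bn = BatchNorm(filters, name=f"{name}.bn")
        self._cache = None
        #: when True, evaluation-mode forwards also record the pooling
        #: positions so backward() works with frozen statistics (used by
        #: gradient checks)
        self.always_cache = False

    def params(self) -> list[Param]:
        return [self.w] + self.bn.params()

    # -- forward -----------------------------------------------------------

    def _correlate(self, x: np.ndarray) -> np.ndarray:
        """Same-length cross-correlation of each row with every filter."""
        L = x.shape[1]
        nfft = next_fast_len(L + self.k - 1, real=True)
        X = np.fft.rfft(x, nfft)                          # complex64
        Wf = np.fft.rfft(self.w.v[:, ::-1], nfft)
        y_full = np.fft.irfft(X[:, None, :] * Wf[None, :, :], nfft)
        start = self.k - 1 - self.pad_left
        return y_full, start, y_full[..., start:start + L]  # last is a view

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        B, L = x.shape
        P = L // self.pool
        y_full, start, y = self._correlate(x)       # y: (B, F, L) view

        if training:
            # per-filter moments of the conv output; sums run over the
            # contiguous FFT buffer and the out-of-window edges are
            # subtracted, which avoids a 100-MB copy per batch
            n = B * L
            s1 = np.einsum("bfl->f", y_full, optimize=True
                           ).astype(np.float64)
            s2 = np.einsum("bfl,bfl->f", y_full, y_full, optimize=True
                           ).astype(np.float64)
            for edge in (y_full[..., :start], y_full[..., start + L:]):
                if edge.shape[-1]:
                    e = np.ascontiguousarray(edge)
                    s1 -= np.einsum("bfl->f", e, optimize=True)
                    s2 -= np.einsum("bfl,bfl->f", e, e, optimize=True)
            mu = s1 / n
            var = np.maximum(s2 / n - mu ** 2, 0.0)
            m = BN_MOMENTUM
            self.bn.running_mean = (m * self.bn.running_mean
                                    + (1 - m) * mu).astype(F32)
            self.bn.running_var = (m * self.bn.running_var
                                   + (1 - m) * var).astype(F32)
        else:
            mu, var = self.bn.running_mean, self.bn.running_var
        inv = 1.0 / np.sqrt(var + BN_EPS)
        a = (self.bn.gamma.v * inv).astype(F32)        # per-filter scale
        c = (self.bn.beta.v - a * mu).astype(F32)      # per-filter shift

        yw = y[..., :P * self.pool].reshape(B, self.f, P, self.pool)
        keep = training or self.always_cache  # backward needs the argmaxes
        if keep:
            amax = yw.argmax(axis=-1)
            ymax = np.take_along_axis(yw, amax[..., None], axis=-1)[..., 0]
        else:
            amax = None
            ymax = yw.max(axis=-1)
        if bool(np.any(a < 0)):
            neg = a < 0
            if keep:
                amin = yw.argmin(axis=-1)
                ymin = np.take_along_axis(yw, amin[..., None],
                                          axis=-1)[..., 0]
                sel_arg = np.where(neg[None, :, None], amin, amax)
            else:
                ymin = yw.min(axis=-1)
                sel_arg = None
            sel_val = np.where(neg[None, :, None], ymin, ymax)
        else:
            sel_arg, sel_val = amax, ymax

        pre = a[None, :, None] * sel_val + c[None, :, None]
        out = np.maximum(pre, 0.0)
        if keep:
            offsets = (np.arange(P) * self.pool)[None, None, :]
            self._cache = dict(
                x=x, L=L, idx=(sel_arg + offsets), sel_val=sel_val, a=a,
                mu=mu.astype(F32), inv=inv.astype(F32), alive=(pre > 0))
        return out.astype(F32)

    # -- backward ----------------------------------------------------------

    def backward(self, dout: np.ndarray) -> tuple[float, float]:
        """Accumulate kernel and BN gradients.

        Returns ``(sum_dx, sum_dx_times_x)`` — the two scalars an upstream
        single-channel batch-norm layer needs — instead of a dense input
        gradient (the input is the first layer's, so nothing else consumes
        it)."""
        cache = self._cache
        x, idx, a = cache["x"], cache["idx"], cache["a"]
        B, L = x.shape
        k, pad_left = self.k, self.pad_left
        g = (dout * cache["alive"]).astype(F32)           # (B, F, P)

        yhat_sel = (cache["sel_val"] - cache["mu"][None, :, None]) \
            * cache["inv"][None, :, None]
        self.bn.gamma.g += np.einsum("bfp,bfp->f", g, yhat_sel)
        self.bn.beta.g += g.sum(axis=(0, 2))

        dy = g * a[None, :, None]                         # sparse dL/dconv
        x_pad = np.pad(x, ((0, 0), (pad_left, k - 1 - pad_left)))
        xw = sliding_window_view(x_pad, k, axis=1)        # (B, L, k) view
        win = xw[np.arange(B)[:, None, None], idx]        # (B, F, P, k)
        dw = np.einsum("bfp,bfpk->fk", dy, win, optimize=True)
        self.w.g += dw

        # scalars for the upstream input batch-norm: padded entries of
        # x_pad are zero so they drop out of sum(dx * x) automatically;
        # sum(dx) needs an explicit correction for windows that overlap
        # the padding.
        sum_dx_x = float(np.sum(self.w.v * dw))
        wsum = self.w.v.sum(axis=1)                       # (F,)
        sum_dx = float(np.einsum("bfp,f->", dy, wsum))
        sum_dx -= self._edge_correction(dy, idx, L)
        return sum_dx, sum_dx_x

    def _edge_correction(self, dy: np.ndarray, idx: np.ndarray,
                         L: int) -> float:
        """Sum of dy * w over (window, tap) pairs that fall in the zero
        padding, i.e. the over-count of ``sum_dx``."""
        k, pad_left = self.k, self.pad_left
        lo_edge = idx < pad_left                    # misses leading taps
        hi_edge = idx + k > pad_left + L            # misses trailing taps
        if not (lo_edge.any() or hi_edge.any()):
            return 0.0
        cw = np.concatenate(
            [np.zeros((self.f, 1), dtype=F32), np.cumsum(self.w.v, axis=1)],
            axis=1)                                  # (F, k+1) prefix sums
        total = cw[:, -1]
        corr = 0.0
        for mask, which in ((lo_edge, "lo"), (hi_edge, "hi")):
            if not mask.any():
                continue
            b_i, f_i, p_i = np.nonzero(mask)
            pos = idx[b_i, f_i, p_i]
            if which == "lo":
                j_lo = pad_left - pos                # taps 0..j_lo-1 invalid
                invalid = cw[f_i, j_lo]
            else:
                j_hi = pad_left + L - pos            # taps >= j_hi invalid
                invalid = total[f_i] - cw[f_i, j_hi]
            corr += float(np.sum(dy[b_i, f_i, p_i] * invalid))
        return corr


# ---------------------------------------------------------------------------
# Standard convolution (second conv layer)
# ---------------------------------------------------------------------------

class Conv1d:
    """Multi-channel 1-D convolution, stride 1, zero-padded ('same')."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 rng: np.random.Generator, name: str = "conv"):
        self.c, self.f, self.k = int(in_channels), int(filters), int(kernel)
        self.pad_left = (self.k - 1) // 2
        self.w = Param(
            glorot_uniform(rng, (filters, in_channels, kernel),
                           fan_in=in_channels * kernel,
                           fan_out=filters * kernel),
            decay=True, name=f"{name}.w")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, C, T = x.shape
        xp = np.pad(x, ((0, 0), (0, 0),
                        (self.pad_left, self.k - 1 - self.pad_left)))
        win = sliding_window_view(xp, self.k, axis=2)     # (B, C, T, k)
        out = np.einsum("bctk,fck->bft", win, self.w.v, optimize=True)
        self._cache = (win, x.shape)
        return out.astype(F32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        win, xshape = self._cache
        self.w.g += np.einsum("bft,bctk->fck", dout, win, optimize=True)
        # full correlation of dout with the flipped kernel gives dx
        pad_r = self.k - 1 - self.pad_left
        gp = np.pad(dout, ((0, 0), (0, 0), (pad_r, self.pad_left)))
        gwin = sliding_window_view(gp, self.k, axis=2)    # (B, F, T, k)
        dx = np.einsum("bftk,fck->bct", gwin, self.w.v[:, :, ::-1],
                       optimize=True)
        return dx.astype(F32)


# ---------------------------------------------------------------------------
# LSTM
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class LSTM:
    """Standard LSTM (gate order i, f, g, o) over ``(B, T, C)`` input.

    ``return_sequences=True`` emits the hidden state at every step;
    otherwise only the final step.  Recurrent kernel is orthogonally
    initialised and the forget-gate bias starts at 1.
    """

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator,
                 return_sequences: bool, name: str = "lstm"):
        H = int(units)
        self.h = H
        self.return_sequences = return_sequences
        self.w = Param(glorot_uniform(rng, (in_dim, 4 * H),
                                      fan_in=in_dim, fan_out=4 * H),
                       decay=True, name=f"{name}.w")
        u = np.concatenate([orthogonal(rng, H, H) for _ in range(4)], axis=1)
        self.u = Param(u, decay=True, name=f"{name}.u")
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0  # forget-gate bias
        self.b = Param(b, decay=False, name=f"{name}.b")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.u, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, T, _ = x.shape
        H = self.h
        xw = x @ self.w.v + self.b.v                      # (B, T, 4H)
        h = np.zeros((B, H), dtype=F32)
        c = np.zeros((B, H), dtype=F32)
        gates = np.empty((T, B, 4 * H), dtype=F32)
        cs = np.empty((T, B, H), dtype=F32)
        hs = np.empty((T, B, H), dtype=F32)
        for t in range(T):
            z = xw[:, t, :] + h @ self.u.v
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c = f * c + i * g
            h = o * np.tanh(c)
            gates[t, :, :H], gates[t, :, H:2 * H] = i, f
            gates[t, :, 2 * H:3 * H], gates[t, :, 3 * H:] = g, o
            cs[t], hs[t] = c, h
        self._cache = (x, gates, cs, hs)
        if self.return_sequences:
            return hs.transpose(1, 0, 2).astype(F32)
        return h.astype(F32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, gates, cs, hs = self._cache
        B, T, _ = x.shape
        H = self.h
        if self.return_sequences:
            dh_seq = dout.transpose(1, 0, 2)
        else:
            dh_seq = np.zeros((T, B, H), dtype=F32)
            dh_seq[-1] = dout
        dW = np.zeros_like(self.w.v)
        dU = np.zeros_like(self.u.v)
        db = np.zeros_like(self.b.v)
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H), dtype=F32)
        dc_next = np.zeros((B, H), dtype=F32)
        for t in range(T - 1, -1, -1):
            i = gates[t, :, :H]
            f = gates[t, :, H:2 * H]
            g = gates[t, :, 2 * H:3 * H]
            o = gates[t, :, 3 * H:]
            c = cs[t]
            c_prev = cs[t - 1] if t > 0 else np.zeros_like(c)
            h_prev = hs[t - 1] if t > 0 else np.zeros((B, H), dtype=F32)
            tc = np.tanh(c)
            dh = dh_seq[t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc ** 2) + dc_next
            di, dg, df = dc * g, dc * i, dc * c_prev
            dc_next = dc * f
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            dW += x[:, t, :].T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.w.v.T
            dh_next = dz @ self.u.v.T
        self.w.g += dW
        self.u.g += dU
        self.b.g += db
        return dx.astype(F32)


# ---------------------------------------------------------------------------
# Dense, activations, dropout
# ---------------------------------------------------------------------------

class Dense:
    def __init__(self, in_dim: int, units: int, rng: np.random.Generator,
                 name: str = "dense"):
        self.w = Param(glorot_uniform(rng, (in_dim, units),
                                      fan_in=in_dim, fan_out=units),
                       decay=True, name=f"{name}.w")
        self.b = Param(np.zeros(units), decay=False, name=f"{name}.b")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._cache = x
        return (x @ self.w.v + self.b.v).astype(F32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.w.g += x.T @ dout
        self.b.g += dout.sum(axis=0)
        return (dout @ self.w.v.T).astype(F32)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(F32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return (dout * self._mask).astype(F32)


class Dropout:
    def __init__(self, rate: float):
        self.rate = float(rate)
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(F32) / keep
        return (x * self._mask).astype(F32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return (dout * self._mask).astype(F32)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def bce_loss(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    """Mean binary cross-entropy with probabilities clipped to
    ``[eps, 1 - eps]`` (eps = 1e-7)."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_prob = np.asarray(y_prob, dtype=float).ravel()
    if y_true.shape != y_prob.shape:
        raise ValueError("label/prediction length mismatch")
    p = np.clip(y_prob, BCE_EPS, 1.0 - BCE_EPS)
    return float(-np.mean(y_true * np.log(p) + (1 - y_true) * np.log(1 - p)))


def sigmoid_bce_with_grad(y_true: np.ndarray,
                          logits: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss value per the clipped-probability definition, with the standard
    fused sigmoid-BCE gradient ``(p - y) / M`` w.r.t. the logits."""
    y = np.asarray(y_true, dtype=F32).reshape(-1, 1)
    p = _sigmoid(logits.astype(np.float64))
    loss = bce_loss(y.ravel(), p.ravel())
    grad = ((p - y) / len(y)).astype(F32)
    return loss, grad


def softmax_ce_with_grad(y_true: np.ndarray,
                         logits: np.ndarray) -> tuple[float, np.ndarray]:
    """Categorical cross-entropy on integer labels with softmax logits."""
    y = np.asarray(y_true, dtype=int).ravel()
    z = logits.astype(np.float64)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    eps = BCE_EPS
    loss = float(-np.mean(np.log(np.clip(p[np.arange(len(y)), y], eps, 1.0))))
    grad = p.copy()
    grad[np.arange(len(y)), y] -= 1.0
    return loss, (grad / len(y)).astype(F32)


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with L2 weight decay added to the gradient of kernel params."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.v) for p in params]
        self.s = [np.zeros_like(p.v) for p in params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, s in zip(self.params, self.m, self.s):
            g = p.g
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.v
            m[...] = b1 * m + (1 - b1) * g
            s[...] = b2 * s + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            shat = s / (1 - b2 ** self.t)
            p.v -= (lr * mhat / (np.sqrt(shat) + self.eps)).astype(F32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
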