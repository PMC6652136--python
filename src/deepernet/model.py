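"""DeepER Net: a dual-branch CNN-LSTM classifier for paired 50-s ECG and
respiration clips.

Each branch is: batch-norm on the raw signal -> 1-D conv (50 filters,
stride 1, zero-padded, ReLU) -> non-overlapping max-pool -> second 1-D conv
(50 filters, ReLU) -> LSTM(32, sequence output) -> LSTM(16, last output),
with dropout (0.5) after each LSTM.  The first ECG kernel and pool span
0.6 s and 0.8 s of signal (600/800 samples at 1 kHz); the RESP kernel and
pool both span one 5-s breathing period (125 samples at 25 Hz).  The second
kernels (25 and 4 pooled steps) each cover exactly 20 s of original signal.
Branch outputs are concatenated into a 512-unit ReLU dense layer (dropout
0.5) and a sigmoid output head (softmax for the three-class variant).

Training: Adam at 1e-3 with the learning rate halved every 50 epochs,
batch size 32, binary cross-entropy, L2 weight decay 1e-4 on kernels, a
stratified 0.3 validation split carved out of the training data, and
selection of the epoch with the lowest validation loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import engine
from .baselines import CVSplit
from .engine import (Adam, BatchNorm, Conv1d, ConvPoolBlock, Dense, Dropout,
                     LSTM, ReLU, bce_loss, sigmoid_bce_with_grad,
                     softmax_ce_with_grad, softmax_probs)
from .metrics import EvalReport, FoldResult
from .preprocess import SegmentDataset

logger = logging.getLogger(__name__)

# evaluation-mode minibatch; small keeps the FFT work set in cache
EVAL_BATCH = 32


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyper-parameters.

    Kernel and pool spans are stored in seconds so the sample counts follow
    the sampling rates exactly; the second-conv kernels are counted in
    pooled steps and are rate-independent.
    """

    fs_ecg: float = 1000.0
    fs_resp: float = 25.0
    window_s: float = 50.0
    ecg_kernel1_s: float = 0.6
    ecg_pool_s: float = 0.8
    resp_kernel1_s: float = 5.0
    resp_pool_s: float = 5.0
    filters_conv1: int = 50
    ecg_kernel2: int = 25
    resp_kernel2: int = 4
    filters_conv2: int = 50
    lstm_units: tuple[int, int] = (32, 16)
    dense_units: int = 512
    dropout: float = 0.5
    weight_decay: float = 1e-4
    n_classes: int = 2  # 2 -> sigmoid head; 3 -> softmax head

    @property
    def ecg_kernel1(self) -> int:
        return int(round(self.ecg_kernel1_s * self.fs_ecg))

    @property
    def ecg_pool(self) -> int:
        return int(round(self.ecg_pool_s * self.fs_ecg))

    @property
    def resp_kernel1(self) -> int:
        return int(round(self.resp_kernel1_s * self.fs_resp))

    @property
    def resp_pool(self) -> int:
        return int(round(self.resp_pool_s * self.fs_resp))

    @property
    def ecg_input_len(self) -> int:
        return int(round(self.window_s * self.fs_ecg))

    @property
    def resp_input_len(self) -> int:
        return int(round(self.window_s * self.fs_resp))

    @property
    def ecg_steps(self) -> int:
        return self.ecg_input_len // self.ecg_pool

    @property
    def resp_steps(self) -> int:
        return self.resp_input_len // self.resp_pool

    def receptive_span_s(self, branch: str) -> float:
        """Original-signal span of the second conv kernel, in seconds."""
        if branch == "ecg":
            return self.ecg_kernel2 * self.ecg_pool_s
        if branch == "resp":
            return self.resp_kernel2 * self.resp_pool_s
        raise ValueError(f"unknown branch {branch!r}")

    def validate(self) -> None:
        for br in ("ecg", "resp"):
            span = self.receptive_span_s(br)
            if abs(span - 20.0) > 1e-9:
                raise ValueError(
                    f"{br} second conv spans {span} s, expected 20 s")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    lr_halve_every: int = 50
    epochs: int = 250
    batch_size: int = 32
    validation_split: float = 0.3
    rng_seed: int = 0

    def lr_at(self, epoch: int) -> float:
        """Step decay: lr * 2^(-floor(epoch / halve_every))."""
        return self.lr * 2.0 ** (-(epoch // self.lr_halve_every))


class _Branch:
    def __init__(self, kernel1: int, pool: int, kernel2: int, cfg: NetConfig,
                 rng: np.random.Generator, name: str):
        self.input_bn = BatchNorm(1, name=f"{name}.bn0")
        self.block = ConvPoolBlock(kernel1, cfg.filters_conv1, pool, rng,
                                   name=f"{name}.conv1")
        self.conv2 = Conv1d(cfg.filters_conv1, cfg.filters_conv2, kernel2,
                            rng, name=f"{name}.conv2")
        self.bn2 = BatchNorm(cfg.filters_conv2, name=f"{name}.bn2")
        self.relu2 = ReLU()
        self.lstm1 = LSTM(cfg.filters_conv2, cfg.lstm_units[0], rng,
                          return_sequences=True, name=f"{name}.lstm1")
        self.drop1 = Dropout(cfg.dropout)
        self.lstm2 = LSTM(cfg.lstm_units[0], cfg.lstm_units[1], rng,
                          return_sequences=False, name=f"{name}.lstm2")
        self.drop2 = Dropout(cfg.dropout)

    def params(self):
        out = []
        for layer in (self.input_bn, self.block, self.conv2, self.bn2,
                      self.lstm1, self.lstm2):
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        u = self.input_bn.forward(x, training)
        h = self.block.forward(u, training)          # (B, F, P)
        h = self.conv2.forward(h, training)
        h = self.bn2.forward(h, training)
        h = self.relu2.forward(h, training)
        seq = np.ascontiguousarray(h.transpose(0, 2, 1))  # (B, P, F)
        s = self.lstm1.forward(seq, training)
        s = self.drop1.forward(s, training, rng)
        s = self.lstm2.forward(s, training)
        s = self.drop2.forward(s, training, rng)
        return s                                      # (B, lstm_units[1])

    def backward(self, d: np.ndarray) -> None:
        d = self.drop2.backward(d)
        d = self.lstm2.backward(d)
        d = self.drop1.backward(d)
        d = self.lstm1.backward(d)
        d = np.ascontiguousarray(d.transpose(0, 2, 1))
        d = self.relu2.backward(d)
        d = self.bn2.backward(d)
        d = self.conv2.backward(d)
        sum_dx, sum_dx_x = self.block.backward(d)
        self.input_bn.accumulate_grads_from_sums(sum_dx, sum_dx_x)

    def first_stage(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Evaluation-mode (bn0 output, post-first-ReLU activation) at full
        input resolution, for activation visualization.  Shapes: (B, L) and
        (B, F, L)."""
        u = self.input_bn.forward(x, training=False)
        _, _, y = self.block._correlate(np.asarray(u, dtype=engine.F32))
        mu = self.block.bn.running_mean[None, :, None]
        inv = 1.0 / np.sqrt(self.block.bn.running_var + engine.BN_EPS)
        z = (self.block.bn.gamma.v[None, :, None] * (y - mu)
             * inv[None, :, None] + self.block.bn.beta.v[None, :, None])
        return u, np.maximum(z, 0.0)


def build_deeper_net(cfg: NetConfig, rng_seed: int = 0) -> "DeepERNet":
    return DeepERNet(cfg, rng_seed=rng_seed)


class DeepERNet:
    """The dual-branch network with explicit forward/backward passes."""

    def __init__(self, cfg: NetConfig, rng_seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng([rng_seed, 0x5EED])
        self.ecg_branch = _Branch(cfg.ecg_kernel1, cfg.ecg_pool,
                                  cfg.ecg_kernel2, cfg, rng, "ecg")
        self.resp_branch = _Branch(cfg.resp_kernel1, cfg.resp_pool,
                                   cfg.resp_kernel2, cfg, rng, "resp")
        concat_dim = 2 * cfg.lstm_units[1]
        self.dense = Dense(concat_dim, cfg.dense_units, rng, name="dense")
        self.relu = ReLU()
        self.drop = Dropout(cfg.dropout)
        out_units = 1 if cfg.n_classes == 2 else cfg.n_classes
        self.head = Dense(cfg.dense_units, out_units, rng, name="head")
        self.trained = False

    # -- parameter plumbing ------------------------------------------------

    def parameters(self):
        out = self.ecg_branch.params() + self.resp_branch.params()
        out += self.dense.params() + self.head.params()
        return out

    def _bn_layers(self):
        for br in (self.ecg_branch, self.resp_branch):
            yield br.input_bn
            yield br.block.bn
            yield br.bn2

    def get_state(self) -> list[np.ndarray]:
        state = [p.v.copy() for p in self.parameters()]
        for bn in self._bn_layers():
            state.append(bn.running_mean.copy())
            state.append(bn.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, v in zip(params, state[:len(params)]):
            p.v[...] = v
        rest = state[len(params):]
        for bn, mean, var in zip(self._bn_layers(), rest[0::2], rest[1::2]):
            bn.running_mean[...] = mean
            bn.running_var[...] = var

    def save(self, path) -> None:
        np.savez(path, *(self.get_state()))

    def load(self, path) -> None:
        with np.load(path) as data:
            self.set_state([data[k] for k in data.files])
        self.trained = True

    # -- forward / backward ------------------------------------------------

    def _check_inputs(self, ecg: np.ndarray, resp: np.ndarray) -> None:
        if ecg.shape[1] != self.cfg.ecg_input_len:
            raise ValueError(
                f"ECG input length {ecg.shape[1]} != "
                f"{self.cfg.ecg_input_len} (= window_s * fs_ecg)")
        if resp.shape[1] != self.cfg.resp_input_len:
            raise ValueError(
                f"RESP input length {resp.shape[1]} != "
                f"{self.cfg.resp_input_len} (= window_s * fs_resp)")

    def forward(self, ecg: np.ndarray, resp: np.ndarray, training: bool,
                rng: np.random.Generator | None = None) -> np.ndarray:
        self._check_inputs(ecg, resp)
        fe = self.ecg_branch.forward(ecg, training, rng)
        fr = self.resp_branch.forward(resp, training, rng)
        z = np.concatenate([fe, fr], axis=1)
        h = self.dense.forward(z, training)
        h = self.relu.forward(h, training)
        h = self.drop.forward(h, training, rng)
        return self.head.forward(h, training)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        d = self.drop.backward(d)
        d = self.relu.backward(d)
        d = self.dense.backward(d)
        k = self.cfg.lstm_units[1]
        self.ecg_branch.backward(d[:, :k])
        self.resp_branch.backward(d[:, k:])

    def predict_proba(self, ecg: np.ndarray, resp: np.ndarray,
                      batch: int = EVAL_BATCH) -> np.ndarray:
        """Evaluation-mode probabilities: P(stressed) for the binary head,
        an (n, 3) softmax matrix for the three-class head."""
        outs = []
        for i in range(0, len(ecg), batch):
            logits = self.forward(ecg[i:i + batch], resp[i:i + batch],
                                  training=False)
            if self.cfg.n_classes == 2:
                outs.append(1.0 / (1.0 + np.exp(-logits[:, 0].astype(float))))
            else:
                outs.append(softmax_probs(logits.astype(float)))
        return np.concatenate(outs)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _stratified_split(y: np.ndarray, frac: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(train_idx, val_idx) with ``frac`` of each class held out."""
    tr, va = [], []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = idx[rng.permutation(len(idx))]
        n_val = int(round(frac * len(idx)))
        va.append(idx[:n_val])
        tr.append(idx[n_val:])
    return (np.sort(np.concatenate(tr)), np.sort(np.concatenate(va)))


def _mean_loss(model: DeepERNet, ecg, resp, y, batch: int = EVAL_BATCH
               ) -> tuple[float, float]:
    """Evaluation-mode (loss, accuracy fraction) on a dataset."""
    probs = model.predict_proba(ecg, resp, batch=batch)
    if model.cfg.n_classes == 2:
        loss = bce_loss(y, probs)
        acc = float(np.mean((probs >= 0.5).astype(int) == y))
    else:
        p = np.clip(probs[np.arange(len(y)), y], engine.BCE_EPS, 1.0)
        loss = float(-np.mean(np.log(p)))
        acc = float(np.mean(np.argmax(probs, axis=1) == y))
    return loss, acc


def train(model: DeepERNet, ecg: np.ndarray, resp: np.ndarray,
          y: np.ndarray, cfg: TrainConfig) -> dict:
    """Train with Adam + step-decayed learning rate; keep the epoch with the
    lowest validation loss.

    Returns a history dict with per-epoch ``lr``, ``train_loss``,
    ``train_acc``, ``val_loss``, ``val_acc`` and the selected
    ``best_epoch``.  Raises ``RuntimeError`` on divergence (non-finite
    loss).
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng([cfg.rng_seed, 0xD0])
    drop_rng = np.random.default_rng([cfg.rng_seed, 0xD1])
    tr_idx, va_idx = _stratified_split(y, cfg.validation_split, rng)
    Xe, Xr, yt = ecg[tr_idx], resp[tr_idx], y[tr_idx]
    Ve, Vr, yv = ecg[va_idx], resp[va_idx], y[va_idx]

    opt = Adam(model.parameters(), lr=cfg.lr,
               weight_decay=model.cfg.weight_decay)
    loss_grad = (sigmoid_bce_with_grad if model.cfg.n_classes == 2
                 else softmax_ce_with_grad)
    history = {"lr": [], "train_loss": [], "train_acc": [],
               "val_loss": [], "val_acc": []}
    best = (np.inf, -1, None)

    n = len(yt)
    for epoch in range(cfg.epochs):
        lr = cfg.lr_at(epoch)
        order = rng.permutation(n)
        losses, hits, seen = [], 0, 0
        for i in range(0, n, cfg.batch_size):
            b = order[i:i + cfg.batch_size]
            logits = model.forward(Xe[b], Xr[b], training=True, rng=drop_rng)
            loss, grad = loss_grad(yt[b], logits)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (loss={loss})")
            opt.zero_grad()
            model.backward(grad)
            opt.step(lr)
            losses.append(loss * len(b))
            if model.cfg.n_classes == 2:
                hits += int(np.sum((logits[:, 0] >= 0).astype(int) == yt[b]))
            else:
                hits += int(np.sum(np.argmax(logits, axis=1) == yt[b]))
            seen += len(b)
        # train metrics are the running batch averages (training mode,
        # i.e. with dropout active), as is conventional for history curves
        tr_loss, tr_acc = float(np.sum(losses) / seen), hits / seen
        va_loss, va_acc = _mean_loss(model, Ve, Vr, yv)
        history["lr"].append(lr)
        history["train_loss"].append(tr_loss)
        history["train_acc"].append(tr_acc)
        history["val_loss"].append(va_loss)
        history["val_acc"].append(va_acc)
        if va_loss < best[0]:
            best = (va_loss, epoch, model.get_state())
        logger.debug("epoch %d lr %.2e train %.4f val %.4f", epoch, lr,
                     tr_loss, va_loss)

    if best[2] is not None:
        model.set_state(best[2])
    history["best_epoch"] = best[1]
    model.trained = True
    return history


def evaluate(model: DeepERNet, ecg: np.ndarray, resp: np.ndarray,
             y: np.ndarray, threshold: float = 0.5) -> FoldResult:
    """Confusion counts, accuracy (%), F1, ROC and AUC on a test set."""
    if len(y) == 0:
        raise ValueError("empty test set")
    if model.cfg.n_classes != 2:
        raise ValueError("evaluate() covers the binary head; use "
                         "predict_proba for the three-class variant")
    probs = model.predict_proba(ecg, resp)
    return EvalReport().add(y, probs, threshold=threshold)


@dataclass
class CVResult:
    report: EvalReport
    histories: list[dict] = field(default_factory=list)
    first_fold_model: DeepERNet | None = None


def crossvalidate(ds: SegmentDataset, net_cfg: NetConfig,
                  train_cfg: TrainConfig, split: CVSplit,
                  keep_first_model: bool = True) -> CVResult:
    """Independent training per outer fold; aggregates mean +/- SD metrics."""
    y = np.asarray(ds.labels, dtype=int)
    for cls in np.unique(y):
        if np.sum(y == cls) < split.n_folds:
            raise ValueError(f"class {cls} has fewer segments than folds")
    result = CVResult(report=EvalReport())
    for fold in range(split.n_folds):
        tr, te = split.train_indices(fold), split.test_indices(fold)
        model = DeepERNet(net_cfg, rng_seed=train_cfg.rng_seed + fold)
        fold_cfg = TrainConfig(
            lr=train_cfg.lr, lr_halve_every=train_cfg.lr_halve_every,
            epochs=train_cfg.epochs, batch_size=train_cfg.batch_size,
            validation_split=train_cfg.validation_split,
            rng_seed=train_cfg.rng_seed + fold)
        hist = train(model, ds.ecg[tr], ds.resp[tr], y[tr], fold_cfg)
        result.histories.append(hist)
        fold_res = result.report.add(
            y[te], model.predict_proba(ds.ecg[te], ds.resp[te]))
        logger.info("fold %d: acc %.1f%% f1 %.3f auc %.3f (best epoch %d)",
                    fold, fold_res.accuracy, fold_res.f1, fold_res.auc,
                    hist["best_epoch"])
        if fold == 0 and keep_first_model:
            result.first_fold_model = model
    return result
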