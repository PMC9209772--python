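"""Multi-stream CNN + attention + GRU gesture classifier.

One independent branch per input stream: each retained sEMG electrode feeds
its own 1-D convolutional stack (conv → optional batch-norm → ReLU →
temporal max-pool → optional CBAM placed after the rectifier), optionally
followed by a GRU that reads the attended activation sequence; the 3-axis
accelerometer, when fused, is one more branch of identical topology. Stream
vectors (GRU last state, or the global time-average of conv features when
the GRU is disabled) are concatenated, passed through a dropout-regularized
fully-connected layer and a final softmax layer of size M:

    p(m | g) = exp(g_m) / Σ_j exp(g_j),      m₀ = argmax_m p(m | g)

with the lowest class index winning exact ties. Five ablation topologies
(bare multi-stream convolution; +BN; +BN+GRU; +BN+CBAM; +BN+CBAM+GRU) share
a single config switchboard so they differ only in their stated components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._autodiff import Tensor
from .cbam import CBAM1d
from .nn import GRU, Adam, BatchNorm1d, Conv1d, Dropout, Linear, Module, cross_entropy, softmax

__all__ = [
    "ModelConfig",
    "ClassScores",
    "TrainOptions",
    "TrainingHistory",
    "MCBAMGRU",
    "build_model",
    "classify_scores",
    "train_model",
    "evaluate_confusion",
    "ablation_config",
    "run_ablation",
    "ABLATION_LABELS",
    "save_checkpoint",
    "load_checkpoint",
]

ABLATION_LABELS = (
    "multi-stream convolution",
    "+ batch normalization (BN)",
    "+ BN + GRU",
    "+ BN + 1D CBAM",
    "+ BN + 1D CBAM + GRU",
)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture switchboard.

    ``conv_blocks`` lists per-stream ``(out_channels, kernel, stride)``;
    ``pool_factors`` (same length) downsample time after each block so the
    recurrent stage reads a short attended sequence. ``input_mode`` selects
    raw decision windows (1 input channel per sEMG stream) or per-channel
    feature images (4 input channels: IEMG/VAR/MDF/FR planes).
    """

    n_semg_streams: int = 6
    use_acc: bool = True
    input_mode: str = "raw_windows"
    conv_blocks: tuple[tuple[int, int, int], ...] = ((32, 3, 1), (64, 3, 1))
    pool_factors: tuple[int, ...] = (5, 5)
    use_bn: bool = True
    use_cbam: bool = True
    use_gru: bool = True
    gru_hidden: int = 64
    cbam_r: int = 8
    fc_dim: int = 128
    dropout_p: float = 0.5
    n_classes: int = 52
    window_samples: int = 200
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not (0 <= self.dropout_p < 1):
            raise ValueError("dropout_p must be in [0, 1)")
        if self.input_mode not in ("raw_windows", "feature_images"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if len(self.pool_factors) != len(self.conv_blocks):
            raise ValueError("pool_factors must match conv_blocks length")
        length = self.window_samples
        for (_, k, s), p in zip(self.conv_blocks, self.pool_factors):
            if k % 2 == 0:
                raise ValueError("conv kernel sizes must be odd")
            length = ((length - 1) // s + 1) // p
            if length < 1:
                raise ValueError(
                    "conv/pool stack consumes the whole window; reduce "
                    "strides or pool factors"
                )
        if self.use_cbam:
            for c, _, _ in self.conv_blocks:
                if c % self.cbam_r != 0:
                    raise ValueError(
                        f"cbam_r={self.cbam_r} must divide every conv width"
                    )

    @property
    def stream_in_channels(self) -> int:
        return 1 if self.input_mode == "raw_windows" else 4

    @property
    def n_streams(self) -> int:
        return self.n_semg_streams + (1 if self.use_acc else 0)

    @property
    def stream_out_dim(self) -> int:
        return self.gru_hidden if self.use_gru else self.conv_blocks[-1][0]


@dataclass(frozen=True)
class ClassScores:
    """Pre-softmax label vector, class probabilities and the decision."""

    g: np.ndarray  # (M,) or (N, M) logits
    p: np.ndarray  # same shape, rows sum to 1
    m0: np.ndarray  # () or (N,) 1-based predicted class index


def classify_scores(logits: np.ndarray) -> ClassScores:
    """Softmax probabilities + argmax decision (lowest index wins ties).

    Classes are reported 1-based (m₀ ∈ 1..M) to match gesture numbering.
    """
    g = np.asarray(logits, dtype=float)
    p = softmax(g, axis=-1)
    m0 = np.argmax(p, axis=-1) + 1
    return ClassScores(g=g, p=p, m0=m0)


class _Stream(Module):
    """One branch: conv blocks (+BN, ReLU, +CBAM, pool) then GRU or GAP."""

    def __init__(self, cfg: ModelConfig, in_channels: int, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.convs: list[Conv1d] = []
        self.bns: list[BatchNorm1d] = []
        self.cbams: list[CBAM1d] = []
        prev = in_channels
        for out_ch, kernel, stride in cfg.conv_blocks:
            self.convs.append(Conv1d(prev, out_ch, kernel, rng, stride=stride))
            if cfg.use_bn:
                self.bns.append(BatchNorm1d(out_ch))
            if cfg.use_cbam:
                self.cbams.append(CBAM1d(out_ch, cfg.cbam_r, rng))
            prev = out_ch
        self.gru = GRU(prev, cfg.gru_hidden, rng) if cfg.use_gru else None

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        for i, conv in enumerate(self.convs):
            x = conv(x)
            if cfg.use_bn:
                x = self.bns[i](x)
            x = x.relu()
            if cfg.pool_factors[i] > 1:
                x = x.maxpool1d(cfg.pool_factors[i])
            if cfg.use_cbam:
                x = self.cbams[i](x)
        if self.gru is not None:
            seq = x.transpose(0, 2, 1)  # (N, T, C)
            return self.gru.last_state(seq)
        return x.mean(axis=2)  # global average pool over time


class MCBAMGRU(Module):
    """The full multi-stream model. Construct via :func:`build_model`."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
        self.streams = [
            _Stream(cfg, cfg.stream_in_channels, rng)
            for _ in range(cfg.n_semg_streams)
        ]
        self.acc_stream = _Stream(cfg, 3, rng) if cfg.use_acc else None
        concat_dim = cfg.stream_out_dim * cfg.n_streams
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 13])
        )
        self.dropout = Dropout(cfg.dropout_p, self._dropout_rng)
        self.fc = Linear(concat_dim, cfg.fc_dim, rng)
        self.head = Linear(cfg.fc_dim, cfg.n_classes, rng)

    def reseed_dropout(self, seed: int) -> None:
        self.dropout.rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))

    def stream_outputs(self, x_semg: np.ndarray,
                       x_acc: np.ndarray | None = None) -> list[Tensor]:
        """Per-branch feature vectors for a batch.

        ``x_semg``: (N, n_semg_streams, C_in, L); ``x_acc``: (N, 3, L).
        """
        x = np.asarray(x_semg, dtype=float)
        if x.ndim == 3:  # (N, S, L) raw windows → add the singleton channel
            x = x[:, :, None, :]
        if x.shape[1] != self.cfg.n_semg_streams:
            raise ValueError(
                f"expected {self.cfg.n_semg_streams} sEMG streams, got {x.shape[1]}"
            )
        outs = [
            stream(Tensor(x[:, s])) for s, stream in enumerate(self.streams)
        ]
        if self.acc_stream is not None:
            if x_acc is None:
                raise ValueError("model fuses ACC but no accelerometer input given")
            outs.append(self.acc_stream(Tensor(np.asarray(x_acc, dtype=float))))
        return outs

    def aggregate_and_classify(self, stream_outputs: list[Tensor]) -> Tensor:
        """Concatenate branch vectors along the feature axis and run the
        dropout-FC / softmax-FC head; returns the logits tensor."""
        if not stream_outputs:
            raise ValueError("no stream outputs to aggregate")
        z = Tensor.concat(stream_outputs, axis=1)
        z = self.dropout(z)
        z = self.fc(z).relu()
        return self.head(z)

    def forward(self, x_semg: np.ndarray, x_acc: np.ndarray | None = None) -> Tensor:
        return self.aggregate_and_classify(self.stream_outputs(x_semg, x_acc))

    def predict_scores(self, x_semg: np.ndarray,
                       x_acc: np.ndarray | None = None) -> ClassScores:
        self.eval()
        logits = self.forward(x_semg, x_acc)
        return classify_scores(logits.data)

    def predict(self, x_semg: np.ndarray, x_acc: np.ndarray | None = None) -> np.ndarray:
        return self.predict_scores(x_semg, x_acc).m0


def build_model(cfg: ModelConfig) -> MCBAMGRU:
    """Construct the model with seeded, reproducible initialization."""
    return MCBAMGRU(cfg)


@dataclass(frozen=True)
class TrainOptions:
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 10
    seed: int = 0


@dataclass
class TrainingHistory:
    epoch: list[int] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        d = {"epoch": self.epoch, "loss": self.loss, "train_acc": self.train_acc}
        if self.val_acc:
            d["val_acc"] = self.val_acc
        return pd.DataFrame(d)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def train_model(
    model: MCBAMGRU,
    x_semg: np.ndarray,
    y: np.ndarray,
    x_acc: np.ndarray | None = None,
    val: tuple | None = None,
    opts: TrainOptions = TrainOptions(),
) -> TrainingHistory:
    """Supervised training with Adam on softmax cross-entropy.

    ``y`` holds 1-based gesture ids; every class in the model's label space
    must appear at least once in the training set. Runs with identical
    (model seed, data, opts seed) reproduce final weights bit-for-bit.
    """
    y = np.asarray(y, dtype=int)
    present = np.unique(y)
    expected = np.arange(1, model.cfg.n_classes + 1)
    missing = np.setdiff1d(expected, present)
    if missing.size:
        raise ValueError(f"classes absent from training set: {missing.tolist()}")
    labels0 = y - 1
    rng = np.random.default_rng(np.random.SeedSequence([opts.seed, 23]))
    model.reseed_dropout(opts.seed)
    optimizer = Adam(model.parameters(), lr=opts.lr)
    history = TrainingHistory()
    n = len(y)
    for epoch in range(opts.epochs):
        model.train()
        losses = []
        n_correct = 0
        for idx in _batches(n, opts.batch_size, rng):
            xb = x_semg[idx]
            ab = None if x_acc is None else x_acc[idx]
            optimizer.zero_grad()
            logits = model.forward(xb, ab)
            loss = cross_entropy(logits, labels0[idx])
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
            n_correct += int((logits.data.argmax(axis=1) == labels0[idx]).sum())
        # train accuracy from the training-pass logits (dropout active), so
        # an epoch costs one forward/backward sweep
        train_acc = n_correct / n
        history.epoch.append(epoch)
        history.loss.append(float(np.mean(losses)))
        history.train_acc.append(train_acc)
        if val is not None:
            vx, vy, vacc_in = (val + (None,))[:3]
            vacc, _ = evaluate_confusion(model, vx, vy, vacc_in)
            history.val_acc.append(vacc)
    model.eval()
    return history


def evaluate_confusion(
    model: MCBAMGRU,
    x_semg: np.ndarray,
    y: np.ndarray,
    x_acc: np.ndarray | None = None,
    batch_size: int = 256,
) -> tuple[float, np.ndarray]:
    """Accuracy and M×M confusion matrix (rows actual, columns predicted).

    Accuracy is the matrix trace over the total count.
    """
    model.eval()
    y = np.asarray(y, dtype=int)
    m = model.cfg.n_classes
    confusion = np.zeros((m, m), dtype=int)
    for i in range(0, len(y), batch_size):
        xb = x_semg[i : i + batch_size]
        ab = None if x_acc is None else x_acc[i : i + batch_size]
        pred = model.predict(xb, ab)
        for actual, predicted in zip(y[i : i + batch_size], pred):
            confusion[actual - 1, predicted - 1] += 1
    total = confusion.sum()
    accuracy = float(np.trace(confusion) / total) if total else 0.0
    return accuracy, confusion


def ablation_config(experiment: int, base: ModelConfig) -> ModelConfig:
    """Configs of the five ablation topologies (1..5), differing only in
    the stated components; inputs are raw sEMG windows without ACC fusion."""
    flags = {
        1: dict(use_bn=False, use_cbam=False, use_gru=False),
        2: dict(use_bn=True, use_cbam=False, use_gru=False),
        3: dict(use_bn=True, use_cbam=False, use_gru=True),
        4: dict(use_bn=True, use_cbam=True, use_gru=False),
        5: dict(use_bn=True, use_cbam=True, use_gru=True),
    }
    if experiment not in flags:
        raise ValueError("experiment must be 1..5")
    return replace(base, use_acc=False, **flags[experiment])


def run_ablation(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    base: ModelConfig,
    seeds: list[int] | tuple[int, ...] = (0, 1, 2, 3, 4),
    opts: TrainOptions = TrainOptions(),
) -> pd.DataFrame:
    """Train the five topologies on identical data/seeds; mean accuracies.

    Returns a five-row table in the canonical order, one accuracy column
    per seed plus the seed-averaged accuracy.
    """
    rows = []
    for exp in range(1, 6):
        accs = []
        for seed in seeds:
            cfg = replace(ablation_config(exp, base), seed=int(seed))
            model = build_model(cfg)
            train_model(model, x_train, y_train, opts=replace(opts, seed=int(seed)))
            acc, _ = evaluate_confusion(model, x_test, y_test)
            accs.append(acc)
        rows.append(
            {
                "experiment": exp,
                "method": ABLATION_LABELS[exp - 1],
                **{f"seed_{s}": a for s, a in zip(seeds, accs)},
                "accuracy": float(np.mean(accs)),
            }
        )
    return pd.DataFrame(rows)


def save_checkpoint(model: MCBAMGRU, path: str | Path) -> None:
    """Single-file checkpoint: weights + embedded config JSON (.npz)."""
    cfg_json = json.dumps(
        {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(model.cfg).items()
        }
    )
    np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path: str | Path) -> MCBAMGRU:
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        state = {k: data[k] for k in data.files if k != "__config__"}
    for key in ("conv_blocks", "pool_factors"):
        cfg_dict[key] = tuple(
            tuple(b) if isinstance(b, list) else b for b in cfg_dict[key]
        )
    model = build_model(ModelConfig(**cfg_dict))
    model.load_state_dict(state)
    model.eval()
    return model
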