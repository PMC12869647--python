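"""Sequence classifiers over per-epoch qEEG feature sequences.

Two architectures, both emitting a single edema probability per patient:

* ``transformer`` — input projection, sinusoidal positional encoding,
  pre-norm encoder blocks (multi-head self-attention + feed-forward),
  mean-pooling over epochs, linear head.
* ``lstm`` — stacked LSTM layers, final hidden state, linear head.

Training follows a repeated-validation protocol: each iteration re-draws a
validation subset of training *patients* (augmented copies follow their
source patient), fits one pass over the remainder, and scores validation
loss; the parameter state with the best validation loss across all
iterations is retained.  Fine-tuning for the prediction task restarts from
a trained detection model at a reduced learning rate.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Tensor, no_grad, softplus_np

__all__ = [
    "ModelConfig",
    "TrainSample",
    "TrainedModel",
    "build_model",
    "train",
    "predict_proba",
    "fine_tune",
    "save_model",
    "load_model",
    "SequenceClassifier",
]

_STATE_VERSION = 1


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters."""

    architecture: str = "transformer"  # "transformer" | "lstm"
    input_width: int = 18 * 9
    embed_dim: int = 64
    n_heads: int = 4
    n_layers: int = 2
    hidden_dim: int = 64
    dropout: float = 0.1
    learning_rate: float = 1e-3
    batch_size: int = 16
    n_iterations: int = 150
    val_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.architecture not in ("transformer", "lstm"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if min(self.input_width, self.embed_dim, self.n_layers,
               self.hidden_dim, self.batch_size) <= 0:
            raise ValueError("model dimensions must be positive")
        if self.architecture == "transformer" and self.embed_dim % self.n_heads:
            raise ValueError("n_heads must divide embed_dim")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class TrainSample:
    """One training sequence with patient provenance.

    ``x`` is (n_epochs, input_width) of standardized features; augmented
    copies keep ``source_id`` pointing at the patient they derive from so
    split hygiene can keep them out of test/validation sets.
    """

    x: np.ndarray
    label: int
    source_id: str
    augmented: bool = False


# --------------------------------------------------------------------------
# modules


class _Param(Tensor):
    def __init__(self, data: np.ndarray) -> None:
        super().__init__(data, requires_grad=True)


def _xavier(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    lim = math.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-lim, lim, size=(n_in, n_out))


class _Linear:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int) -> None:
        self.W = _Param(_xavier(rng, n_in, n_out))
        self.b = _Param(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self) -> List[Tensor]:
        return [self.W, self.b]


class _LayerNorm:
    def __init__(self, dim: int, eps: float = 1e-5) -> None:
        self.g = _Param(np.ones(dim))
        self.b = _Param(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps).pow(-0.5) * self.g + self.b

    def params(self) -> List[Tensor]:
        return [self.g, self.b]


def _dropout(x: Tensor, p: float, rng: Optional[np.random.Generator]) -> Tensor:
    if p <= 0.0 or rng is None:
        return x
    keep = 1.0 - p
    mask = (rng.random(x.shape) < keep) / keep
    return x * mask


def _sinusoidal_pe(n_pos: int, dim: int) -> np.ndarray:
    pos = np.arange(n_pos)[:, None]
    i = np.arange(dim // 2)[None, :]
    angles = pos / np.power(10000.0, 2 * i / dim)
    pe = np.zeros((n_pos, dim))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


class _SelfAttention:
    def __init__(self, rng: np.random.Generator, dim: int, heads: int) -> None:
        self.dim, self.heads = dim, heads
        self.q = _Linear(rng, dim, dim)
        self.k = _Linear(rng, dim, dim)
        self.v = _Linear(rng, dim, dim)
        self.o = _Linear(rng, dim, dim)

    def __call__(self, x: Tensor, p_drop: float,
                 rng: Optional[np.random.Generator]) -> Tensor:
        B, T, D = x.shape
        H, dh = self.heads, self.dim // self.heads

        def split(t: Tensor) -> Tensor:  # (B,T,D) -> (B,H,T,dh)
            return t.reshape(B, T, H, dh).swapaxes(1, 2)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dh))
        att = scores.softmax(axis=-1)
        att = _dropout(att, p_drop, rng)
        out = (att @ v).swapaxes(1, 2).reshape(B, T, D)
        return self.o(out)

    def params(self) -> List[Tensor]:
        return self.q.params() + self.k.params() + self.v.params() + self.o.params()


class _EncoderBlock:
    def __init__(self, rng: np.random.Generator, dim: int, heads: int,
                 ff_mult: int = 2) -> None:
        self.ln1 = _LayerNorm(dim)
        self.att = _SelfAttention(rng, dim, heads)
        self.ln2 = _LayerNorm(dim)
        self.ff1 = _Linear(rng, dim, ff_mult * dim)
        self.ff2 = _Linear(rng, ff_mult * dim, dim)

    def __call__(self, x: Tensor, p_drop: float,
                 rng: Optional[np.random.Generator]) -> Tensor:
        x = x + _dropout(self.att(self.ln1(x), p_drop, rng), p_drop, rng)
        h = self.ff2(self.ff1(self.ln2(x)).relu())
        return x + _dropout(h, p_drop, rng)

    def params(self) -> List[Tensor]:
        return (self.ln1.params() + self.att.params() + self.ln2.params()
                + self.ff1.params() + self.ff2.params())


class _LSTMLayer:
    """One LSTM layer with fused gate projections (order: i, f, g, o)."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_h: int) -> None:
        self.n_h = n_h
        self.wx = _Linear(rng, n_in, 4 * n_h)
        self.wh = _Linear(rng, n_h, 4 * n_h)
        self.wx.b.data[n_h:2 * n_h] = 1.0  # forget-gate bias

    def __call__(self, xs: List[Tensor]) -> List[Tensor]:
        B = xs[0].shape[0]
        nh = self.n_h
        h = Tensor(np.zeros((B, nh)))
        c = Tensor(np.zeros((B, nh)))
        out = []
        for x in xs:
            z = self.wx(x) + self.wh(h)
            i = z.slice_last(0, nh).sigmoid()
            f = z.slice_last(nh, 2 * nh).sigmoid()
            g = z.slice_last(2 * nh, 3 * nh).tanh()
            o = z.slice_last(3 * nh, 4 * nh).sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            out.append(h)
        return out

    def params(self) -> List[Tensor]:
        return self.wx.params() + self.wh.params()


class SequenceClassifier:
    """Either architecture behind one forward interface (logit output)."""

    def __init__(self, config: ModelConfig) -> None:
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.architecture = config.architecture
        if config.architecture == "transformer":
            self.proj = _Linear(rng, config.input_width, config.embed_dim)
            self.blocks = [_EncoderBlock(rng, config.embed_dim, config.n_heads)
                           for _ in range(config.n_layers)]
            self.ln_f = _LayerNorm(config.embed_dim)
            self.head = _Linear(rng, config.embed_dim, 1)
        else:
            dims = [config.input_width] + [config.hidden_dim] * config.n_layers
            self.lstm = [_LSTMLayer(rng, dims[i], dims[i + 1])
                         for i in range(config.n_layers)]
            self.head = _Linear(rng, config.hidden_dim, 1)

    def params(self) -> List[Tensor]:
        if self.architecture == "transformer":
            ps = self.proj.params() + self.ln_f.params() + self.head.params()
            for b in self.blocks:
                ps += b.params()
            return ps
        ps = self.head.params()
        for l in self.lstm:
            ps += l.params()
        return ps

    def logits(self, x: np.ndarray,
               rng: Optional[np.random.Generator] = None) -> Tensor:
        """Forward pass; ``x`` is (B, T, input_width).  ``rng`` enables dropout."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[2] != self.config.input_width:
            raise ValueError(
                f"expected (B, T, {self.config.input_width}), got {x.shape}")
        if x.shape[1] == 0:
            raise ValueError("zero-length sequence")
        B, T, _ = x.shape
        p = self.config.dropout
        if self.architecture == "transformer":
            h = self.proj(Tensor(x))
            h = h + Tensor(_sinusoidal_pe(T, self.config.embed_dim)[None])
            h = _dropout(h, p, rng)
            for blk in self.blocks:
                h = blk(h, p, rng)
            pooled = self.ln_f(h).mean(axis=1)
            return self.head(pooled).reshape(B)
        xs = [Tensor(x[:, t, :]) for t in range(T)]
        for li, layer in enumerate(self.lstm):
            xs = layer(xs)
            if li < len(self.lstm) - 1:
                xs = [_dropout(h, p, rng) for h in xs]
        return self.head(xs[-1]).reshape(B)

    def state_dict(self) -> List[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def load_state(self, state: Sequence[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(state):
            raise ValueError("state does not match architecture")
        for p, s in zip(own, state):
            if p.data.shape != s.shape:
                raise ValueError("state does not match architecture")
            p.data = s.copy()


def build_model(config: ModelConfig) -> SequenceClassifier:
    """Untrained classifier with seeded initialization."""
    return SequenceClassifier(config)


# --------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params: List[Tensor], lr: float,
                 betas: Tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _bce_with_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    # mean( softplus(z) - y*z )
    return (logits.softplus() - logits * y).mean()


def _eval_loss(model: SequenceClassifier, samples: Sequence[TrainSample]) -> float:
    if not samples:
        return math.nan
    x = np.stack([s.x for s in samples])
    y = np.array([s.label for s in samples], dtype=float)
    with no_grad():
        z = model.logits(x).data
    return float(np.mean(softplus_np(z) - y * z))


@dataclass
class TrainedModel:
    """A fitted classifier plus its training provenance."""

    model: SequenceClassifier
    config: ModelConfig
    history: List[Dict[str, float]] = field(default_factory=list)
    best_val_loss: float = math.inf
    final_train_loss: float = math.nan

    @property
    def architecture(self) -> str:
        return self.model.architecture


def train(model: SequenceClassifier, samples: Sequence[TrainSample],
          config: Optional[ModelConfig] = None,
          lr_override: Optional[float] = None) -> TrainedModel:
    """Repeated-validation training; retains the best-validation state.

    Per iteration: draw ``val_fraction`` of training *patients* as the
    validation subset (augmented copies follow their source), run one
    minibatch pass over the remaining samples, then score validation loss.
    """
    config = config or model.config
    if not samples:
        raise ValueError("empty training set")
    labels = {s.label for s in samples}
    if labels != {0, 1}:
        raise ValueError("training set must contain both classes")
    lr = lr_override if lr_override is not None else config.learning_rate
    rng = np.random.default_rng(config.seed + 1)
    patient_ids = sorted({s.source_id for s in samples})
    opt = _Adam(model.params(), lr)
    best_state = model.state_dict()
    best_val = math.inf
    history: List[Dict[str, float]] = []
    n_val = max(int(round(config.val_fraction * len(patient_ids))), 1)
    if n_val >= len(patient_ids):
        n_val = len(patient_ids) - 1
    for it in range(config.n_iterations):
        val_ids = set(rng.choice(patient_ids, size=n_val, replace=False))
        fit = [s for s in samples if s.source_id not in val_ids]
        val = [s for s in samples if s.source_id in val_ids]
        if not any(s.label == 1 for s in fit) or not any(s.label == 0 for s in fit):
            fit = list(samples)  # degenerate draw on tiny cohorts
        order = rng.permutation(len(fit))
        train_loss = 0.0
        n_batches = 0
        for b0 in range(0, len(fit), config.batch_size):
            batch = [fit[i] for i in order[b0:b0 + config.batch_size]]
            x = np.stack([s.x for s in batch])
            y = np.array([s.label for s in batch], dtype=float)
            opt.zero_grad()
            z = model.logits(x, rng=rng if config.dropout > 0 else None)
            loss = _bce_with_logits(z, y)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at iteration {it}")
            loss.backward()
            opt.step()
            train_loss += float(loss.data)
            n_batches += 1
        train_loss /= max(n_batches, 1)
        val_loss = _eval_loss(model, val) if val else train_loss
        history.append({"iteration": it, "train_loss": train_loss,
                        "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
    model.load_state(best_state)
    return TrainedModel(model=model, config=config, history=history,
                        best_val_loss=best_val,
                        final_train_loss=_eval_loss(model, samples))


def predict_proba(trained: "TrainedModel | SequenceClassifier",
                  x: np.ndarray) -> np.ndarray:
    """Edema probability per sample; dropout disabled."""
    model = trained.model if isinstance(trained, TrainedModel) else trained
    with no_grad():
        z = model.logits(np.asarray(x))
    return 1.0 / (1.0 + np.exp(-np.clip(z.data, -60, 60)))


def fine_tune(source: TrainedModel, samples: Sequence[TrainSample],
              config: Optional[ModelConfig] = None,
              lr_scale: float = 0.1) -> TrainedModel:
    """Continue training from a detection model at a reduced learning rate."""
    config = config or source.config
    if config.architecture != source.architecture:
        raise ValueError("architecture mismatch between source and fine-tune config")
    model = SequenceClassifier(config)
    model.load_state(source.model.state_dict())
    if config.n_iterations == 0:
        return TrainedModel(model=model, config=config,
                            best_val_loss=source.best_val_loss,
                            final_train_loss=_eval_loss(model, samples))
    return train(model, samples, config,
                 lr_override=config.learning_rate * lr_scale)


# --------------------------------------------------------------------------
# persistence


def save_model(trained: TrainedModel, path: str) -> None:
    """Versioned binary container (npz) + adjacent JSON config echo."""
    arrays = {f"p{i}": a for i, a in enumerate(trained.model.state_dict())}
    np.savez(path, _version=np.array(_STATE_VERSION), **arrays)
    with open(str(path) + ".json", "w") as fh:
        json.dump(asdict(trained.config), fh, indent=2)


def load_model(path: str) -> TrainedModel:
    with open(str(path) + ".json") as fh:
        config = ModelConfig(**json.load(fh))
    with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as z:
        if int(z["_version"]) != _STATE_VERSION:
            raise ValueError("unsupported model container version")
        state = [z[f"p{i}"] for i in range(len(z.files) - 1)]
    model = SequenceClassifier(config)
    model.load_state(state)
    return TrainedModel(model=model, config=config)
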