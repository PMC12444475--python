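"""Adversarially regularised Transformer classifier for E-P pairs.

The generator projects each pair's 11 standardised features to a hidden
width of 64, passes them through two Transformer encoder layers (two
attention heads each, dropout 0.1), and maps the encoding through a
64 -> 32 -> 1 head (ReLU, dropout 0.2, sigmoid) to a probability of
regulatory interaction.  A label-conditioned discriminator — an MLP over
the 11 features concatenated with either the true label ("real") or the
generator's score ("generated"), layers 12 -> 64 -> 32 -> 1 with LeakyReLU
0.2 and dropout 0.3 — is trained to tell the two apart.  The generator
minimises its supervised binary cross-entropy plus ``lambda_adv`` times an
adversarial term that rewards fooling the discriminator; this adversarial
pressure regularises the score distribution rather than synthesising data.

By default the projected vector enters the encoder as a length-1 sequence
(self-attention then degenerates to a gated feed-forward path); a
feature-as-token layout (11 tokens, learned per-feature embeddings, mean
pooling) is available via ``GeneratorSpec.token_layout``.

Training is fully deterministic given (data, config, seed): parameter
initialisation, batch composition and dropout masks each draw from their
own seeded generator stream, so disabling the discriminator does not
perturb the generator's randomness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .autodiff import Tensor, Adam, concat, backward, zero_grads

__all__ = ["GeneratorSpec", "DiscriminatorSpec", "TrainConfig", "TrainedModel",
           "generator_forward", "discriminator_forward", "balanced_batches",
           "train", "predict", "save_checkpoint", "load_checkpoint",
           "load_train_config"]


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class GeneratorSpec:
    input_dim: int = 11
    hidden: int = 64
    n_encoder_layers: int = 2
    n_heads: int = 2
    encoder_dropout: float = 0.1
    ff_dim: int = 128
    head_hidden: int = 32
    head_dropout: float = 0.2
    token_layout: str = "scalar"      # "scalar" (length-1 sequence) or "per_feature"

    def __post_init__(self):
        if self.hidden % self.n_heads:
            raise ValueError("hidden must be divisible by n_heads")
        if self.token_layout not in ("scalar", "per_feature"):
            raise ValueError("token_layout must be 'scalar' or 'per_feature'")


@dataclass(frozen=True)
class DiscriminatorSpec:
    input_dim: int = 12               # 11 features + score-or-label
    hidden: tuple[int, ...] = (64, 32)
    slope: float = 0.2
    dropout: float = 0.3


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 2e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    epochs: int = 20
    batch_size: int = 32
    patience: int = 5
    min_delta: float = 1e-4
    lambda_adv: float = 1.0
    val_fraction: float = 0.125
    adversarial: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0 or self.epochs < 1 or self.batch_size < 2:
            raise ValueError("invalid training configuration")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")


def load_train_config(path) -> TrainConfig:
    """Training configuration from a YAML mapping of field name -> value."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return TrainConfig(**data)


@dataclass
class TrainedModel:
    gspec: GeneratorSpec
    dspec: DiscriminatorSpec | None
    config: TrainConfig
    gparams: dict[str, np.ndarray]
    dparams: dict[str, np.ndarray] | None
    history: dict[str, list[float]]
    best_epoch: int


# ---------------------------------------------------------------------------
# initialisation


def _linear_init(rng, fan_in, fan_out):
    bound = 1.0 / np.sqrt(fan_in)
    w = rng.uniform(-bound, bound, size=(fan_in, fan_out))
    b = rng.uniform(-bound, bound, size=(fan_out,))
    return w, b


def init_generator(spec: GeneratorSpec, rng) -> dict[str, np.ndarray]:
    p: dict[str, np.ndarray] = {}
    h = spec.hidden
    if spec.token_layout == "scalar":
        p["in.w"], p["in.b"] = _linear_init(rng, spec.input_dim, h)
    else:
        bound = 1.0 / np.sqrt(spec.input_dim)
        p["tok.embed"] = rng.uniform(-bound, bound, size=(spec.input_dim, h))
        p["tok.bias"] = rng.uniform(-bound, bound, size=(spec.input_dim, h))
    for layer in range(spec.n_encoder_layers):
        pre = f"enc{layer}."
        for name in ("q", "k", "v", "o"):
            p[pre + name + ".w"], p[pre + name + ".b"] = _linear_init(rng, h, h)
        p[pre + "ff1.w"], p[pre + "ff1.b"] = _linear_init(rng, h, spec.ff_dim)
        p[pre + "ff2.w"], p[pre + "ff2.b"] = _linear_init(rng, spec.ff_dim, h)
        for ln in ("ln1", "ln2"):
            p[pre + ln + ".g"] = np.ones(h)
            p[pre + ln + ".b"] = np.zeros(h)
    p["head1.w"], p["head1.b"] = _linear_init(rng, h, spec.head_hidden)
    p["head2.w"], p["head2.b"] = _linear_init(rng, spec.head_hidden, 1)
    return p


def init_discriminator(spec: DiscriminatorSpec, rng) -> dict[str, np.ndarray]:
    p: dict[str, np.ndarray] = {}
    dims = (spec.input_dim, *spec.hidden, 1)
    for i in range(len(dims) - 1):
        p[f"l{i}.w"], p[f"l{i}.b"] = _linear_init(rng, dims[i], dims[i + 1])
    return p


def _as_tensors(params: dict[str, np.ndarray]) -> dict[str, Tensor]:
    return {k: Tensor(v) for k, v in params.items()}


# ---------------------------------------------------------------------------
# forward passes


def _dropout(t: Tensor, p: float, train: bool, rng) -> Tensor:
    if not train or p <= 0:
        return t
    mask = (rng.random(t.shape) >= p) / (1.0 - p)
    return t * Tensor(mask)


def _layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    h = x.shape[-1]
    mu = x.sum(axis=-1, keepdims=True) * (1.0 / h)
    xc = x - mu
    var = (xc * xc).sum(axis=-1, keepdims=True) * (1.0 / h)
    return xc / (var + eps).pow_const(0.5) * gamma + beta


def _attention(h: Tensor, p: dict[str, Tensor], prefix: str, n_heads: int) -> Tensor:
    b, length, hid = h.shape
    dh = hid // n_heads

    def heads(t: Tensor) -> Tensor:
        return t.reshape((b, length, n_heads, dh)).transpose((0, 2, 1, 3))

    q = heads(h @ p[prefix + "q.w"] + p[prefix + "q.b"])
    k = heads(h @ p[prefix + "k.w"] + p[prefix + "k.b"])
    v = heads(h @ p[prefix + "v.w"] + p[prefix + "v.b"])
    scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(dh))
    attn = scores.softmax()
    out = (attn @ v).transpose((0, 2, 1, 3)).reshape((b, length, hid))
    return out @ p[prefix + "o.w"] + p[prefix + "o.b"]


def _encoder_layer(h: Tensor, p: dict[str, Tensor], prefix: str,
                   spec: GeneratorSpec, train: bool, rng) -> Tensor:
    a = _attention(h, p, prefix, spec.n_heads)
    a = _dropout(a, spec.encoder_dropout, train, rng)
    h = _layer_norm(h + a, p[prefix + "ln1.g"], p[prefix + "ln1.b"])
    f = (h @ p[prefix + "ff1.w"] + p[prefix + "ff1.b"]).relu()
    f = f @ p[prefix + "ff2.w"] + p[prefix + "ff2.b"]
    f = _dropout(f, spec.encoder_dropout, train, rng)
    return _layer_norm(h + f, p[prefix + "ln2.g"], p[prefix + "ln2.b"])


def generator_forward(x, params: dict[str, Tensor], spec: GeneratorSpec,
                      train: bool = False, rng=None) -> Tensor:
    """Scores in (0, 1) for a batch of feature rows (n x input_dim)."""
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[1] != spec.input_dim:
        raise ValueError(f"expected {spec.input_dim} features, got {x.shape[1]}")
    if not np.isfinite(x).all():
        raise ValueError("non-finite feature values")
    n = x.shape[0]
    xt = Tensor(x)
    if spec.token_layout == "scalar":
        h = (xt @ params["in.w"] + params["in.b"]).reshape((n, 1, spec.hidden))
    else:
        h = xt.reshape((n, spec.input_dim, 1)) * params["tok.embed"] + params["tok.bias"]
    for layer in range(spec.n_encoder_layers):
        h = _encoder_layer(h, params, f"enc{layer}.", spec, train, rng)
    pooled = h.sum(axis=1) * (1.0 / h.shape[1])
    z = (pooled @ params["head1.w"] + params["head1.b"]).relu()
    z = _dropout(z, spec.head_dropout, train, rng)
    return (z @ params["head2.w"] + params["head2.b"]).sigmoid()


def discriminator_forward(x, score_or_label, params: dict[str, Tensor],
                          spec: DiscriminatorSpec, train: bool = False,
                          rng=None) -> Tensor:
    """Realness in (0, 1) for feature rows concatenated with a score/label."""
    x = np.atleast_2d(np.asarray(x, float))
    if not np.isfinite(x).all():
        raise ValueError("non-finite feature values")
    if isinstance(score_or_label, Tensor):
        y = score_or_label
    else:
        y = Tensor(np.asarray(score_or_label, float).reshape(x.shape[0], 1))
    h = concat([Tensor(x), y], axis=1)
    if h.shape[1] != spec.input_dim:
        raise ValueError(f"expected {spec.input_dim} inputs, got {h.shape[1]}")
    n_layers = len(spec.hidden)
    for i in range(n_layers):
        h = (h @ params[f"l{i}.w"] + params[f"l{i}.b"]).leaky_relu(spec.slope)
        h = _dropout(h, spec.dropout, train, rng)
    return (h @ params[f"l{n_layers}.w"] + params[f"l{n_layers}.b"]).sigmoid()


_EPS = 1e-7


def bce(p: Tensor, y) -> Tensor:
    """Mean binary cross-entropy of probabilities against 0/1 targets."""
    y = np.asarray(y, float).reshape(p.shape)
    term = Tensor(y) * (p + _EPS).log() + Tensor(1.0 - y) * (1.0 - p + _EPS).log()
    return -term.mean()


# ---------------------------------------------------------------------------
# batching


def balanced_batches(X: np.ndarray, y: np.ndarray, batch_size: int, rng):
    """Class-balanced minibatches.

    Every full batch holds ceil(b/2) positives and floor(b/2) negatives.
    The majority class is consumed exactly once per epoch without
    replacement; the minority class is recycled through reshuffled
    repetitions.  A final partial batch drains the majority remainder with
    a proportional number of minority rows.
    """
    y = np.asarray(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present for balanced batching")
    per_pos = int(np.ceil(batch_size / 2))
    per_neg = batch_size // 2

    def stream(idx):
        while True:
            for i in rng.permutation(idx):
                yield i

    pos_major = pos.size >= neg.size
    major, minor = (pos, neg) if pos_major else (neg, pos)
    per_major, per_minor = (per_pos, per_neg) if pos_major else (per_neg, per_pos)
    major_order = rng.permutation(major)
    minor_stream = stream(minor)

    batches = []
    start = 0
    while start < major_order.size:
        take = min(per_major, major_order.size - start)
        m_idx = major_order[start:start + take]
        start += take
        if take == per_major:
            k = per_minor
        else:  # partial final batch: keep the class ratio
            k = max(1, int(round(take * per_minor / per_major)))
        s_idx = np.array([next(minor_stream) for _ in range(k)])
        idx = np.concatenate([m_idx, s_idx]) if pos_major else np.concatenate([s_idx, m_idx])
        idx = rng.permutation(idx)
        batches.append((X[idx], y[idx]))
    return batches


# ---------------------------------------------------------------------------
# training


def _stratified_val_split(y: np.ndarray, val_fraction: float, rng):
    train_idx, val_idx = [], []
    for cls in (0, 1):
        idx = rng.permutation(np.flatnonzero(y == cls))
        k = max(1, int(np.floor(val_fraction * idx.size)))
        val_idx.extend(idx[:k])
        train_idx.extend(idx[k:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(val_idx))


def train(table, gspec: GeneratorSpec | None = None,
          dspec: DiscriminatorSpec | None = None,
          config: TrainConfig | None = None) -> TrainedModel:
    """Adversarial (or plain supervised) training on a labelled feature table.

    Per batch, the discriminator takes one Adam step on
    ``BCE(D(x, y), 1) + BCE(D(x, G(x)), 0)`` with the generator frozen,
    then the generator takes one step on
    ``BCE(G(x), y) + lambda_adv * BCE(D(x, G(x)), 1)`` with the
    discriminator frozen.  After each epoch the generator's validation BCE
    is computed in eval mode; training stops once it fails to improve by
    ``min_delta`` for ``patience`` epochs, and the best-epoch generator
    parameters are restored.
    """
    gspec = gspec or GeneratorSpec()
    config = config or TrainConfig()
    adversarial = config.adversarial
    if adversarial:
        dspec = dspec or DiscriminatorSpec(input_dim=gspec.input_dim + 1)

    X = table.X_std
    y = np.asarray(table.labels, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("training rows must be labelled 0/1")

    ss = np.random.SeedSequence(config.seed)
    s_data, s_g, s_d = ss.spawn(3)
    rng_data = np.random.default_rng(s_data)
    rng_g = np.random.default_rng(s_g)
    rng_d = np.random.default_rng(s_d)

    gparams = _as_tensors(init_generator(gspec, rng_g))
    dparams = _as_tensors(init_discriminator(dspec, rng_d)) if adversarial else None

    tr_idx, val_idx = _stratified_val_split(y.astype(int), config.val_fraction, rng_data)
    X_tr, y_tr = X[tr_idx], y[tr_idx]
    X_val, y_val = X[val_idx], y[val_idx]

    opt_g = Adam(gparams, config.lr, config.adam_beta1, config.adam_beta2)
    opt_d = Adam(dparams, config.lr, config.adam_beta1, config.adam_beta2) if adversarial else None

    history = {"g_loss": [], "d_loss": [], "val_loss": []}
    best_val = np.inf
    best_epoch = -1
    best_params: dict[str, np.ndarray] = {}
    stale = 0

    for epoch in range(config.epochs):
        g_losses, d_losses = [], []
        for xb, yb in balanced_batches(X_tr, y_tr, config.batch_size, rng_data):
            if adversarial:
                frozen_scores = generator_forward(xb, gparams, gspec, train=False).data
                d_real = discriminator_forward(xb, yb, dparams, dspec,
                                               train=True, rng=rng_d)
                d_fake = discriminator_forward(xb, frozen_scores, dparams, dspec,
                                               train=True, rng=rng_d)
                d_loss = bce(d_real, np.ones(len(xb))) + bce(d_fake, np.zeros(len(xb)))
                _check_finite(d_loss, "discriminator loss")
                zero_grads(dparams)
                backward(d_loss)
                opt_d.step()
                d_losses.append(float(d_loss.data))

            p = generator_forward(xb, gparams, gspec, train=True, rng=rng_g)
            g_loss = bce(p, yb)
            if adversarial and config.lambda_adv != 0:
                d_out = discriminator_forward(xb, p, dparams, dspec, train=False)
                g_loss = g_loss + config.lambda_adv * bce(d_out, np.ones(len(xb)))
            _check_finite(g_loss, "generator loss")
            zero_grads(gparams)
            backward(g_loss)
            opt_g.step()
            g_losses.append(float(g_loss.data))

        val_loss = float(bce(generator_forward(X_val, gparams, gspec), y_val).data)
        history["g_loss"].append(float(np.mean(g_losses)))
        if d_losses:
            history["d_loss"].append(float(np.mean(d_losses)))
        history["val_loss"].append(val_loss)

        if best_val - val_loss >= config.min_delta:
            best_val = val_loss
            best_epoch = epoch
            best_params = {k: t.data.copy() for k, t in gparams.items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break

    if best_epoch < 0:  # validation never improved; keep the final state
        best_epoch = len(history["val_loss"]) - 1
        best_params = {k: t.data.copy() for k, t in gparams.items()}

    return TrainedModel(
        gspec=gspec,
        dspec=dspec if adversarial else None,
        config=config,
        gparams=best_params,
        dparams={k: t.data.copy() for k, t in dparams.items()} if adversarial else None,
        history=history,
        best_epoch=best_epoch,
    )


def _check_finite(loss: Tensor, what: str) -> None:
    if not np.isfinite(loss.data).all():
        raise FloatingPointError(f"non-finite {what}")


def predict(model: TrainedModel, table_or_X, batch_size: int = 512) -> np.ndarray:
    """Eval-mode scores aligned to the table's rows, each in (0, 1)."""
    X = table_or_X if isinstance(table_or_X, np.ndarray) else table_or_X.X_std
    if X.shape[1] != model.gspec.input_dim:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model input {model.gspec.input_dim}"
        )
    params = _as_tensors(model.gparams)
    out = []
    for start in range(0, X.shape[0], batch_size):
        chunk = X[start:start + batch_size]
        out.append(generator_forward(chunk, params, model.gspec).data.ravel())
    return np.concatenate(out) if out else np.empty(0)


# ---------------------------------------------------------------------------
# checkpoint serialisation (single file: JSON header + raw little-endian arrays)

_MAGIC = b"EPLINKCKPT1\n"


def save_checkpoint(model: TrainedModel, path) -> None:
    arrays: dict[str, np.ndarray] = {f"g/{k}": v for k, v in model.gparams.items()}
    if model.dparams is not None:
        arrays.update({f"d/{k}": v for k, v in model.dparams.items()})
    header = {
        "gspec": asdict(model.gspec),
        "dspec": None if model.dspec is None else asdict(model.dspec),
        "config": asdict(model.config),
        "history": model.history,
        "best_epoch": model.best_epoch,
        "arrays": {k: list(v.shape) for k, v in sorted(arrays.items())},
    }
    blob = json.dumps(header, sort_keys=True).encode() + b"\n"
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(len(blob).to_bytes(8, "little"))
        fh.write(blob)
        for k in sorted(arrays):
            fh.write(np.ascontiguousarray(arrays[k], dtype="<f8").tobytes())


def load_checkpoint(path) -> TrainedModel:
    with open(path, "rb") as fh:
        if fh.read(len(_MAGIC)) != _MAGIC:
            raise ValueError(f"{path} is not an eplink checkpoint")
        n = int.from_bytes(fh.read(8), "little")
        header = json.loads(fh.read(n).decode())
        arrays = {}
        for k, shape in header["arrays"].items():
            count = int(np.prod(shape)) if shape else 1
            buf = fh.read(8 * count)
            arrays[k] = np.frombuffer(buf, dtype="<f8").reshape(shape).copy()
    cfg = header["config"]
    dspec = header["dspec"]
    return TrainedModel(
        gspec=GeneratorSpec(**header["gspec"]),
        dspec=None if dspec is None else DiscriminatorSpec(
            **{**dspec, "hidden": tuple(dspec["hidden"])}),
        config=TrainConfig(**cfg),
        gparams={k[2:]: v for k, v in arrays.items() if k.startswith("g/")},
        dparams=({k[2:]: v for k, v in arrays.items() if k.startswith("d/")}
                 or None),
        history=header["history"],
        best_epoch=header["best_epoch"],
    )
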