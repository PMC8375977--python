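"""Training recipe: Nadam + soft Dice loss, plateau LR schedule, He-uniform
initialization, and bit-exact weight serialization.

The learning rate starts at 5e-4 and is divided by 10 whenever the best
validation loss has not improved for two consecutive epochs (the stagnation
counter resets after each decay). "Trained to convergence" is
operationalized as stopping once the rate has decayed twice and validation
loss stagnates for a further patience window.
"""

from __future__ import annotations

import io
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .architectures import MoNet, MoNetConfig, UNet, build_monet, build_unet
from .data_pipeline import augment as augment_sample
from .metrics import soft_dice_loss, soft_dice_loss_grad, soft_dice_score
from .nn import BatchNorm2d, Conv2d, ConvTranspose2d, Nadam


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


class IntegrityError(RuntimeError):
    """Serialized weight container is inconsistent with its manifest."""


@dataclass
class TrainingConfig:
    initial_lr: float = 5e-4
    plateau_patience: int = 2
    decay_factor: float = 10.0
    batch_size: int = 32
    max_epochs: int = 50
    max_decays: int = 2          # early stop once a further decay would occur
    seed: int = 0
    augment: bool = True
    loss_epsilon: float = 1e-6
    init_scheme: str = "he_uniform"

    def validate(self):
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if self.decay_factor <= 1:
            raise ValueError("decay_factor must exceed 1")
        if self.plateau_patience < 1:
            raise ValueError("patience must be >= 1")
        return self


@dataclass
class TrainingHistory:
    """Per-epoch train loss, validation loss, learning rate and wall time."""

    epochs: list = field(default_factory=list)

    def append(self, **row):
        self.epochs.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @property
    def learning_rates(self):
        return [e["lr"] for e in self.epochs]

    @property
    def val_losses(self):
        return [e["val_loss"] for e in self.epochs]


# ---------------------------------------------------------------------------
# Plateau schedule
# ---------------------------------------------------------------------------

class PlateauScheduler:
    """Divide the LR by ``factor`` after ``patience`` stagnant epochs."""

    def __init__(self, initial_lr, patience=2, factor=10.0):
        if initial_lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = initial_lr
        self.patience = patience
        self.factor = factor
        self.best = np.inf
        self.wait = 0
        self.n_decays = 0

    def step(self, val_loss) -> float:
        """Record one epoch's validation loss; returns the LR to use next."""
        if val_loss < self.best:
            self.best = val_loss
            self.wait = 0
        else:
            self.wait += 1
            if self.wait >= self.patience:
                self.lr /= self.factor
                self.wait = 0
                self.n_decays += 1
        return self.lr


def plateau_scheduler_step(val_losses, current_lr, patience=2, factor=10.0):
    """Stateless form: the LR after replaying ``val_losses`` from scratch."""
    sched = PlateauScheduler(current_lr, patience, factor)
    if not len(val_losses):
        raise ValueError("history must be non-empty")
    for v in val_losses:
        sched.step(v)
    return sched.lr


def replay_lr_trace(val_losses, initial_lr, patience=2, factor=10.0):
    """LR in effect during each epoch, reconstructed from the loss trace.

    Epoch 1 runs at ``initial_lr``; each subsequent epoch runs at the rate
    produced by the schedule after the previous epoch's validation loss.
    """
    sched = PlateauScheduler(initial_lr, patience, factor)
    trace = []
    for v in val_losses:
        trace.append(sched.lr)
        sched.step(v)
    return trace


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def initialize_weights(net, seed=0, scheme="he_uniform"):
    """He-uniform init: conv weights ~ U(-sqrt(6/fan_in), +sqrt(6/fan_in)),
    zero biases, unit batch-norm scale, reset running statistics."""
    if scheme != "he_uniform":
        raise ValueError(f"unknown init scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    for _, layer in net.modules():
        if isinstance(layer, (Conv2d, ConvTranspose2d)):
            fan_in = int(np.prod(layer.weight.shape[1:]))
            bound = np.sqrt(6.0 / fan_in)
            layer.weight = rng.uniform(
                -bound, bound, size=layer.weight.shape).astype(
                    layer.weight.dtype)
            layer.bias = np.zeros_like(layer.bias)
        elif isinstance(layer, BatchNorm2d):
            layer.gamma = np.ones_like(layer.gamma)
            layer.beta = np.zeros_like(layer.beta)
            layer.running_mean = np.zeros_like(layer.running_mean)
            layer.running_var = np.ones_like(layer.running_var)
    return net


# ---------------------------------------------------------------------------
# Batching and the loop
# ---------------------------------------------------------------------------

def _to_batch(samples):
    x = np.stack([s.image for s in samples])[:, None].astype(np.float32)
    t = np.stack([s.mask for s in samples])[:, None].astype(np.float32)
    return x, t


def evaluate_loss(net, samples, batch_size=32, epsilon=1e-6):
    """Mean soft Dice loss over batches, in inference mode."""
    losses, weights = [], []
    for i in range(0, len(samples), batch_size):
        x, t = _to_batch(samples[i:i + batch_size])
        p = net.forward(x, training=False)
        losses.append(soft_dice_loss(p, t, epsilon))
        weights.append(len(x))
    return float(np.average(losses, weights=weights))


def train(net, train_samples, val_samples, cfg: TrainingConfig):
    """Minimize soft Dice loss with Nadam under the plateau LR schedule.

    Returns ``(net, TrainingHistory)``. Augmentation is applied to training
    batches only; every random draw flows from ``cfg.seed``.
    """
    cfg.validate()
    if not train_samples or not val_samples:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng([cfg.seed, 1])
    aug_rng = np.random.default_rng([cfg.seed, 2])
    drop_rng = np.random.default_rng([cfg.seed, 3])
    initialize_weights(net, seed=cfg.seed, scheme=cfg.init_scheme)
    opt = Nadam(net, lr=cfg.initial_lr)
    sched = PlateauScheduler(cfg.initial_lr, cfg.plateau_patience,
                             cfg.decay_factor)
    history = TrainingHistory()
    for epoch in range(1, cfg.max_epochs + 1):
        t0 = time.perf_counter()
        order = rng.permutation(len(train_samples))
        epoch_losses = []
        lr_epoch = sched.lr
        opt.lr = lr_epoch
        for i in range(0, len(order), cfg.batch_size):
            batch = [train_samples[j] for j in order[i:i + cfg.batch_size]]
            if cfg.augment:
                batch = [augment_sample(s, rng=aug_rng) for s in batch]
            x, t = _to_batch(batch)
            p = net.forward(x, training=True, rng=drop_rng)
            loss = soft_dice_loss(p, t, cfg.loss_epsilon)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"loss became non-finite at epoch {epoch}")
            g = soft_dice_loss_grad(p, t, cfg.loss_epsilon).astype(np.float32)
            net.zero_grad()
            net.backward(g)
            opt.step()
            epoch_losses.append(loss)
        val_loss = evaluate_loss(net, val_samples, cfg.batch_size,
                                 cfg.loss_epsilon)
        history.append(epoch=epoch, train_loss=float(np.mean(epoch_losses)),
                       val_loss=val_loss, lr=lr_epoch,
                       seconds=time.perf_counter() - t0)
        prev_decays = sched.n_decays
        sched.step(val_loss)
        if sched.n_decays > prev_decays and prev_decays >= cfg.max_decays:
            break  # converged: a further decay beyond the budget triggered
    return net, history


def fit_fixed_batch(samples, widths=(4, 8, 16), steps=300, lr=5e-3,
                    seed=0, check_every=10, target_score=None,
                    dropout=0.0):
    """Overfit harness: full-batch Nadam on a fixed set of slices.

    Trains a narrow MoNet on ``samples`` (no augmentation, no dropout) and
    records the training soft-Dice score every ``check_every`` steps; stops
    early once ``target_score`` is reached. Returns (net, scores) where
    ``scores`` maps step -> soft-Dice score. The learning rate is higher
    than the full recipe's initial rate: full-batch descent on a handful of
    fixed slices tolerates (and needs) a more aggressive step size.
    """
    config = MoNetConfig(widths=tuple(widths), dropout=dropout)
    net = build_monet(config)
    initialize_weights(net, seed=seed)
    drop_rng = np.random.default_rng([seed, 3])
    opt = Nadam(net, lr=lr)
    x, t = _to_batch(samples)
    scores = {}
    for step in range(1, steps + 1):
        p = net.forward(x, training=True, rng=drop_rng)
        loss = soft_dice_loss(p, t)
        if not np.isfinite(loss):
            raise TrainingDivergedError(f"loss non-finite at step {step}")
        net.zero_grad()
        net.backward(soft_dice_loss_grad(p, t).astype(np.float32))
        opt.step()
        if step % check_every == 0 or step == steps:
            score = soft_dice_score(net.forward(x, training=False), t)
            scores[step] = float(score)
            if target_score is not None and score >= target_score:
                break
    return net, scores


# ---------------------------------------------------------------------------
# Weight serialization (.monet container)
# ---------------------------------------------------------------------------

_MAGIC = b"MONETW1\n"


def _architecture_descriptor(net):
    if isinstance(net, MoNet):
        return {"kind": "monet", "config": asdict(net.config)}
    if isinstance(net, UNet):
        return {"kind": "unet", "base_filters": net.base_filters}
    return {"kind": "custom"}


def serialize_weights(net, path) -> int:
    """Write a JSON manifest + little-endian float32 payload; returns bytes.

    The payload concatenates every registered tensor (including batch-norm
    running statistics) in enumeration order, so its length is exactly
    4 bytes per counted parameter.
    """
    tensors = list(net.named_tensors())
    manifest = {
        "format": "monet-weights-v1",
        "architecture": _architecture_descriptor(net),
        "dtype": "<f4",
        "tensors": [{"name": n, "shape": list(a.shape),
                     "trainable": bool(tr)} for n, a, tr in tensors],
    }
    mbytes = json.dumps(manifest, separators=(",", ":")).encode()
    payload = b"".join(
        np.ascontiguousarray(a, dtype="<f4").tobytes() for _, a, _ in tensors)
    blob = (_MAGIC + len(mbytes).to_bytes(8, "little") + mbytes + payload)
    if hasattr(path, "write"):
        path.write(blob)
    else:
        Path(path).write_bytes(blob)
    return len(blob)


def deserialize_weights(path):
    """Rebuild the architecture named in the manifest and load its weights.

    The round trip is bit-exact for float32 networks; a payload whose length
    disagrees with the manifest raises :class:`IntegrityError`.
    """
    raw = path.read() if hasattr(path, "read") else Path(path).read_bytes()
    if not raw.startswith(_MAGIC):
        raise IntegrityError("not a .monet weight container")
    off = len(_MAGIC)
    mlen = int.from_bytes(raw[off:off + 8], "little")
    off += 8
    manifest = json.loads(raw[off:off + mlen].decode())
    off += mlen
    payload = raw[off:]
    n_expected = sum(int(np.prod(t["shape"])) for t in manifest["tensors"])
    if len(payload) != 4 * n_expected:
        raise IntegrityError(
            f"payload holds {len(payload)} bytes, manifest expects "
            f"{4 * n_expected}")
    arch = manifest["architecture"]
    if arch["kind"] == "monet":
        cfg = dict(arch["config"])
        for key in ("widths", "dilations"):
            cfg[key] = tuple(cfg[key])
        net = build_monet(MoNetConfig(**cfg))
    elif arch["kind"] == "unet":
        net = build_unet(arch["base_filters"])
    else:
        raise IntegrityError("container does not name a known architecture")
    state, pos = {}, 0
    for t in manifest["tensors"]:
        n = int(np.prod(t["shape"]))
        state[t["name"]] = np.frombuffer(
            payload, dtype="<f4", count=n, offset=4 * pos
        ).reshape(t["shape"])
        pos += n
    net.load_state_dict(state)
    return net


def serialized_size_bytes(net) -> int:
    buf = io.BytesIO()
    return serialize_weights(net, buf)
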