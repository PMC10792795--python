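"""Component 2: convolutional refinement of the statistical keypoint prior.

The refiner is a small depthwise-separable convolution network (entry-flow
style residual blocks, global average pooling, a linear head) that runs on a
plain CPU.  It consumes a 7-channel encoding of one molar crop — the
intensity-standardized image plus six Gaussian heatmaps marking the prior's
keypoint guesses — and emits a correction to the prior: the output vector is
``prior + delta`` with ``delta`` produced by the linear head, so an untrained
network reproduces the prior exactly and training only has to learn
image-conditioned corrections.  Two normalized coordinate grids are appended
internally before the first convolution so that pooled features can carry
positional information.

Training minimizes the mean squared error between the predicted and labeled
12-value keypoint vectors with an Adam optimizer, a fixed batch size and
early stopping on a held-out validation split (split at the image level so
that augmented copies of one molar never straddle the split).  Slots whose
side was never labeled are masked out of the loss.  All computation is plain
numpy, so runs with the same seed are reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from perioloss.prior import TrainingExample

_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8


@dataclass
class RefinerConfig:
    """Architecture and optimization settings for the refiner.

    Defaults follow the study recipe where one was stated (learning rate
    0.001, batch size 32, five epochs with early stopping, dropout 0.5 on all
    layers except the last); the network scale is a desk-size separable-conv
    stack rather than a full Xception.
    """

    input_height: int = 128
    input_width: int = 96
    n_blocks: int = 3
    filters_per_block: tuple[int, ...] = (32, 64, 128)
    activation: str = "relu"
    dropout_rate: float = 0.5
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 5
    early_stop_patience: int = 2
    heatmap_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.filters_per_block = tuple(self.filters_per_block)
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if len(self.filters_per_block) != self.n_blocks:
            raise ValueError("filters_per_block length must equal n_blocks")
        if self.activation not in ("relu", "tanh"):
            raise ValueError(f"unsupported activation {self.activation!r}")
        if min(self.input_height, self.input_width) < 2 ** self.n_blocks:
            raise ValueError("input too small for the number of pooling stages")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RefinerConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class TrainingHistory:
    """Per-epoch masked-MSE losses and the epoch training stopped at."""

    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    stopped_epoch: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_mse) + 1),
                "train_mse": self.train_mse,
                "val_mse": self.val_mse,
            }
        )


# ---------------------------------------------------------------------------
# input encoding


def standardize_image(image: np.ndarray, config: RefinerConfig) -> np.ndarray:
    """Resize to the network input size and scale to zero mean, unit variance."""
    from skimage.transform import resize

    img = np.asarray(image, dtype=np.float32)
    if img.shape != (config.input_height, config.input_width):
        img = resize(
            img,
            (config.input_height, config.input_width),
            preserve_range=True,
            anti_aliasing=True,
        ).astype(np.float32)
    sd = img.std()
    return (img - img.mean()) / (sd if sd > 1e-6 else 1.0)


def keypoint_heatmaps(prior_vector: np.ndarray, config: RefinerConfig) -> np.ndarray:
    """Six isotropic Gaussian heatmaps (amplitude 1) at the prior keypoints."""
    h, w, sigma = config.input_height, config.input_width, config.heatmap_sigma
    vec = np.asarray(prior_vector, dtype=np.float32).reshape(6, 2)
    ys = np.arange(h, dtype=np.float32)[:, None]
    xs = np.arange(w, dtype=np.float32)[None, :]
    maps = np.empty((h, w, 6), dtype=np.float32)
    for i, (u, v) in enumerate(vec):
        px, py = u * (w - 1), v * (h - 1)
        maps[:, :, i] = np.exp(-((xs - px) ** 2 + (ys - py) ** 2) / (2.0 * sigma**2))
    return maps


def encode_input(
    image: np.ndarray, prior_vector: np.ndarray, config: RefinerConfig
) -> np.ndarray:
    """Stack image and prior heatmaps into the 7-channel network input."""
    img = standardize_image(image, config)
    return np.concatenate([img[:, :, None], keypoint_heatmaps(prior_vector, config)], axis=2)


# ---------------------------------------------------------------------------
# layers (NHWC tensors, float32, hand-written backward passes)


class _Param:
    __slots__ = ("v", "g", "m", "s")

    def __init__(self, value: np.ndarray):
        self.v = value.astype(np.float32)
        self.g = np.zeros_like(self.v)
        self.m = np.zeros_like(self.v)
        self.s = np.zeros_like(self.v)


class _SeparableConv:
    """Depthwise 3x3 followed by a pointwise 1x1 projection."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.wd = _Param(rng.normal(0.0, np.sqrt(2.0 / 9.0), (9, c_in)))
        self.wp = _Param(rng.normal(0.0, np.sqrt(2.0 / c_in), (c_in, c_out)))
        self.b = _Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.wd, self.wp, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        # depthwise 3x3 as nine shifted multiply-adds over the padded tensor
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        mid = np.zeros_like(x)
        for k in range(9):
            i, j = divmod(k, 3)
            mid += xp[:, i : i + h, j : j + w, :] * self.wd.v[k]
        out = mid @ self.wp.v + self.b.v
        if train:
            self._cache = (xp, mid, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, mid, xshape = self._cache
        n, h, w, c = xshape
        flat_mid = mid.reshape(-1, mid.shape[-1])
        flat_dout = dout.reshape(-1, dout.shape[-1])
        self.wp.g += flat_mid.T @ flat_dout
        self.b.g += flat_dout.sum(axis=0)
        dmid = dout @ self.wp.v.T
        dxp = np.zeros_like(xp)
        for k in range(9):
            i, j = divmod(k, 3)
            self.wd.g[k] += (xp[:, i : i + h, j : j + w, :] * dmid).sum(axis=(0, 1, 2))
            dxp[:, i : i + h, j : j + w, :] += dmid * self.wd.v[k]
        self._cache = None
        return dxp[:, 1 : h + 1, 1 : w + 1, :]


class _Pointwise:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.w = _Param(rng.normal(0.0, np.sqrt(2.0 / c_in), (c_in, c_out)))
        self.b = _Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._cache = x
        return x @ self.w.v + self.b.v

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.w.g += x.reshape(-1, x.shape[-1]).T @ dout.reshape(-1, dout.shape[-1])
        self.b.g += dout.reshape(-1, dout.shape[-1]).sum(axis=0)
        self._cache = None
        return dout @ self.w.v.T


def _avgpool2(x: np.ndarray) -> np.ndarray:
    n, h, w, c = x.shape
    return x[:, : h - h % 2, : w - w % 2, :].reshape(n, h // 2, 2, w // 2, 2, c).mean((2, 4))


def _avgpool2_back(dout: np.ndarray, in_shape) -> np.ndarray:
    n, h, w, c = in_shape
    dx = np.zeros(in_shape, dtype=dout.dtype)
    up = np.repeat(np.repeat(dout, 2, axis=1), 2, axis=2) * 0.25
    dx[:, : up.shape[1], : up.shape[2], :] = up
    return dx


class _Block:
    """sepconv -> act -> sepconv -> pool, with a pooled pointwise shortcut."""

    def __init__(self, c_in: int, c_out: int, activation: str, rng: np.random.Generator):
        self.conv1 = _SeparableConv(c_in, c_out, rng)
        self.conv2 = _SeparableConv(c_out, c_out, rng)
        self.short = _Pointwise(c_in, c_out, rng)
        self.activation = activation
        self._cache = None

    def params(self):
        return self.conv1.params() + self.conv2.params() + self.short.params()

    def _act(self, z):
        return np.maximum(z, 0.0) if self.activation == "relu" else np.tanh(z)

    def _act_back(self, dz, a):
        return dz * (a > 0) if self.activation == "relu" else dz * (1.0 - a**2)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        a1 = self._act(self.conv1.forward(x, train))
        y = self.conv2.forward(a1, train)
        yp = _avgpool2(y)
        sp = _avgpool2(self.short.forward(x, train))
        out = self._act(yp + sp)
        if train:
            self._cache = (a1, y.shape, x.shape, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        a1, yshape, xshape, out = self._cache
        dsum = self._act_back(dout, out)
        dy = _avgpool2_back(dsum, yshape)
        ds = _avgpool2_back(dsum, (*xshape[:3], dsum.shape[-1]))
        da1 = self.conv2.backward(dy)
        dx = self.conv1.backward(self._act_back(da1, a1))
        dx += self.short.backward(ds)
        self._cache = None
        return dx


class SeparableConvRefiner:
    """Desk-scale separable-conv keypoint refiner with a residual prior head."""

    def __init__(self, config: RefinerConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c_in = 7 + 2  # image + 6 heatmaps + 2 coordinate grids
        self.blocks: list[_Block] = []
        for f in config.filters_per_block:
            self.blocks.append(_Block(c_in, f, config.activation, rng))
            c_in = f
        n_feat = config.filters_per_block[-1]
        # zero-init head: the untrained refiner is the identity on the prior
        self.head_w = _Param(np.zeros((n_feat + 12, 12)))
        self.head_b = _Param(np.zeros(12))
        self._drop_rng = np.random.default_rng(rng.integers(2**31))
        self._step = 0
        self._cache = None
        xs = np.linspace(0.0, 1.0, config.input_width, dtype=np.float32)
        ys = np.linspace(0.0, 1.0, config.input_height, dtype=np.float32)
        self._coords = np.stack(np.meshgrid(xs, ys), axis=-1)  # (H, W, 2)

    # -- parameter plumbing

    def params(self) -> list[_Param]:
        out = [self.head_w, self.head_b]
        for blk in self.blocks:
            out.extend(blk.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.g[...] = 0.0

    def adam_step(self) -> None:
        self._step += 1
        lr = self.config.learning_rate
        t = self._step
        for p in self.params():
            p.m = _ADAM_B1 * p.m + (1 - _ADAM_B1) * p.g
            p.s = _ADAM_B2 * p.s + (1 - _ADAM_B2) * p.g**2
            mhat = p.m / (1 - _ADAM_B1**t)
            shat = p.s / (1 - _ADAM_B2**t)
            p.v -= lr * mhat / (np.sqrt(shat) + _ADAM_EPS)

    def get_weights(self) -> list[np.ndarray]:
        return [p.v.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p.v[...] = w

    # -- forward / backward

    def _dropout(self, x: np.ndarray, train: bool):
        rate = self.config.dropout_rate
        if not train or rate <= 0.0:
            return x, None
        keep = self._drop_rng.random(x.shape).astype(np.float32) >= rate
        return x * keep / (1.0 - rate), keep

    def forward(self, encoded: np.ndarray, priors: np.ndarray, train: bool = False):
        """Map (N,H,W,7) encodings plus (N,12) priors to (N,12) predictions."""
        x = np.concatenate(
            [encoded, np.broadcast_to(self._coords, (*encoded.shape[:3], 2))], axis=3
        ).astype(np.float32)
        drop_masks = []
        for blk in self.blocks:
            x = blk.forward(x, train)
            x, keep = self._dropout(x, train)
            drop_masks.append(keep)
        feat = x.mean(axis=(1, 2))
        featd, keep_f = self._dropout(feat, train)
        z = np.concatenate([featd, priors.astype(np.float32)], axis=1)
        delta = z @ self.head_w.v + self.head_b.v
        out = priors + delta
        if train:
            self._cache = (x.shape, drop_masks, keep_f, z)
        return out

    def backward(self, dout: np.ndarray) -> None:
        xshape, drop_masks, keep_f, z = self._cache
        dout = dout.astype(np.float32)
        self.head_w.g += z.T @ dout
        self.head_b.g += dout.sum(axis=0)
        dz = dout @ self.head_w.v.T
        dfeat = dz[:, : xshape[-1]]
        if keep_f is not None:
            dfeat = dfeat * keep_f / (1.0 - self.config.dropout_rate)
        n, h, w, _ = xshape
        dx = np.broadcast_to(dfeat[:, None, None, :] / (h * w), xshape).copy()
        for blk, keep in zip(reversed(self.blocks), reversed(drop_masks)):
            if keep is not None:
                dx = dx * keep / (1.0 - self.config.dropout_rate)
            dx = blk.backward(dx)
        self._cache = None

    # -- persistence

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", *[p.v for p in self.params()])
        self.config.to_yaml(directory / "config.yaml")

    @classmethod
    def load(cls, directory: str | Path) -> "SeparableConvRefiner":
        directory = Path(directory)
        model = cls(RefinerConfig.from_yaml(directory / "config.yaml"))
        with np.load(directory / "weights.npz") as data:
            model.set_weights([data[k] for k in data.files])
        return model


def build_refiner(config: RefinerConfig) -> SeparableConvRefiner:
    """Construct an untrained refiner; same seed gives identical parameters."""
    return SeparableConvRefiner(config)


# ---------------------------------------------------------------------------
# training


def masked_mse(pred: np.ndarray, true: np.ndarray, mask: np.ndarray) -> tuple[float, int]:
    """Sum of squared errors over unmasked slots plus the slot count."""
    m = mask.astype(bool)
    return float(np.sum((pred[m] - true[m]) ** 2)), int(m.sum())


def _stack_examples(triples: list[TrainingExample], config: RefinerConfig):
    cache: dict[str, np.ndarray] = {}
    enc = np.empty(
        (len(triples), config.input_height, config.input_width, 7), dtype=np.float32
    )
    priors = np.stack([t.prior_vector for t in triples]).astype(np.float32)
    trues = np.stack([t.true_vector for t in triples]).astype(np.float32)
    masks = np.stack([t.mask for t in triples]).astype(bool)
    for i, t in enumerate(triples):
        if t.molar_id not in cache:
            cache[t.molar_id] = standardize_image(t.image, config)
        enc[i, :, :, 0] = cache[t.molar_id]
        enc[i, :, :, 1:] = keypoint_heatmaps(t.prior_vector, config)
    return enc, priors, trues, masks


def _dataset_loss(model, enc, priors, trues, masks, batch: int) -> float:
    sse = 0.0
    count = 0
    for lo in range(0, len(enc), batch):
        sl = slice(lo, lo + batch)
        pred = model.forward(enc[sl], priors[sl], train=False)
        s, c = masked_mse(pred, trues[sl], masks[sl])
        sse += s
        count += c
    return sse / max(count, 1)


def train_refiner(
    model: SeparableConvRefiner,
    triples: list[TrainingExample],
    config: RefinerConfig | None = None,
    val_frac: float = 0.2,
) -> tuple[SeparableConvRefiner, TrainingHistory]:
    """Fit the refiner with Adam, masked MSE and validation early stopping.

    A ``val_frac`` share of *molars* (not triples) is held out for validation
    so augmented copies of one image never leak across the split.  Training
    stops when the validation loss fails to improve for
    ``early_stop_patience`` consecutive epochs; the best-validation weights
    are restored before returning.
    """
    config = config or model.config
    if len(triples) < 2 * config.batch_size:
        raise ValueError(
            f"need at least {2 * config.batch_size} training triples, got {len(triples)}"
        )
    rng = np.random.default_rng(config.seed)
    ids = sorted({t.molar_id for t in triples})
    ids = [ids[i] for i in rng.permutation(len(ids))]
    n_val = max(1, int(round(val_frac * len(ids))))
    val_ids = set(ids[:n_val])
    train_t = [t for t in triples if t.molar_id not in val_ids]
    val_t = [t for t in triples if t.molar_id in val_ids]

    enc_tr, pri_tr, tru_tr, msk_tr = _stack_examples(train_t, config)
    enc_va, pri_va, tru_va, msk_va = _stack_examples(val_t, config)

    history = TrainingHistory()
    best_val = np.inf
    best_weights = model.get_weights()
    bad_epochs = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_t))
        sse = 0.0
        count = 0
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            model.zero_grad()
            pred = model.forward(enc_tr[idx], pri_tr[idx], train=True)
            diff = (pred - tru_tr[idx]) * msk_tr[idx]
            n_slots = max(int(msk_tr[idx].sum()), 1)
            model.backward(2.0 * diff / n_slots)
            model.adam_step()
            sse += float(np.sum(diff**2))
            count += n_slots
        history.train_mse.append(sse / max(count, 1))
        val_loss = _dataset_loss(model, enc_va, pri_va, tru_va, msk_va, config.batch_size)
        history.val_mse.append(val_loss)
        history.stopped_epoch = epoch
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_weights = model.get_weights()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.early_stop_patience:
                break
    model.set_weights(best_weights)
    return model, history


def predict_keypoints(
    model: SeparableConvRefiner,
    image: np.ndarray,
    prior_vector: np.ndarray,
    config: RefinerConfig | None = None,
) -> np.ndarray:
    """Refine one prior keypoint vector; deterministic, clamped to [0, 1]."""
    config = config or model.config
    enc = encode_input(image, prior_vector, config)[None]
    pred = model.forward(enc, np.asarray(prior_vector, dtype=np.float32)[None], train=False)
    return np.clip(pred[0], 0.0, 1.0)
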