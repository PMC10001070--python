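"""Faster-SqueezeNet feature extractor.

A compact convolutional network built from SqueezeNet fire modules
(squeeze 1x1 convolution feeding parallel 1x1 and 3x3 expand convolutions
whose outputs are concatenated), augmented with two DenseNet-style concat
blocks and one ResNet-style residual block.  The layer inventory is fixed:
4 convolutional layers, 3 blocks, 1 batch-normalisation stage, and a global
average pooling layer producing a fixed-length feature vector per image.

The concat blocks realise x_l = H_l([x_0, ..., x_{l-1}]): the block pools
its input and a fire-transformed copy, concatenates them along channels,
and hands the widened map to the following convolution.  The residual block
computes H(x) = F(x) + x with F a fire module (1x1 projection when channel
counts disagree).

Everything runs on the CPU in numpy; convolutions use a
sliding-window-view im2col.  The convolutional trunk is randomly
initialised (He fan-in scaling) under a fixed seed and used as a frozen
feature extractor; only the softmax classifier head is trained, which is
what the hyperparameter search tunes.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np

from .datasets import LabeledImageSet

__all__ = [
    "FireModuleSpec",
    "ConvSpec",
    "BlockSpec",
    "NetworkSpec",
    "FeatureMatrix",
    "TrainingDivergence",
    "FasterSqueezeNet",
    "concat_block",
    "residual_block",
    "build_network",
    "extract_features",
    "train_classifier_head",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class FireModuleSpec:
    squeeze_channels: int
    expand1x1_channels: int
    expand3x3_channels: int

    def __post_init__(self) -> None:
        if min(self.squeeze_channels, self.expand1x1_channels,
               self.expand3x3_channels) <= 0:
            raise ValueError("fire module channel counts must be positive")
        if self.squeeze_channels >= self.output_channels:
            raise ValueError("squeeze must be narrower than the expand output")

    @property
    def output_channels(self) -> int:
        return self.expand1x1_channels + self.expand3x3_channels


@dataclass(frozen=True)
class ConvSpec:
    channels: int
    kernel: int = 3
    stride: int = 1


@dataclass(frozen=True)
class BlockSpec:
    """kind: 'concat' (pool + fire branch, channel concatenation) or
    'residual' (fire output summed with the input, then pooled)."""

    kind: str
    fire: FireModuleSpec

    def __post_init__(self) -> None:
        if self.kind not in ("concat", "residual"):
            raise ValueError("block kind must be 'concat' or 'residual'")


def default_network_spec(feature_dim: int = 128) -> "NetworkSpec":
    return NetworkSpec(
        conv_layer_specs=(
            ConvSpec(16, 3, 2),
            ConvSpec(32, 3, 1),
            ConvSpec(64, 3, 1),
            ConvSpec(feature_dim, 1, 1),
        ),
        block_specs=(
            BlockSpec("concat", FireModuleSpec(8, 8, 8)),
            BlockSpec("concat", FireModuleSpec(16, 16, 16)),
            BlockSpec("residual", FireModuleSpec(16, 32, 32)),
        ),
        batchnorm=True,
        feature_dim=feature_dim,
    )


@dataclass(frozen=True)
class NetworkSpec:
    conv_layer_specs: tuple[ConvSpec, ...]
    block_specs: tuple[BlockSpec, ...]
    batchnorm: bool = True
    feature_dim: int = 128

    def __post_init__(self) -> None:
        if len(self.conv_layer_specs) != 4:
            raise ValueError("exactly 4 convolutional layers are required")
        if len(self.block_specs) != 3:
            raise ValueError("exactly 3 blocks are required")
        if self.feature_dim <= 0:
            raise ValueError("feature_dim must be positive")
        if self.conv_layer_specs[-1].channels != self.feature_dim:
            raise ValueError("final convolution must emit feature_dim channels")


@dataclass
class FeatureMatrix:
    vectors: np.ndarray  # (n_images, feature_dim)
    image_ids: list[str]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.size and not np.isfinite(self.vectors).all():
            raise ValueError("feature matrix contains non-finite entries")


class TrainingDivergence(RuntimeError):
    def __init__(self, hyperparams: dict):
        super().__init__(f"training diverged with hyperparameters {hyperparams}")
        self.hyperparams = hyperparams


# ---------------------------------------------------------------- primitives

def conv2d(x: np.ndarray, W: np.ndarray, b: np.ndarray,
           stride: int = 1, pad: int | None = None) -> np.ndarray:
    """NHWC convolution; W has shape (kh, kw, C_in, C_out)."""
    kh, kw, cin, cout = W.shape
    if x.shape[-1] != cin:
        raise ValueError(f"expected {cin} input channels, got {x.shape[-1]}")
    if pad is None:
        pad = kh // 2
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    if x.shape[1] < kh or x.shape[2] < kw:
        raise ValueError("input smaller than the convolution kernel")
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (N, H', W', C_in, kh, kw)
    return np.einsum("nhwcij,ijco->nhwo", win, W, optimize=True) + b


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def maxpool2(x: np.ndarray) -> np.ndarray:
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    x = x[:, : h2 * 2, : w2 * 2]
    return x.reshape(n, h2, 2, w2, 2, c).max(axis=(2, 4))


def global_average_pool(x: np.ndarray) -> np.ndarray:
    return x.mean(axis=(1, 2))


def concat_block(inputs: list[np.ndarray]) -> np.ndarray:
    """Concatenate feature maps along the channel axis (dense-style link).

    All inputs must share batch and spatial dimensions; the output channel
    count is the sum of the inputs' before the block's closing convolution.
    """
    if not inputs:
        raise ValueError("concat_block requires at least one input")
    ref = inputs[0].shape[:3]
    for m in inputs[1:]:
        if m.shape[:3] != ref:
            raise ValueError(
                f"spatial/batch mismatch in concat: {m.shape} vs {inputs[0].shape}")
    return np.concatenate(inputs, axis=-1)


def residual_block(x: np.ndarray, stack) -> np.ndarray:
    """Shortcut connection H(x) = F(x) + x."""
    fx = stack(x)
    if fx.shape != x.shape:
        raise ValueError(
            f"residual shapes irreconcilable: F(x) {fx.shape} vs x {x.shape}")
    return fx + x


# ------------------------------------------------------------------ network

def _he(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[:-1]))
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class FasterSqueezeNet:
    """Frozen convolutional trunk + trainable softmax head."""

    def __init__(self, spec: NetworkSpec, seed: int):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        self.params: dict[str, np.ndarray] = {}
        cs = spec.conv_layer_specs
        bs = spec.block_specs

        c_in = 3
        for li, (conv, block) in enumerate(zip(cs[:3], bs)):
            self._init_conv(rng, f"conv{li}", conv, c_in)
            c_block_in = conv.channels
            self._init_fire(rng, f"fire{li}", bs[li].fire, c_block_in)
            if block.kind == "concat":
                c_in = c_block_in + block.fire.output_channels
            else:
                if block.fire.output_channels != c_block_in:
                    self.params[f"proj{li}_W"] = _he(
                        rng, (1, 1, c_block_in, block.fire.output_channels))
                    self.params[f"proj{li}_b"] = np.zeros(
                        block.fire.output_channels)
                c_in = block.fire.output_channels
        self._init_conv(rng, "conv3", cs[3], c_in)
        # batchnorm statistics (frozen; optionally calibrated on data)
        self.bn_mean = np.zeros(c_in)
        self.bn_var = np.ones(c_in)
        self.bn_eps = 1e-5
        self._bn_channels = c_in
        # classifier head (created by train_classifier_head)
        self.head_W: np.ndarray | None = None
        self.head_b: np.ndarray | None = None
        self.class_names: tuple[str, ...] | None = None

    def _init_conv(self, rng, name: str, conv: ConvSpec, c_in: int) -> None:
        self.params[f"{name}_W"] = _he(
            rng, (conv.kernel, conv.kernel, c_in, conv.channels))
        self.params[f"{name}_b"] = np.zeros(conv.channels)
        setattr(self, f"_{name}_stride", conv.stride)

    def _init_fire(self, rng, name: str, fire: FireModuleSpec, c_in: int) -> None:
        self.params[f"{name}_sq_W"] = _he(rng, (1, 1, c_in, fire.squeeze_channels))
        self.params[f"{name}_sq_b"] = np.zeros(fire.squeeze_channels)
        self.params[f"{name}_e1_W"] = _he(
            rng, (1, 1, fire.squeeze_channels, fire.expand1x1_channels))
        self.params[f"{name}_e1_b"] = np.zeros(fire.expand1x1_channels)
        self.params[f"{name}_e3_W"] = _he(
            rng, (3, 3, fire.squeeze_channels, fire.expand3x3_channels))
        self.params[f"{name}_e3_b"] = np.zeros(fire.expand3x3_channels)

    def _fire(self, name: str, x: np.ndarray) -> np.ndarray:
        p = self.params
        s = relu(conv2d(x, p[f"{name}_sq_W"], p[f"{name}_sq_b"], pad=0))
        e1 = conv2d(s, p[f"{name}_e1_W"], p[f"{name}_e1_b"], pad=0)
        e3 = conv2d(s, p[f"{name}_e3_W"], p[f"{name}_e3_b"], pad=1)
        return concat_block([e1, e3])

    def forward(self, images: np.ndarray) -> np.ndarray:
        """Map (N, H, W, 3) images in [0, 1] to (N, feature_dim) vectors."""
        x = np.asarray(images, dtype=float)
        if x.ndim != 4 or x.shape[-1] != 3:
            raise ValueError("expected images of shape (N, H, W, 3)")
        p = self.params
        for li, block in enumerate(self.spec.block_specs):
            x = relu(conv2d(x, p[f"conv{li}_W"], p[f"conv{li}_b"],
                            stride=getattr(self, f"_conv{li}_stride")))
            if block.kind == "concat":
                branch = maxpool2(relu(self._fire(f"fire{li}", x)))
                x = concat_block([maxpool2(x), branch])
            else:
                fx = relu(self._fire(f"fire{li}", x))
                shortcut = x
                if f"proj{li}_W" in p:
                    shortcut = conv2d(x, p[f"proj{li}_W"], p[f"proj{li}_b"], pad=0)
                x = maxpool2(residual_block(shortcut, lambda _x: fx))
        if self.spec.batchnorm:
            x = (x - self.bn_mean) / np.sqrt(self.bn_var + self.bn_eps)
        x = relu(conv2d(x, p["conv3_W"], p["conv3_b"],
                        stride=self._conv3_stride, pad=0))
        return global_average_pool(x)

    def calibrate_batchnorm(self, images: np.ndarray) -> None:
        """Set the frozen batch-norm statistics from a calibration batch."""
        x = np.asarray(images, dtype=float)
        p = self.params
        for li, block in enumerate(self.spec.block_specs):
            x = relu(conv2d(x, p[f"conv{li}_W"], p[f"conv{li}_b"],
                            stride=getattr(self, f"_conv{li}_stride")))
            if block.kind == "concat":
                x = concat_block([maxpool2(x),
                                  maxpool2(relu(self._fire(f"fire{li}", x)))])
            else:
                fx = relu(self._fire(f"fire{li}", x))
                shortcut = x
                if f"proj{li}_W" in p:
                    shortcut = conv2d(x, p[f"proj{li}_W"], p[f"proj{li}_b"], pad=0)
                x = maxpool2(fx + shortcut)
        flat = x.reshape(-1, x.shape[-1])
        self.bn_mean = flat.mean(axis=0)
        self.bn_var = flat.var(axis=0)

    # ------------------------------------------------------------ head

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        if self.head_W is None:
            raise RuntimeError("classifier head has not been trained")
        logits = features @ self.head_W + self.head_b
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(features), axis=1)

    # ------------------------------------------------------- persistence

    def save(self, path) -> None:
        state = {
            "version": CHECKPOINT_VERSION,
            "spec": self.spec,
            "seed": self.seed,
            "params": self.params,
            "bn_mean": self.bn_mean,
            "bn_var": self.bn_var,
            "head_W": self.head_W,
            "head_b": self.head_b,
            "class_names": self.class_names,
        }
        with open(path, "wb") as fh:
            pickle.dump(state, fh)

    @classmethod
    def load(cls, path) -> "FasterSqueezeNet":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        if state.get("version") != CHECKPOINT_VERSION:
            raise ValueError("unsupported checkpoint version")
        model = cls(state["spec"], state["seed"])
        model.params = state["params"]
        model.bn_mean = state["bn_mean"]
        model.bn_var = state["bn_var"]
        model.head_W = state["head_W"]
        model.head_b = state["head_b"]
        model.class_names = state["class_names"]
        return model


def build_network(spec: NetworkSpec | None = None, seed: int = 0,
                  ) -> FasterSqueezeNet:
    return FasterSqueezeNet(spec or default_network_spec(), seed)


def preprocess_images(images: np.ndarray) -> np.ndarray:
    """Scale uint8 [0, 255] images to float [0, 1] (no augmentation)."""
    return np.asarray(images, dtype=float) / 255.0


def extract_features(model: FasterSqueezeNet, images: LabeledImageSet,
                     batch_size: int = 64) -> FeatureMatrix:
    """One feature vector per image, order preserved; empty in, empty out."""
    if len(images) == 0:
        return FeatureMatrix(
            vectors=np.empty((0, model.spec.feature_dim)), image_ids=[])
    x = preprocess_images(images.images)
    chunks = [model.forward(x[i:i + batch_size])
              for i in range(0, len(x), batch_size)]
    return FeatureMatrix(vectors=np.vstack(chunks),
                         image_ids=list(images.image_ids))


DEFAULT_HYPERPARAMS = {
    "learning_rate": 0.01,
    "dropout": 0.5,
    "batch_size": 5,
    "epochs": 50,
}


def train_classifier_head(
    model: FasterSqueezeNet,
    train: LabeledImageSet,
    hyperparams: dict | None = None,
    seed: int = 0,
    features: FeatureMatrix | None = None,
) -> tuple[FasterSqueezeNet, float]:
    """Train the softmax head by minibatch SGD; return validation error.

    Hyperparameters: learning_rate, dropout (inverted dropout on the feature
    vector during training only), batch_size, epochs.  An internal seeded
    80/20 train/validation split of ``train`` supplies the validation error
    in [0, 1] that serves as the tuning objective.  Precomputed features may
    be passed to avoid re-running the frozen trunk.
    """
    hp = dict(DEFAULT_HYPERPARAMS)
    hp.update(hyperparams or {})
    n_classes = len(train.class_names)
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    if features is None:
        features = extract_features(model, train)
    Xall = features.vectors
    yall = train.labels
    # standardise features for a well-conditioned head fit
    mu, sd = Xall.mean(axis=0), Xall.std(axis=0) + 1e-8
    Xs = (Xall - mu) / sd
    model._head_mu, model._head_sd = mu, sd

    rng = np.random.default_rng(int(seed))
    idx = rng.permutation(len(Xs))
    n_val = max(1, int(round(0.2 * len(Xs))))
    val_idx, tr_idx = idx[:n_val], idx[n_val:]
    Xtr, ytr = Xs[tr_idx], yall[tr_idx]
    Xva, yva = Xs[val_idx], yall[val_idx]

    D = Xs.shape[1]
    W = rng.standard_normal((D, n_classes)) * 0.01
    b = np.zeros(n_classes)
    lr = float(hp["learning_rate"])
    drop = float(hp["dropout"])
    bs = max(1, int(hp["batch_size"]))
    for _epoch in range(int(hp["epochs"])):
        order = rng.permutation(len(Xtr))
        for start in range(0, len(Xtr), bs):
            sel = order[start:start + bs]
            xb, yb = Xtr[sel], ytr[sel]
            if drop > 0:
                mask = (rng.uniform(size=xb.shape) >= drop) / (1.0 - drop)
                xb = xb * mask
            logits = xb @ W + b
            logits -= logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            proba = e / e.sum(axis=1, keepdims=True)
            grad = proba.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            grad /= len(yb)
            gW = xb.T @ grad
            gb = grad.sum(axis=0)
            if not (np.isfinite(gW).all() and np.isfinite(gb).all()):
                raise TrainingDivergence(hp)
            W -= lr * gW
            b -= lr * gb
        # a blown-up weight norm is divergence even when softmax stays finite
        if not np.isfinite(W).all() or np.abs(W).max() > 1e8:
            raise TrainingDivergence(hp)
    model.head_W, model.head_b = W, b
    model.class_names = train.class_names
    val_err = float(np.mean(np.argmax(Xva @ W + b, axis=1) != yva))
    return model, val_err


def head_predict(model: FasterSqueezeNet, features: np.ndarray) -> np.ndarray:
    """Predict class indices from raw (unstandardised) feature vectors."""
    mu = getattr(model, "_head_mu", 0.0)
    sd = getattr(model, "_head_sd", 1.0)
    return model.predict((features - mu) / sd)
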