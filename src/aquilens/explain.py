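"""Local surrogate explanations (LIME-style) for the black-box classifier.

The explainer perturbs an instance, queries the black box, and fits a
weighted sparse linear surrogate whose coefficients are read as local
feature contributions:

1. the image is partitioned into superpixels (a deterministic grid by
   default; graph-based Felzenszwalb segmentation optionally);
2. random on/off masks over the superpixels produce perturbed images, with
   switched-off segments filled by their mean colour; each sample is
   weighted by the proximity kernel exp(−d²/width²), where d is the
   fraction of masked segments;
3. a weighted linear regression of the target-class probability on the
   mask indicators, restricted to the ``num_features`` segments with the
   largest absolute fitted weights, yields the contributions.

A tabular mode perturbs feature vectors instead of superpixels by
resampling switched-off features from their training marginals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.linear_model import LinearRegression, Ridge

__all__ = [
    "Explanation",
    "segment_image",
    "perturb_and_predict",
    "fit_surrogate",
    "explain_instance",
    "TabularExplainer",
    "save_heatmap",
]

DEFAULT_KERNEL_WIDTH = 0.25
DEFAULT_NUM_SAMPLES = 1000


@dataclass
class Explanation:
    """Sparse local surrogate around one instance."""

    instance_id: str
    target_class: int
    feature_ids: list[int]
    contributions: list[float]
    intercept: float
    surrogate_fit_quality: float
    num_samples: int
    seed: int
    segments: np.ndarray | None = field(default=None, repr=False)

    def to_json(self, path=None) -> str:
        d = asdict(self)
        d.pop("segments")
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def top_feature(self) -> int:
        """Feature with the largest positive contribution."""
        i = int(np.argmax(self.contributions))
        return self.feature_ids[i]


def segment_image(image: np.ndarray, method: str = "grid",
                  n_segments: int = 16, seed: int = 0) -> np.ndarray:
    """Integer-labelled partition of the image into connected regions."""
    img = np.asarray(image)
    h, w = img.shape[:2]
    if h == 1 and w == 1:
        return np.zeros((1, 1), dtype=int)
    if method == "grid":
        side = max(1, int(round(np.sqrt(n_segments))))
        rows = np.minimum((np.arange(h) * side) // h, side - 1)
        cols = np.minimum((np.arange(w) * side) // w, side - 1)
        return (rows[:, None] * side + cols[None, :]).astype(int)
    if method == "felzenszwalb":
        from skimage.segmentation import felzenszwalb

        labels = felzenszwalb(img, scale=50, sigma=0.8,
                              min_size=max(4, h * w // (4 * n_segments)))
        # relabel to a dense 0..K-1 range
        _, dense = np.unique(labels, return_inverse=True)
        return dense.reshape(h, w).astype(int)
    raise ValueError(f"unknown segmentation method {method!r}")


def _fill_image(image: np.ndarray, segments: np.ndarray) -> np.ndarray:
    """Image with every segment replaced by its mean colour."""
    filled = np.empty_like(image, dtype=float)
    for s in np.unique(segments):
        sel = segments == s
        filled[sel] = image[sel].reshape(-1, image.shape[-1]).mean(axis=0)
    return filled


def perturb_and_predict(instance: np.ndarray, segments: np.ndarray,
                        predict_fn, num_samples: int, seed: int,
                        kernel_width: float = DEFAULT_KERNEL_WIDTH,
                        batch_size: int = 64,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random on/off superpixel masks, black-box outputs, proximity weights.

    The first sample is always the all-on mask (the unperturbed instance,
    proximity weight 1).  ``predict_fn`` maps a batch of images to class
    probabilities.  Weights are exp(−d²/width²) with d the masked fraction.
    """
    instance = np.asarray(instance, dtype=float)
    seg_ids = np.unique(segments)
    n_seg = len(seg_ids)
    rng = np.random.default_rng(int(seed))
    masks = rng.integers(0, 2, size=(num_samples, n_seg))
    masks[0] = 1
    filled = _fill_image(instance, segments)
    onehot = np.stack([segments == s for s in seg_ids])  # (n_seg, H, W)

    preds = []
    for start in range(0, num_samples, batch_size):
        chunk = masks[start:start + batch_size]
        imgs = np.empty((len(chunk),) + instance.shape)
        for i, m in enumerate(chunk):
            off = (~m.astype(bool)) @ onehot.reshape(n_seg, -1)
            off = off.reshape(segments.shape).astype(bool)
            img = instance.copy()
            img[off] = filled[off]
            imgs[i] = img
        try:
            p = np.asarray(predict_fn(imgs))
        except Exception as exc:
            raise RuntimeError(
                f"predict_fn failed on samples {start}..{start + len(chunk)}"
            ) from exc
        preds.append(p)
    predictions = np.vstack(preds)
    dist = 1.0 - masks.mean(axis=1)
    weights = np.exp(-(dist**2) / kernel_width**2)
    return masks, predictions, weights


def fit_surrogate(masks: np.ndarray, predictions: np.ndarray,
                  weights: np.ndarray, num_features: int,
                  target_class: int = 0, instance_id: str = "",
                  seed: int = 0) -> Explanation:
    """Weighted sparse linear fit of the target-class probability on masks.

    Feature selection: fit on all mask indicators, keep the
    ``num_features`` largest-|coefficient| segments, refit restricted.
    A numerically singular design falls back to a small ridge penalty.
    """
    masks = np.asarray(masks, dtype=float)
    y = np.asarray(predictions, dtype=float)
    if y.ndim == 2:
        y = y[:, target_class]
    if len(masks) < num_features:
        raise ValueError("need at least num_features perturbation samples")

    def _wls(X, y):
        model = LinearRegression()
        model.fit(X, y, sample_weight=weights)
        coef = model.coef_
        if not np.isfinite(coef).all():
            raise np.linalg.LinAlgError
        return model

    def _fit(X, y):
        try:
            return _wls(X, y), False
        except np.linalg.LinAlgError:
            warnings.warn("singular surrogate design; ridge fallback",
                          stacklevel=2)
            model = Ridge(alpha=1e-3)
            model.fit(X, y, sample_weight=weights)
            return model, True

    full, _ = _fit(masks, y)
    order = np.argsort(-np.abs(full.coef_))
    keep = np.sort(order[:num_features])
    restricted, _ = _fit(masks[:, keep], y)
    resid = y - restricted.predict(masks[:, keep])
    wmean = np.average(y, weights=weights)
    ss_tot = np.average((y - wmean) ** 2, weights=weights)
    ss_res = np.average(resid**2, weights=weights)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return Explanation(
        instance_id=instance_id,
        target_class=int(target_class),
        feature_ids=[int(k) for k in keep],
        contributions=[float(c) for c in restricted.coef_],
        intercept=float(restricted.intercept_),
        surrogate_fit_quality=float(r2),
        num_samples=len(masks),
        seed=int(seed),
    )


def explain_instance(instance: np.ndarray, predict_fn,
                     num_features: int = 5,
                     num_samples: int = DEFAULT_NUM_SAMPLES,
                     seed: int = 0, target_class: int | None = None,
                     segmentation: str = "grid", n_segments: int = 16,
                     kernel_width: float = DEFAULT_KERNEL_WIDTH,
                     instance_id: str = "") -> Explanation:
    """Segment, perturb, and fit: the full local explanation of one image."""
    segments = segment_image(instance, method=segmentation,
                             n_segments=n_segments, seed=seed)
    masks, preds, weights = perturb_and_predict(
        instance, segments, predict_fn, num_samples, seed,
        kernel_width=kernel_width)
    if target_class is None:
        target_class = int(np.argmax(preds[0]))
    num_features = min(num_features, masks.shape[1])
    exp = fit_surrogate(masks, preds, weights, num_features,
                        target_class=target_class, instance_id=instance_id,
                        seed=seed)
    exp.segments = segments
    return exp


class TabularExplainer:
    """LIME in tabular mode over feature vectors.

    Stores per-feature mean and standard deviation of the training matrix;
    switched-off features are resampled from N(mean, std) (zero-variance
    features are retained with zero perturbation, i.e. stay at their mean).
    """

    def __init__(self, training_features: np.ndarray,
                 class_names: tuple[str, ...]):
        X = np.asarray(training_features, dtype=float)
        if X.size == 0:
            raise ValueError("training feature matrix is empty")
        self.mean = X.mean(axis=0)
        self.std = X.std(axis=0)
        self.class_names = tuple(class_names)

    def explain_instance(self, instance: np.ndarray, predict_fn,
                         num_features: int = 5,
                         num_samples: int = DEFAULT_NUM_SAMPLES,
                         seed: int = 0, target_class: int | None = None,
                         kernel_width: float = DEFAULT_KERNEL_WIDTH,
                         instance_id: str = "") -> Explanation:
        x = np.asarray(instance, dtype=float).ravel()
        D = x.size
        rng = np.random.default_rng(int(seed))
        masks = rng.integers(0, 2, size=(num_samples, D))
        masks[0] = 1
        noise = self.mean + self.std * rng.standard_normal((num_samples, D))
        samples = np.where(masks.astype(bool), x, noise)
        preds = np.asarray(predict_fn(samples))
        if target_class is None:
            target_class = int(np.argmax(preds[0]))
        dist = 1.0 - masks.mean(axis=1)
        weights = np.exp(-(dist**2) / kernel_width**2)
        return fit_surrogate(masks, preds, weights,
                             min(num_features, D),
                             target_class=target_class,
                             instance_id=instance_id, seed=seed)


def save_heatmap(explanation: Explanation, instance: np.ndarray, path) -> None:
    """PNG overlay: signed segment contributions on the instance."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if explanation.segments is None:
        raise ValueError("explanation carries no segment map")
    heat = np.zeros(explanation.segments.shape, dtype=float)
    for fid, c in zip(explanation.feature_ids, explanation.contributions):
        heat[explanation.segments == fid] = c
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(np.asarray(instance).astype(np.uint8))
    vmax = max(np.abs(heat).max(), 1e-12)
    im = ax.imshow(heat, cmap="coolwarm", alpha=0.45, vmin=-vmax, vmax=vmax)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=100)
    plt.close(fig)
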