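"""Hyperparameter search space and the AAO tuning objective.

The extractor head's training hyperparameters are encoded as a box in R^D
for the Aquila optimizer.  Each dimension carries a codec:

* ``linear``   — position used as-is (clamped to bounds);
* ``log``      — position lives in log10 space, decoded as 10^x;
* ``integer``  — position rounded half-up and clamped;

so the default space is learning rate log-uniform on [1e-4, 1e-1], dropout
on [0.1, 0.7], and batch size integer on {2..32}.  The tuning fitness is
the validation classification error percentage,

    fitness = 100 · (misclassified / total),

measured after training the head with the decoded hyperparameters on a
reduced budget (a 5-epoch proxy of the full 50-epoch setting, to keep a
desk-scale search affordable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aquila import AAOConfig, Bounds, OptimizationTrace, optimize
from .datasets import LabeledImageSet
from .squeezenet import (FasterSqueezeNet, FeatureMatrix, TrainingDivergence,
                         extract_features, head_predict, train_classifier_head)

__all__ = ["Dimension", "SearchSpace", "default_search_space",
           "decode", "fitness", "tune"]

PROXY_EPOCHS = 5


@dataclass(frozen=True)
class Dimension:
    name: str
    low: float
    high: float
    codec: str = "linear"  # linear | log | integer

    def __post_init__(self) -> None:
        if self.codec not in ("linear", "log", "integer"):
            raise ValueError(f"unknown codec {self.codec!r}")
        if self.low >= self.high:
            raise ValueError("low must be below high")
        if self.codec == "log" and self.low <= 0:
            raise ValueError("log dimensions need positive bounds")

    @property
    def position_bounds(self) -> tuple[float, float]:
        if self.codec == "log":
            return (np.log10(self.low), np.log10(self.high))
        return (self.low, self.high)

    def decode_coord(self, x: float) -> float | int:
        lo, hi = self.position_bounds
        x = float(np.clip(x, lo, hi))
        if self.codec == "log":
            return float(10.0**x)
        if self.codec == "integer":
            return int(np.clip(np.floor(x + 0.5), self.low, self.high))
        return x

    def encode_value(self, v: float) -> float:
        if self.codec == "log":
            return float(np.log10(v))
        return float(v)


@dataclass(frozen=True)
class SearchSpace:
    dimensions: tuple[Dimension, ...]

    @property
    def bounds(self) -> Bounds:
        lo, hi = zip(*(d.position_bounds for d in self.dimensions))
        return Bounds(np.array(lo), np.array(hi))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.dimensions)


def default_search_space() -> SearchSpace:
    return SearchSpace(dimensions=(
        Dimension("learning_rate", 1e-4, 1e-1, "log"),
        Dimension("dropout", 0.1, 0.7, "linear"),
        Dimension("batch_size", 2, 32, "integer"),
    ))


def decode(position: np.ndarray, space: SearchSpace) -> dict:
    """Map an optimizer position to a valid hyperparameter set."""
    position = np.asarray(position, dtype=float)
    if position.size != len(space.dimensions):
        raise ValueError("position dimensionality mismatch")
    return {d.name: d.decode_coord(x)
            for d, x in zip(space.dimensions, position)}


def encode(hyperparams: dict, space: SearchSpace) -> np.ndarray:
    return np.array([d.encode_value(hyperparams[d.name])
                     for d in space.dimensions])


def fitness(position: np.ndarray, space: SearchSpace,
            model: FasterSqueezeNet, train_data: LabeledImageSet,
            validation_data: LabeledImageSet, seed: int = 0,
            epochs: int = PROXY_EPOCHS,
            train_features: FeatureMatrix | None = None,
            validation_features: FeatureMatrix | None = None) -> float:
    """Validation classification error (percent) for one position.

    Trains the extractor head with the decoded hyperparameters and counts
    misclassified validation samples; a training divergence is scored with
    the worst-case fitness of 100.
    """
    hp = decode(position, space)
    hp["epochs"] = epochs
    try:
        model, _ = train_classifier_head(model, train_data, hp, seed=seed,
                                         features=train_features)
    except TrainingDivergence:
        import warnings

        warnings.warn(f"training diverged at {hp}; fitness set to 100",
                      stacklevel=2)
        return 100.0
    if validation_features is None:
        validation_features = extract_features(model, validation_data)
    pred = head_predict(model, validation_features.vectors)
    n_wrong = int(np.sum(pred != validation_data.labels))
    return 100.0 * n_wrong / len(validation_data.labels)


@dataclass
class TuningResult:
    best_hyperparams: dict
    best_fitness: float
    trace: OptimizationTrace
    names: tuple[str, ...] = field(default_factory=tuple)


def tune(space: SearchSpace, train_data: LabeledImageSet,
         config: AAOConfig, model: FasterSqueezeNet | None = None,
         objective=None, validation_fraction: float = 0.25,
         epochs: int = PROXY_EPOCHS) -> TuningResult:
    """Minimise the validation error over the search space with the AAO.

    A custom ``objective(position) -> float`` may replace the default
    head-training fitness (used e.g. to validate the optimizer against
    analytically known minima).
    """
    if objective is None:
        from .datasets import stratified_split
        from .squeezenet import build_network

        if len(np.unique(train_data.labels)) < 2:
            raise ValueError("tuning requires at least 2 classes")
        model = model or build_network(seed=config.seed)
        tr, va = stratified_split(train_data, 1.0 - validation_fraction,
                                  seed=config.seed)
        tr_feat = extract_features(model, tr)
        va_feat = extract_features(model, va)

        def objective(position):
            return fitness(position, space, model, tr, va, seed=config.seed,
                           epochs=epochs, train_features=tr_feat,
                           validation_features=va_feat)

    best_x, best_f, trace = optimize(objective, space.bounds, config)
    return TuningResult(best_hyperparams=decode(best_x, space),
                        best_fitness=best_f, trace=trace, names=space.names)
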