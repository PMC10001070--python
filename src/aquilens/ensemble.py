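"""Weighted majority-voting ensemble of three recurrent classifiers.

The ensemble combines an Elman RNN, a GRU, and a BiLSTM trained on the same
feature vectors.  For an instance with member predictions Δ_ji (1 if member
i votes class j) and member weights w_i ≥ 0, the ensemble class is

    c = argmax_j Σ_i Δ_ji · w_i,

ties broken deterministically toward the lowest class index.  Member
weights default to each member's validation accuracy, normalised to sum to
one (uniform weights are a configurable alternative); with equal weights
the vote reduces to simple majority.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recurrent import SequenceClassifier

__all__ = [
    "MEMBER_KINDS",
    "train_member",
    "weighted_vote",
    "vote_matrix",
    "ensemble_accuracy",
    "set_weights_from_validation",
    "EnsembleSpec",
]

MEMBER_KINDS = ("elman", "gru", "bilstm")


def train_member(cell_kind: str, features: np.ndarray, labels: np.ndarray,
                 seed: int = 0, **kwargs) -> SequenceClassifier:
    """Train one recurrent member on feature vectors; returns the classifier."""
    labels = np.asarray(labels, dtype=int)
    n_classes = int(labels.max()) + 1
    clf = SequenceClassifier(cell_kind, n_features=features.shape[1],
                             n_classes=n_classes, seed=seed, **kwargs)
    try:
        return clf.fit(features, labels)
    except RuntimeError as exc:
        raise RuntimeError(f"member {cell_kind!r} failed: {exc}") from exc


def weighted_vote(predictions, weights) -> int:
    """Class index maximising the weight-sum of members voting for it."""
    predictions = np.asarray(predictions, dtype=int)
    weights = np.asarray(weights, dtype=float)
    if predictions.shape != weights.shape:
        raise ValueError("predictions and weights must have equal length")
    if not weights.sum() > 0:
        raise ValueError("weights must not all be zero")
    scores = np.zeros(int(predictions.max()) + 1)
    np.add.at(scores, predictions, weights)
    return int(np.argmax(scores))  # argmax takes the lowest index on ties


def vote_matrix(member_predictions: np.ndarray, weights,
                n_classes: int) -> np.ndarray:
    """Vectorised vote over instances; member_predictions is (m, n)."""
    preds = np.asarray(member_predictions, dtype=int)
    weights = np.asarray(weights, dtype=float)
    if not weights.sum() > 0:
        raise ValueError("weights must not all be zero")
    m, n = preds.shape
    scores = np.zeros((n, n_classes))
    for i in range(m):
        np.add.at(scores, (np.arange(n), preds[i]), weights[i])
    return np.argmax(scores, axis=1)


def ensemble_accuracy(true_labels, voted_labels) -> float:
    """Percentage of instances whose voted class is the true class."""
    t = np.asarray(true_labels)
    v = np.asarray(voted_labels)
    if t.shape != v.shape:
        raise ValueError("label arrays must have equal length")
    if t.size == 0:
        raise ValueError("accuracy undefined for zero instances")
    return 100.0 * float(np.mean(t == v))


def set_weights_from_validation(members, val_features: np.ndarray,
                                val_labels: np.ndarray) -> np.ndarray:
    """w_i = validation accuracy of member i, normalised to sum to 1."""
    val_labels = np.asarray(val_labels, dtype=int)
    accs = np.array([np.mean(m.predict(val_features) == val_labels)
                     for m in members], dtype=float)
    if accs.sum() == 0:
        warnings.warn("all members at zero validation accuracy; "
                      "falling back to uniform weights", stacklevel=2)
        return np.full(len(members), 1.0 / len(members))
    return accs / accs.sum()


@dataclass
class EnsembleSpec:
    """Trained members plus their voting weights."""

    members: list[SequenceClassifier]
    weights: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.members) != len(self.weights):
            raise ValueError("one weight per member required")
        if not self.weights.sum() > 0:
            raise ValueError("weights must not all be zero")

    def member_predictions(self, features: np.ndarray) -> np.ndarray:
        return np.stack([m.predict(features) for m in self.members])

    def predict(self, features: np.ndarray) -> np.ndarray:
        preds = self.member_predictions(features)
        return vote_matrix(preds, self.weights, len(self.class_names))

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Weight-averaged member probabilities (for the explainer)."""
        probs = [m.predict_proba(features) for m in self.members]
        w = self.weights / self.weights.sum()
        return np.tensordot(w, np.stack(probs), axes=1)

    def prediction_table(self, features: np.ndarray,
                         image_ids: list[str]) -> pd.DataFrame:
        preds = self.member_predictions(features)
        final = vote_matrix(preds, self.weights, len(self.class_names))
        df = pd.DataFrame({"image_id": image_ids})
        for kind, row, w in zip(MEMBER_KINDS, preds, self.weights):
            df[f"vote_{kind}"] = [self.class_names[c] for c in row]
            df[f"weight_{kind}"] = w
        df["final"] = [self.class_names[c] for c in final]
        return df


def train_ensemble(features: np.ndarray, labels: np.ndarray,
                   class_names: tuple[str, ...], seed: int = 0,
                   validation: tuple[np.ndarray, np.ndarray] | None = None,
                   weighting: str = "validation",
                   **member_kwargs) -> EnsembleSpec:
    """Train all three members and set the voting weights.

    When no validation pair is given, a seeded 80/20 split of the training
    features supplies it.
    """
    labels = np.asarray(labels, dtype=int)
    if validation is None and weighting == "validation":
        rng = np.random.default_rng(seed + 17)
        idx = rng.permutation(len(labels))
        n_val = max(1, int(round(0.2 * len(labels))))
        validation = (features[idx[:n_val]], labels[idx[:n_val]])
        features, labels = features[idx[n_val:]], labels[idx[n_val:]]
    members = [train_member(kind, features, labels, seed=seed + k,
                            **member_kwargs)
               for k, kind in enumerate(MEMBER_KINDS)]
    if weighting == "uniform":
        weights = np.full(len(members), 1.0 / len(members))
    else:
        weights = set_weights_from_validation(members, *validation)
    return EnsembleSpec(members=members, weights=weights,
                        class_names=class_names)
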