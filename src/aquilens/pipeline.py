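"""End-to-end orchestration: data → features → tuning → ensemble → report.

A run executes the full diagnosis pipeline in order — load or generate the
image set, preprocess (resize + rescale, no augmentation), extract
Faster-SqueezeNet features, optionally tune the head hyperparameters with
the Aquila optimizer, train the recurrent voting ensemble, score the test
split, and explain a few test instances — writing reports, traces,
explanations, and a manifest (seeds, config hash, package version) into the
run directory.  Every stage draws its seed from the master seed through a
counter-based fan-out, so a run is bit-reproducible end to end.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from ._rng import stage_seed
from .aquila import AAOConfig
from .datasets import (DatasetProfile, LabeledImageSet, builtin_profiles,
                       generate_dataset, load_imageset, stratified_split)
from .ensemble import ensemble_accuracy, train_ensemble
from .explain import explain_instance, save_heatmap
from .metrics import class_report, render_report
from .squeezenet import build_network, default_network_spec, extract_features
from .tuning import default_search_space, tune

__all__ = ["RunConfig", "run", "preprocess"]


@dataclass
class RunConfig:
    """Settings for one end-to-end run."""

    source: str = "dataset1"  # builtin profile name or an image directory
    train_fraction: float = 0.8
    master_seed: int = 0
    output_dir: str = "runs/run0"
    image_size: int = 64
    feature_dim: int = 128
    separability: float = 1.0
    tune_hyperparams: bool = False
    tuning_population: int = 6
    tuning_iterations: int = 5
    head_epochs: int = 20
    member_epochs: int = 25
    member_hidden: int = 24
    timesteps: int = 8
    weighting: str = "validation"  # or "uniform"
    n_explanations: int = 2
    explain_samples: int = 300

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def preprocess(images: np.ndarray, size: int) -> np.ndarray:
    """Resize to the network input size; keep uint8 [0, 255] storage.

    Intensity rescaling to [0, 1] happens inside the feature extractor.
    """
    from PIL import Image

    images = np.asarray(images)
    if images.shape[1] == size and images.shape[2] == size:
        return images
    out = np.empty((len(images), size, size, 3), dtype=np.uint8)
    for i, img in enumerate(images):
        out[i] = np.asarray(
            Image.fromarray(img).resize((size, size), Image.BILINEAR))
    return out


def _load_source(config: RunConfig) -> LabeledImageSet:
    profiles = builtin_profiles()
    if config.source in profiles:
        profile = profiles[config.source].with_separability(
            config.separability)
        return generate_dataset(profile, seed=stage_seed(config.master_seed,
                                                         "generate"))
    return load_imageset(config.source)


def run(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "stages": {},
    }
    config.to_yaml(out / "config.yaml")
    try:
        data = _load_source(config)
        data.images = preprocess(data.images, config.image_size)
        train, test = stratified_split(
            data, config.train_fraction,
            seed=stage_seed(config.master_seed, "split"))
        manifest["stages"]["data"] = {
            "n_train": len(train), "n_test": len(test),
            "classes": list(data.class_names)}

        model = build_network(default_network_spec(config.feature_dim),
                              seed=stage_seed(config.master_seed, "network"))
        model.calibrate_batchnorm(
            np.asarray(train.images[: min(64, len(train))], dtype=float) / 255.0)

        hyperparams = {"epochs": config.head_epochs}
        if config.tune_hyperparams:
            aao = AAOConfig(population_size=config.tuning_population,
                            max_iterations=config.tuning_iterations,
                            seed=stage_seed(config.master_seed, "tune"))
            result = tune(default_search_space(), train, aao, model=model)
            result.trace.to_csv(out / "tuning_trace.csv")
            hyperparams.update(result.best_hyperparams)
            manifest["stages"]["tuning"] = {
                "best_hyperparams": {k: float(v) for k, v
                                     in result.best_hyperparams.items()},
                "best_fitness": result.best_fitness}

        feats_train = extract_features(model, train)
        feats_test = extract_features(model, test)
        np.savez(out / "features.npz", train=feats_train.vectors,
                 test=feats_test.vectors, train_labels=train.labels,
                 test_labels=test.labels)

        ens = train_ensemble(
            feats_train.vectors, train.labels, data.class_names,
            seed=stage_seed(config.master_seed, "ensemble"),
            weighting=config.weighting,
            epochs=config.member_epochs, hidden_units=config.member_hidden,
            timesteps=config.timesteps)
        manifest["stages"]["ensemble"] = {
            "weights": [float(w) for w in ens.weights]}

        pred_train = ens.predict(feats_train.vectors)
        pred_test = ens.predict(feats_test.vectors)
        reports = {
            f"Training Phase ({config.train_fraction:.0%})": class_report(
                train.labels, pred_train, data.class_names),
            f"Testing Phase ({1 - config.train_fraction:.0%})": class_report(
                test.labels, pred_test, data.class_names),
        }
        render_report(reports, out / "class_report.csv")
        ens.prediction_table(feats_test.vectors, test.image_ids).to_csv(
            out / "predictions.csv", index=False)
        manifest["stages"]["evaluation"] = {
            "train_accuracy": ensemble_accuracy(train.labels, pred_train),
            "test_accuracy": ensemble_accuracy(test.labels, pred_test)}

        # explain a few test images through the full image->vote black box
        def black_box(images_batch):
            fm = extract_features(model, LabeledImageSet(
                images=np.clip(images_batch, 0, 255).astype(np.uint8),
                labels=np.zeros(len(images_batch), dtype=int),
                class_names=data.class_names))
            return ens.predict_proba(fm.vectors)

        ex_seed = stage_seed(config.master_seed, "explain")
        for i in range(min(config.n_explanations, len(test))):
            exp = explain_instance(
                test.images[i].astype(float), black_box,
                num_samples=config.explain_samples, seed=ex_seed + i,
                instance_id=test.image_ids[i])
            exp.to_json(out / f"explanation_{test.image_ids[i]}.json")
            save_heatmap(exp, test.images[i],
                         out / f"explanation_{test.image_ids[i]}.png")
    except Exception:
        manifest["status"] = "failed"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise
    manifest["status"] = "ok"
    # digest of the numeric outputs for reproducibility checks
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(feats_test.vectors).tobytes())
    h.update(pred_test.tobytes())
    manifest["numeric_digest"] = h.hexdigest()[:16]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
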