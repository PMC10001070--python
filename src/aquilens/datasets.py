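"""Synthetic class-labelled histology-like image sets.

Real gland/tumour image collections cannot be redistributed, so this module
generates texture images whose class-conditional statistics (blob density,
blob shape irregularity, base colour) differ by a controllable amount.  A
``separability`` knob in [0, 1] linearly interpolates every class's
generative parameters between the pooled mean (separability 0: all classes
identically distributed) and the fully distinct per-class values
(separability 1).

Two built-in profiles mirror the composition of public benchmark sets:

* ``dataset1`` — a two-class colorectal set, 74 benign / 91 malignant
  (165 images, native resolutions 567x430 to 775x522 px);
* ``dataset2`` — a three-class osteosarcoma set, 536 non-tumour (NT) /
  345 viable tumour (VT) / 263 non-viable tumour (NVT) (1144 images).

Synthetic images default to 64x64 px; the native resolutions are carried as
metadata only.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image

from ._rng import rng_from

__all__ = [
    "TextureParams",
    "DatasetProfile",
    "LabeledImageSet",
    "builtin_profiles",
    "generate_dataset",
    "stratified_split",
    "save_imageset",
    "load_imageset",
]


@dataclass(frozen=True)
class TextureParams:
    """Per-class generative texture parameters.

    blob_density   expected number of cell-like blobs per 64x64 tile
    irregularity   0 = round blobs, 1 = strongly lobed boundaries
    base_color     background RGB in [0, 255] (H&E-like pinks/purples)
    blob_color     blob RGB in [0, 255]
    noise_scale    amplitude of the smooth background noise field
    """

    blob_density: float
    irregularity: float
    base_color: tuple[float, float, float]
    blob_color: tuple[float, float, float]
    noise_scale: float

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.blob_density, self.irregularity, *self.base_color,
             *self.blob_color, self.noise_scale],
            dtype=float,
        )

    @staticmethod
    def from_vector(v: np.ndarray) -> "TextureParams":
        return TextureParams(
            blob_density=float(v[0]),
            irregularity=float(np.clip(v[1], 0.0, 1.0)),
            base_color=(float(v[2]), float(v[3]), float(v[4])),
            blob_color=(float(v[5]), float(v[6]), float(v[7])),
            noise_scale=float(max(v[8], 0.0)),
        )


@dataclass(frozen=True)
class DatasetProfile:
    """Composition and generative parameters of a synthetic image set."""

    name: str
    class_names: tuple[str, ...]
    class_counts: dict[str, int]
    image_size: tuple[int, int] = (64, 64)
    texture_params: dict[str, TextureParams] = field(default_factory=dict)
    separability: float = 1.0
    native_resolution: str | None = None  # metadata only, never rendered

    def __post_init__(self) -> None:
        if len(self.class_counts) != len(self.class_names):
            raise ValueError("class_counts must match class_names")
        if sum(self.class_counts.values()) <= 0:
            raise ValueError("profile must contain at least one image")
        for c, n in self.class_counts.items():
            if n <= 0:
                raise ValueError(f"class {c!r} has non-positive count {n}")
        if not 0.0 <= self.separability <= 1.0:
            raise ValueError("separability must lie in [0, 1]")

    @property
    def n_images(self) -> int:
        return sum(self.class_counts.values())

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def with_separability(self, s: float) -> "DatasetProfile":
        return replace(self, separability=float(s))

    def effective_params(self) -> dict[str, TextureParams]:
        """Class parameters after the separability interpolation.

        Each class vector p_c is moved toward the count-unweighted pooled
        mean p̄: p_c(s) = p̄ + s (p_c − p̄), so s = 0 collapses all classes
        onto an identical generative distribution.
        """
        vecs = {c: self.texture_params[c].as_vector() for c in self.class_names}
        mean = np.mean(list(vecs.values()), axis=0)
        s = self.separability
        return {
            c: TextureParams.from_vector(mean + s * (v - mean))
            for c, v in vecs.items()
        }


@dataclass
class LabeledImageSet:
    """Images (n, H, W, 3) uint8 in [0, 255] with integer class labels."""

    images: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...]
    profile_name: str = ""
    seed: int | None = None
    split_role: str = "all"
    image_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch")
        if len(self.labels) and self.labels.max() >= len(self.class_names):
            raise ValueError("label index out of range")
        if not self.image_ids:
            self.image_ids = [f"{self.profile_name or 'img'}_{i:05d}"
                              for i in range(len(self.labels))]

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray, role: str | None = None) -> "LabeledImageSet":
        return LabeledImageSet(
            images=self.images[idx],
            labels=self.labels[idx],
            class_names=self.class_names,
            profile_name=self.profile_name,
            seed=self.seed,
            split_role=role or self.split_role,
            image_ids=[self.image_ids[i] for i in np.asarray(idx)],
        )


def builtin_profiles() -> dict[str, DatasetProfile]:
    """Built-in synthetic profiles mirroring the benchmark compositions."""
    # H&E-ish palette: pink stroma background, purple nuclei blobs
    benign = TextureParams(18, 0.15, (225, 185, 205), (120, 70, 150), 12.0)
    malignant = TextureParams(34, 0.75, (205, 160, 190), (85, 45, 120), 18.0)

    nt = TextureParams(14, 0.10, (230, 195, 210), (130, 85, 160), 10.0)
    vt = TextureParams(32, 0.70, (200, 155, 185), (80, 40, 115), 18.0)
    nvt = TextureParams(24, 0.45, (215, 175, 170), (150, 100, 95), 24.0)

    d1 = DatasetProfile(
        name="dataset1",
        class_names=("benign", "malignant"),
        class_counts={"benign": 74, "malignant": 91},
        texture_params={"benign": benign, "malignant": malignant},
        native_resolution="567x430 to 775x522",
    )
    d2 = DatasetProfile(
        name="dataset2",
        class_names=("NT", "VT", "NVT"),
        class_counts={"NT": 536, "VT": 345, "NVT": 263},
        texture_params={"NT": nt, "VT": vt, "NVT": nvt},
        native_resolution="1024x1024 tiles",
    )
    return {"dataset1": d1, "dataset2": d2}


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  scale: float) -> np.ndarray:
    """Perlin-like smooth field: bilinear upsampling of a coarse random grid."""
    h, w = shape
    ch, cw = max(h // 8, 2), max(w // 8, 2)
    coarse = rng.standard_normal((ch, cw))
    yi = np.linspace(0, ch - 1, h)
    xi = np.linspace(0, cw - 1, w)
    y0 = np.floor(yi).astype(int)
    x0 = np.floor(xi).astype(int)
    y1 = np.minimum(y0 + 1, ch - 1)
    x1 = np.minimum(x0 + 1, cw - 1)
    fy = (yi - y0)[:, None]
    fx = (xi - x0)[None, :]
    field_ = (coarse[np.ix_(y0, x0)] * (1 - fy) * (1 - fx)
              + coarse[np.ix_(y1, x0)] * fy * (1 - fx)
              + coarse[np.ix_(y0, x1)] * (1 - fy) * fx
              + coarse[np.ix_(y1, x1)] * fy * fx)
    return scale * field_


def _render_image(rng: np.random.Generator, params: TextureParams,
                  size: tuple[int, int]) -> np.ndarray:
    h, w = size
    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(params.base_color)
    img += _smooth_noise(rng, (h, w), params.noise_scale)[:, :, None]

    area_scale = (h * w) / (64.0 * 64.0)
    n_blobs = rng.poisson(max(params.blob_density, 0.0) * area_scale)
    yy, xx = np.mgrid[0:h, 0:w]
    blob_color = np.asarray(params.blob_color)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r0 = rng.uniform(2.0, 5.5)
        # lobed boundary: radius modulated by low-order harmonics of angle
        amps = params.irregularity * rng.uniform(0.0, 0.5, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        dy, dx = yy - cy, xx - cx
        dist = np.hypot(dy, dx)
        theta = np.arctan2(dy, dx)
        rim = r0 * (1.0 + sum(a * np.cos((k + 2) * theta + p)
                              for k, (a, p) in enumerate(zip(amps, phases))))
        inside = dist <= np.maximum(rim, 0.5)
        # soft edge for a stained-tissue look
        alpha = np.clip((np.maximum(rim, 0.5) - dist + 1.0) / 2.0, 0.0, 1.0)
        alpha = np.where(inside | (alpha > 0), alpha, 0.0) * 0.85
        img = img * (1 - alpha[:, :, None]) + blob_color * alpha[:, :, None]
    img += rng.normal(0.0, 2.0, size=img.shape)  # sensor-like grain
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_dataset(profile: DatasetProfile, seed: int) -> LabeledImageSet:
    """Generate exactly ``class_counts[c]`` images per class, deterministically.

    The same (profile, seed) pair always yields byte-identical arrays: each
    image gets its own child generator spawned from a ``SeedSequence`` so the
    stream is independent of generation order.
    """
    params = profile.effective_params()
    n_total = profile.n_images
    h, w = profile.image_size
    images = np.empty((n_total, h, w, 3), dtype=np.uint8)
    labels = np.empty(n_total, dtype=int)
    ss = np.random.SeedSequence(int(seed))
    children = ss.spawn(n_total)
    i = 0
    for ci, cname in enumerate(profile.class_names):
        for _ in range(profile.class_counts[cname]):
            rng = np.random.default_rng(children[i])
            images[i] = _render_image(rng, params[cname], (h, w))
            labels[i] = ci
            i += 1
    return LabeledImageSet(
        images=images,
        labels=labels,
        class_names=profile.class_names,
        profile_name=profile.name,
        seed=int(seed),
    )


def stratified_split(
    data: LabeledImageSet, train_fraction: float, seed: int
) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Seeded per-class split into train and test partitions.

    Within each class the indices are shuffled and the first
    round-half-up(count x fraction) go to train, the remainder to test; so
    dataset1 at 0.8 yields 59 + 73 = 132 training and 33 test images.  The
    two outputs partition the input exactly (no overlap, nothing dropped).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly in (0, 1)")
    rng = rng_from(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for ci in range(len(data.class_names)):
        idx = np.flatnonzero(data.labels == ci)
        idx = rng.permutation(idx)
        n_train = int(np.floor(len(idx) * train_fraction + 0.5))
        if n_train == 0 or n_train == len(idx):
            warnings.warn(
                f"class {data.class_names[ci]!r} has an empty side of the "
                f"split (count={len(idx)}, fraction={train_fraction})",
                stacklevel=2,
            )
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    tr = np.sort(np.concatenate(train_idx)).astype(int)
    te = np.sort(np.concatenate(test_idx)).astype(int)
    return data.subset(tr, role="train"), data.subset(te, role="test")


def save_imageset(data: LabeledImageSet, out_dir) -> None:
    """Write a directory-per-class PNG layout plus a CSV manifest."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(len(data)):
        cname = data.class_names[data.labels[i]]
        cdir = out / cname
        cdir.mkdir(exist_ok=True)
        fname = f"{data.image_ids[i]}.png"
        Image.fromarray(data.images[i]).save(cdir / fname)
        rows.append((f"{cname}/{fname}", cname, data.split_role))
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "split"])
        writer.writerows(rows)


def load_imageset(in_dir, class_names: tuple[str, ...] | None = None) -> LabeledImageSet:
    """Read a directory-per-class PNG/JPEG layout (manifest optional)."""
    from pathlib import Path

    root = Path(in_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"image directory not found: {root}")
    if class_names is None:
        class_names = tuple(sorted(p.name for p in root.iterdir() if p.is_dir()))
    images, labels, ids = [], [], []
    for ci, cname in enumerate(class_names):
        cdir = root / cname
        for f in sorted(cdir.glob("*")):
            if f.suffix.lower() not in {".png", ".jpg", ".jpeg"}:
                continue
            try:
                arr = np.asarray(Image.open(f).convert("RGB"))
            except Exception:
                warnings.warn(f"skipping undecodable image {f}", stacklevel=2)
                continue
            images.append(arr)
            labels.append(ci)
            ids.append(f.stem)
    if not images:
        raise FileNotFoundError(f"no images found under {root}")
    return LabeledImageSet(
        images=np.stack(images),
        labels=np.asarray(labels),
        class_names=class_names,
        profile_name=root.name,
        image_ids=ids,
    )
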