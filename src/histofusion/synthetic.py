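"""Synthetic six-class histology-texture dataset.

The real study data (2,019 private skin-biopsy slides, six diagnostic
categories) is not publicly deposited, so this module generates a stand-in
with the same structural properties: per-class image counts, large RGB
source images from which square patches are cut at random and resized to the
network input size, a stratified 7:1:2 train/validation/test split and
k-fold cross-validation indices.

Each class is a distinct texture: a base RGB colour plus a sinusoidal stripe
field with class-specific frequency and orientation, plus i.i.d. Gaussian
pixel noise.  Stripe phase varies per image.  This gives classes that are
statistically separable (by colour means and gradient energy) without any
attempt at visual realism of stained tissue.

Every operation is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

#: per-class occurrence counts of the six diagnostic categories in the
#: emulated dataset (total 2019)
DEFAULT_CLASS_COUNTS = (162, 451, 265, 328, 597, 216)

#: per-class texture descriptors: base RGB colour, stripe frequency
#: (cycles across the image width), stripe orientation (radians),
#: stripe amplitude, Gaussian noise sigma
DEFAULT_TEXTURE_PARAMS = tuple(
    {
        "base_color": color,
        "frequency": freq,
        "orientation": orient,
        "amplitude": 0.18,
        "noise_sigma": 0.05,
    }
    for color, freq, orient in [
        ((0.75, 0.45, 0.55), 4.0, 0.0),
        ((0.55, 0.35, 0.65), 7.0, 0.5),
        ((0.80, 0.60, 0.40), 10.0, 1.0),
        ((0.45, 0.60, 0.60), 13.0, 1.5),
        ((0.65, 0.50, 0.75), 16.0, 2.0),
        ((0.85, 0.70, 0.60), 19.0, 2.5),
    ]
)


class ConfigurationError(ValueError):
    """Invalid generator or split configuration."""


class DimensionError(ValueError):
    """Array dimensions incompatible with the requested operation."""


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic dataset generator.

    Defaults mirror the emulated study: 6 classes with counts
    (162, 451, 265, 328, 597, 216), source images of 2048x1536 pixels,
    960x960 random patches resized to 140x140.  ``scale`` shrinks all
    geometric sizes and the class counts proportionally so the full
    pipeline can run at desk scale; all invariants hold at any scale.
    """

    n_classes: int = 6
    class_counts: tuple[int, ...] = DEFAULT_CLASS_COUNTS
    source_size: tuple[int, int] = (2048, 1536)  # (width, height)
    patch_size: int = 960
    target_size: int = 140
    patches_per_image: int = 10
    texture_params: tuple[dict, ...] = DEFAULT_TEXTURE_PARAMS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ConfigurationError("n_classes must be >= 1")
        if len(self.class_counts) != self.n_classes:
            raise ConfigurationError(
                f"class_counts has {len(self.class_counts)} entries, "
                f"expected n_classes={self.n_classes}"
            )
        if any(c < 1 for c in self.class_counts):
            raise ConfigurationError("all class counts must be >= 1")
        if self.patch_size > min(self.source_size):
            raise ConfigurationError(
                f"patch_size {self.patch_size} exceeds source dimensions "
                f"{self.source_size}"
            )
        if not 1 <= self.target_size <= self.patch_size:
            raise ConfigurationError("need 1 <= target_size <= patch_size")
        if len(self.texture_params) < self.n_classes:
            raise ConfigurationError("texture_params shorter than n_classes")

    def scaled(self, scale: float) -> "SyntheticSpec":
        """Proportionally shrunk copy: sizes and class counts scaled."""
        if not 0 < scale <= 1:
            raise ConfigurationError("scale must be in (0, 1]")
        rnd = lambda v: max(1, int(round(v * scale)))
        return dataclasses.replace(
            self,
            class_counts=tuple(rnd(c) for c in self.class_counts),
            source_size=(rnd(self.source_size[0]), rnd(self.source_size[1])),
            patch_size=rnd(self.patch_size),
            target_size=rnd(self.target_size),
        )


@dataclasses.dataclass
class ImageDataset:
    """Images (H x W x 3 float arrays in [0,1]), 1-based labels, splits."""

    images: list[np.ndarray]
    labels: np.ndarray
    split: np.ndarray | None = None
    seed: int = 0

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, mask: np.ndarray) -> "ImageDataset":
        idx = np.flatnonzero(mask)
        return ImageDataset(
            images=[self.images[i] for i in idx],
            labels=self.labels[idx],
            split=None if self.split is None else self.split[idx],
            seed=self.seed,
        )


def _texture_image(
    width: int, height: int, params: dict, rng: np.random.Generator
) -> np.ndarray:
    """One source image: base colour + oriented sinusoid + Gaussian noise."""
    y, x = np.mgrid[0:height, 0:width].astype(np.float32)
    # normalized coordinates so frequency means cycles across the width,
    # invariant to the absolute pixel size (survives the scaled mode)
    u = (x * np.cos(params["orientation"]) + y * np.sin(params["orientation"])) / width
    phase = rng.uniform(0, 2 * np.pi)
    stripes = np.sin(2 * np.pi * params["frequency"] * u + phase, dtype=np.float32)
    base = np.asarray(params["base_color"], dtype=np.float32)
    img = base[None, None, :] + params["amplitude"] * stripes[:, :, None]
    img += rng.normal(0.0, params["noise_sigma"], img.shape).astype(np.float32)
    return np.clip(img, 0.0, 1.0)


def generate_source_images(spec: SyntheticSpec) -> ImageDataset:
    """Generate all source images of the dataset.

    Returns exactly ``sum(spec.class_counts)`` images with 1-based labels,
    deterministic given ``spec.seed``.  For the full-size default geometry
    this is memory-hungry; :func:`iter_source_images` streams instead.
    """
    images, labels = [], []
    for img, label in iter_source_images(spec):
        images.append(img)
        labels.append(label)
    return ImageDataset(
        images=images, labels=np.asarray(labels, dtype=int), seed=spec.seed
    )


def iter_source_images(spec: SyntheticSpec):
    """Yield ``(image, label)`` pairs in class order, deterministically."""
    w, h = spec.source_size
    for cls in range(spec.n_classes):
        params = spec.texture_params[cls]
        for i in range(spec.class_counts[cls]):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, cls, i])
            )
            yield _texture_image(w, h, params, rng), cls + 1


def extract_random_patches(
    image: np.ndarray, patch_size: int, n: int, seed: int
) -> list[np.ndarray]:
    """Cut ``n`` random axis-aligned square patches fully inside the image."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise DimensionError("expected an H x W x 3 image")
    H, W = image.shape[:2]
    if patch_size > H or patch_size > W:
        raise DimensionError(
            f"patch_size {patch_size} exceeds image size {H}x{W}"
        )
    rng = np.random.default_rng(seed)
    patches = []
    for _ in range(n):
        top = rng.integers(0, H - patch_size + 1)
        left = rng.integers(0, W - patch_size + 1)
        patches.append(image[top : top + patch_size, left : left + patch_size].copy())
    return patches


def resize_patch(patch: np.ndarray, target_size: int) -> np.ndarray:
    """Bilinear resize to target_size x target_size x 3, values kept in [0,1]."""
    if target_size < 1:
        raise ConfigurationError("target_size must be >= 1")
    if patch.shape[0] == patch.shape[1] == target_size:
        return patch.astype(np.float32, copy=True)
    out = _sk_resize(
        patch,
        (target_size, target_size, 3),
        order=1,
        anti_aliasing=target_size < patch.shape[0],
        preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _largest_remainder(n: int, ratios: Sequence[float]) -> list[int]:
    """Apportion n into len(ratios) integer parts by largest remainder."""
    exact = np.asarray(ratios, dtype=float) * n
    base = np.floor(exact).astype(int)
    short = n - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    for j in order[:short]:
        base[j] += 1
    return base.tolist()


SPLIT_NAMES = ("train", "validation", "test")


def split_dataset(
    dataset: ImageDataset, ratios: Sequence[float], seed: int
) -> ImageDataset:
    """Assign train/validation/test splits, stratified per class.

    Within each class the sample counts follow the largest-remainder rule on
    ``ratios``, so per-class proportions match the global ratios within one
    sample.  Returns a new dataset; deterministic given ``seed``.
    """
    ratios = list(ratios)
    if len(ratios) != 3:
        raise ConfigurationError("ratios must have 3 entries")
    if any(r < 0 for r in ratios):
        raise ConfigurationError("ratios must be non-negative")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigurationError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    split = np.empty(len(dataset), dtype=object)
    for cls in np.unique(dataset.labels):
        idx = np.flatnonzero(dataset.labels == cls)
        idx = rng.permutation(idx)
        parts = _largest_remainder(len(idx), ratios)
        start = 0
        for name, count in zip(SPLIT_NAMES, parts):
            split[idx[start : start + count]] = name
            start += count
    return ImageDataset(
        images=dataset.images,
        labels=dataset.labels,
        split=split.astype("U10"),
        seed=dataset.seed,
    )


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """k disjoint index folds partitioning 0..n-1, sizes differing by <= 1."""
    if k < 1 or k > n:
        raise ConfigurationError(f"need 1 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def make_patch_dataset(spec: SyntheticSpec, ratios=(0.7, 0.1, 0.2)) -> ImageDataset:
    """End-to-end dataset build: sources -> split -> patches -> resize.

    The split is assigned at the *source image* level so that patches cut
    from one source never straddle splits (no leakage across splits); the
    split is stratified per class.  Sources are streamed and discarded, so
    peak memory is one source image plus the resized patches.
    """
    # per-source split assignment, stratified by class
    counts = spec.class_counts
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 977]))
    source_split: list[list[str]] = []
    for cls in range(spec.n_classes):
        parts = _largest_remainder(counts[cls], ratios)
        names = np.repeat(SPLIT_NAMES, parts)
        source_split.append(list(rng.permutation(names)))

    images, labels, splits = [], [], []
    per_class_pos = [0] * spec.n_classes
    for source, label in iter_source_images(spec):
        cls = label - 1
        i = per_class_pos[cls]
        per_class_pos[cls] += 1
        patch_seed = int(
            np.random.SeedSequence([spec.seed, 31, cls, i]).generate_state(1)[0]
            % 2**31
        )
        for patch in extract_random_patches(
            source, spec.patch_size, spec.patches_per_image, patch_seed
        ):
            images.append(resize_patch(patch, spec.target_size))
            labels.append(label)
            splits.append(source_split[cls][i])
    return ImageDataset(
        images=images,
        labels=np.asarray(labels, dtype=int),
        split=np.asarray(splits, dtype="U10"),
        seed=spec.seed,
    )


def handcrafted_features(images: Sequence[np.ndarray]) -> np.ndarray:
    """8 simple per-image features: 3 channel means, 3 channel stds,
    horizontal and vertical gradient energy.  Used to verify that the
    generated classes carry learnable signal."""
    rows = []
    for img in images:
        gx = np.diff(img.mean(axis=2), axis=1)
        gy = np.diff(img.mean(axis=2), axis=0)
        rows.append(
            np.concatenate(
                [
                    img.mean(axis=(0, 1)),
                    img.std(axis=(0, 1)),
                    [np.mean(gx**2), np.mean(gy**2)],
                ]
            )
        )
    return np.asarray(rows)


def write_dataset(dataset: ImageDataset, out_dir: str | Path) -> Path:
    """Write images as PNG plus a tab-separated manifest (path, label, split).

    Returns the manifest path."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("path\tlabel\tsplit\n")
        for i, img in enumerate(dataset.images):
            name = f"img_{i:05d}.png"
            iio.imwrite(
                out_dir / name, (img * 255).round().astype(np.uint8)
            )
            split = dataset.split[i] if dataset.split is not None else ""
            fh.write(f"{name}\t{dataset.labels[i]}\t{split}\n")
    return manifest


def read_dataset(manifest: str | Path) -> ImageDataset:
    """Load a dataset from a manifest written by :func:`write_dataset`."""
    import imageio.v3 as iio

    manifest = Path(manifest)
    root = manifest.parent
    images, labels, splits = [], [], []
    with open(manifest) as fh:
        header = fh.readline()
        if not header.startswith("path\t"):
            raise ConfigurationError("manifest missing 'path\\tlabel\\tsplit' header")
        for line in fh:
            path, label, split = line.rstrip("\n").split("\t")
            images.append(
                np.asarray(iio.imread(root / path), dtype=np.float32) / 255.0
            )
            labels.append(int(label))
            splits.append(split)
    return ImageDataset(
        images=images,
        labels=np.asarray(labels, dtype=int),
        split=np.asarray(splits, dtype="U10") if any(splits) else None,
    )
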