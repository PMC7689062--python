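"""Dataset handling: IDX/ubyte readers, a synthetic pattern generator, CSV.

Full-scale runs read MNIST-style IDX files (big-endian magic 2051 for image
tensors, 2049 for label vectors).  For desk-scale experiments and tests the
synthetic generator produces class-discriminable intensity patterns: each
class owns a fixed sparse prototype of bright square blobs on a dark grid,
blobs disjoint across classes, and each sample is the prototype plus
independent per-pixel Gaussian noise clipped to [0, 255].  Intensities are
later rate-coded, so class separation in pixel space translates directly
into separable input spike statistics.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ImageDataset",
    "SyntheticSpec",
    "IdxFormatError",
    "read_idx",
    "write_idx",
    "make_synthetic",
    "write_results",
    "read_results",
]

_MAGIC_IMAGES = 2051
_MAGIC_LABELS = 2049


class IdxFormatError(ValueError):
    """Raised when an IDX file has a bad magic number or truncated payload."""


@dataclass
class ImageDataset:
    """Images (uint8 intensity grids) with aligned integer labels."""

    images: np.ndarray  # (n, h, w) uint8
    labels: np.ndarray  # (n,) int
    split: str = ""

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have the same length")
        if self.images.size and (self.images.min() < 0 or self.images.max() > 255):
            raise ValueError("intensities must lie in [0, 255]")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def _read_header(buf: bytes, path: Path, expected_magic: int, n_dims: int):
    header_len = 4 + 4 * n_dims
    if len(buf) < header_len:
        raise IdxFormatError(f"{path}: truncated header at offset {len(buf)}")
    magic = struct.unpack(">i", buf[:4])[0]
    if magic != expected_magic:
        raise IdxFormatError(
            f"{path}: bad magic {magic} at offset 0 (expected {expected_magic})"
        )
    dims = struct.unpack(f">{n_dims}i", buf[4:header_len])
    return dims, header_len


def read_idx(images_path: str | Path, labels_path: str | Path,
             split: str = "") -> ImageDataset:
    """Read an MNIST-style IDX image/label file pair."""
    images_path, labels_path = Path(images_path), Path(labels_path)
    buf = images_path.read_bytes()
    (n, h, w), off = _read_header(buf, images_path, _MAGIC_IMAGES, 3)
    expected = n * h * w
    payload = buf[off:]
    if len(payload) < expected:
        raise IdxFormatError(
            f"{images_path}: truncated payload at offset {off + len(payload)}"
            f" (expected {expected} bytes)"
        )
    images = np.frombuffer(payload[:expected], dtype=np.uint8).reshape(n, h, w)

    buf = labels_path.read_bytes()
    (n_lab,), off = _read_header(buf, labels_path, _MAGIC_LABELS, 1)
    payload = buf[off:]
    if len(payload) < n_lab:
        raise IdxFormatError(
            f"{labels_path}: truncated payload at offset {off + len(payload)}"
        )
    labels = np.frombuffer(payload[:n_lab], dtype=np.uint8).astype(np.int64)
    return ImageDataset(images=images.copy(), labels=labels, split=split)


def write_idx(dataset: ImageDataset, images_path: str | Path,
              labels_path: str | Path) -> None:
    """Write a dataset as an IDX image/label file pair (test/round-trip aid)."""
    images = np.ascontiguousarray(dataset.images, dtype=np.uint8)
    n, h, w = images.shape
    with open(images_path, "wb") as f:
        f.write(struct.pack(">4i", _MAGIC_IMAGES, n, h, w))
        f.write(images.tobytes())
    with open(labels_path, "wb") as f:
        f.write(struct.pack(">2i", _MAGIC_LABELS, n))
        f.write(np.asarray(dataset.labels, dtype=np.uint8).tobytes())


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic class-pattern generator.

    Each class gets ``blob_count`` bright ``blob_size`` x ``blob_size``
    squares at fixed random positions, disjoint across classes; samples add
    zero-mean Gaussian pixel noise of standard deviation ``noise_sigma``
    intensity units.
    """

    n_classes: int = 3
    grid_h: int = 16
    grid_w: int = 16
    blob_count: int = 3
    blob_size: int = 3
    intensity: int = 255
    noise_sigma: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 < self.intensity <= 255:
            raise ValueError("intensity must lie in (0, 255]")


def _prototypes(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Fixed per-class prototypes with blobs disjoint across all classes."""
    protos = np.zeros((spec.n_classes, spec.grid_h, spec.grid_w))
    occupied = np.zeros((spec.grid_h, spec.grid_w), dtype=bool)
    b = spec.blob_size
    for c in range(spec.n_classes):
        placed = 0
        attempts = 0
        while placed < spec.blob_count:
            attempts += 1
            if attempts > 10000:
                raise ValueError(
                    "could not place disjoint blobs; grid too small for spec"
                )
            r = rng.integers(0, spec.grid_h - b + 1)
            col = rng.integers(0, spec.grid_w - b + 1)
            if occupied[r : r + b, col : col + b].any():
                continue
            protos[c, r : r + b, col : col + b] = spec.intensity
            occupied[r : r + b, col : col + b] = True
            placed += 1
    return protos


def make_synthetic(
    spec: SyntheticSpec, n_train: int, n_test: int
) -> tuple[ImageDataset, ImageDataset]:
    """Generate a train/test dataset pair, reproducible from the spec seed.

    Labels cycle through the classes so both splits are balanced.  With
    ``noise_sigma = 0`` every sample equals its class prototype exactly.
    """
    rng = np.random.default_rng(spec.seed)
    protos = _prototypes(spec, rng)

    def sample(n: int, tag: str) -> ImageDataset:
        labels = np.arange(n) % spec.n_classes
        imgs = protos[labels]
        if spec.noise_sigma > 0:
            imgs = imgs + rng.normal(0.0, spec.noise_sigma, imgs.shape)
        imgs = np.clip(np.rint(imgs), 0, 255).astype(np.uint8)
        return ImageDataset(images=imgs, labels=labels, split=tag)

    return sample(n_train, "train"), sample(n_test, "test")


def write_results(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a sweep/report table as CSV with a fixed header row."""
    frame.to_csv(path, index=False, float_format="%.10g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_results`."""
    return pd.read_csv(path)
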