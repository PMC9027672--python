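"""Seeded synthetic CT-like phantoms with known ground truth.

Real abdominal CT slices of the kind used to develop tumor-screening
pipelines are rarely shareable, so this module builds geometric stand-ins:
a dark background, a brighter elliptical "organ", and (for positive cases)
a still-brighter circular "tumor" blob inside the organ, with optional
additive Gaussian noise.  The three intensity modes give a multilevel
thresholding stage a known three-class structure to recover, and the
presence/absence of the blob gives the classifier a known binary label.

Every generator here is a pure function of its seed and parameters, so
datasets are bit-reproducible.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np


class PhantomSpecError(ValueError):
    """Raised when a phantom specification violates its invariants."""


@dataclass
class GrayImage:
    """A 2-D grayscale image with an explicit gray-level count.

    Parameters
    ----------
    pixels : ndarray of int, shape (height, width)
        Intensities in ``[0, levels - 1]``.
    levels : int
        Number of representable gray levels ``L`` (default 256).
    """

    pixels: np.ndarray
    levels: int = 256

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise PhantomSpecError(f"pixels must be 2-D, got shape {px.shape}")
        if self.levels < 2:
            raise PhantomSpecError(f"levels must be >= 2, got {self.levels}")
        h, w = px.shape
        if h < 8 or w < 8:
            raise PhantomSpecError(f"image must be at least 8x8, got {h}x{w}")
        if not np.issubdtype(px.dtype, np.integer):
            if not np.allclose(px, np.rint(px)):
                raise PhantomSpecError("pixels must hold integer intensities")
            px = np.rint(px).astype(np.int64)
        if px.min() < 0 or px.max() >= self.levels:
            raise PhantomSpecError(
                f"pixel values must lie in [0, {self.levels - 1}], "
                f"got range [{px.min()}, {px.max()}]"
            )
        self.pixels = px.astype(np.int64)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


@dataclass(frozen=True)
class Ellipse:
    """Axis specification for the organ region, in pixel units.

    ``center`` and ``semi_axes`` are (row, col) pairs; ``angle`` rotates the
    row-aligned axis counter-clockwise (radians).
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float = 0.0

    def half_extents(self) -> tuple[float, float]:
        """Half-width of the rotated ellipse's bounding box along rows/cols."""
        ar, ac = self.semi_axes
        c, s = math.cos(self.angle), math.sin(self.angle)
        return (
            math.sqrt((ar * c) ** 2 + (ac * s) ** 2),
            math.sqrt((ar * s) ** 2 + (ac * c) ** 2),
        )

    def contains(self, point: tuple[float, float]) -> bool:
        dr = point[0] - self.center[0]
        dc = point[1] - self.center[1]
        c, s = math.cos(self.angle), math.sin(self.angle)
        u = dr * c + dc * s
        v = -dr * s + dc * c
        ar, ac = self.semi_axes
        return (u / ar) ** 2 + (v / ac) ** 2 <= 1.0


@dataclass(frozen=True)
class Blob:
    """A filled circle (tumor candidate), in pixel units."""

    center: tuple[float, float]
    radius: float


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom image.

    ``mode_intensities`` are the (background, organ, tumor) class means; they
    must be strictly increasing and inside ``[0, levels - 1]``.
    ``mode_sds`` give the per-mode additive Gaussian noise standard deviation
    in intensity units (zeros give a noiseless phantom whose histogram has
    mass only at the three modes).  ``tumor_blob`` must be present exactly
    when ``has_tumor`` is true.
    """

    image_size: tuple[int, int] = (128, 128)
    mode_intensities: tuple[float, float, float] = (40.0, 120.0, 200.0)
    mode_sds: tuple[float, float, float] = (0.0, 0.0, 0.0)
    organ_ellipse: Ellipse = field(
        default_factory=lambda: Ellipse((64.0, 64.0), (42.0, 30.0), 0.0)
    )
    tumor_blob: Optional[Blob] = None
    has_tumor: bool = False
    levels: int = 256
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        if h < 8 or w < 8:
            raise PhantomSpecError(f"image_size must be at least 8x8, got {h}x{w}")
        if self.levels < 2:
            raise PhantomSpecError(f"levels must be >= 2, got {self.levels}")
        modes = self.mode_intensities
        if len(modes) != 3 or len(self.mode_sds) != 3:
            raise PhantomSpecError(
                "mode_intensities and mode_sds must each have 3 entries "
                "(background, organ, tumor)"
            )
        if not (modes[0] < modes[1] < modes[2]):
            raise PhantomSpecError(
                f"mode_intensities must be strictly increasing, got {modes}"
            )
        if modes[0] < 0 or modes[2] > self.levels - 1:
            raise PhantomSpecError(
                f"mode_intensities must lie in [0, {self.levels - 1}], got {modes}"
            )
        if any(sd < 0 for sd in self.mode_sds):
            raise PhantomSpecError(f"mode_sds must be nonnegative, got {self.mode_sds}")
        er, ec = self.organ_ellipse.half_extents()
        cr, cc = self.organ_ellipse.center
        if min(self.organ_ellipse.semi_axes) <= 0:
            raise PhantomSpecError(
                f"organ_ellipse semi_axes must be positive, "
                f"got {self.organ_ellipse.semi_axes}"
            )
        if cr - er < 0 or cr + er > h - 1 or cc - ec < 0 or cc + ec > w - 1:
            raise PhantomSpecError(
                "organ_ellipse must lie fully inside the image bounds"
            )
        if self.has_tumor != (self.tumor_blob is not None):
            raise PhantomSpecError(
                "tumor_blob must be present exactly when has_tumor is set"
            )
        if self.tumor_blob is not None:
            if self.tumor_blob.radius <= 0:
                raise PhantomSpecError(
                    f"tumor_blob radius must be positive, got {self.tumor_blob.radius}"
                )
            if not self.organ_ellipse.contains(self.tumor_blob.center):
                raise PhantomSpecError(
                    "tumor_blob center must lie inside organ_ellipse"
                )


@dataclass(frozen=True)
class PhantomJitter:
    """Per-field perturbation half-ranges used by :func:`generate_dataset`.

    Each field is the half-width of a uniform jitter applied to the base
    spec, in the field's own units (intensity levels, pixels, radians).
    """

    intensity: float = 10.0
    shift: float = 6.0
    axes: float = 6.0
    angle: float = 0.35
    radius: float = 3.0


@dataclass
class LabeledDataset:
    """A sequence of (image-or-feature-vector, binary label) pairs.

    Labels follow the convention 0 = non-tumor, 1 = tumor.  ``meta`` holds
    optional per-item provenance (e.g. the PhantomSpec an image came from).
    """

    items: list
    meta: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for _, label in self.items:
            if label not in (0, 1):
                raise PhantomSpecError(f"labels must be 0 or 1, got {label}")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def labels(self) -> np.ndarray:
        return np.array([label for _, label in self.items], dtype=np.int64)

    @property
    def class_counts(self) -> dict[int, int]:
        labels = self.labels
        return {0: int(np.sum(labels == 0)), 1: int(np.sum(labels == 1))}

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        meta = [self.meta[i] for i in indices] if self.meta else []
        return LabeledDataset([self.items[i] for i in indices], meta=meta)

    def feature_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack feature-vector items into (X, y); fails on image items."""
        xs = []
        for obj, _ in self.items:
            vec = np.asarray(getattr(obj, "values", obj), dtype=float)
            if vec.ndim != 1:
                raise PhantomSpecError("items are not feature vectors")
            xs.append(vec)
        return np.vstack(xs), self.labels


def _region_masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    h, w = spec.image_size
    rows, cols = np.mgrid[0:h, 0:w]
    ell = spec.organ_ellipse
    c, s = math.cos(ell.angle), math.sin(ell.angle)
    dr = rows - ell.center[0]
    dc = cols - ell.center[1]
    u = dr * c + dc * s
    v = -dr * s + dc * c
    ar, ac = ell.semi_axes
    organ = (u / ar) ** 2 + (v / ac) ** 2 <= 1.0
    if spec.tumor_blob is not None:
        blob = spec.tumor_blob
        tumor = (rows - blob.center[0]) ** 2 + (
            cols - blob.center[1]
        ) ** 2 <= blob.radius**2
        tumor &= organ  # blob never spills outside the organ
    else:
        tumor = np.zeros((h, w), dtype=bool)
    return organ, tumor


def generate_phantom(spec: PhantomSpec) -> GrayImage:
    """Render one phantom image from its spec.

    The image is built mode-by-mode (background, organ ellipse, tumor blob),
    then per-mode Gaussian noise is added, and the result is rounded and
    clipped to ``[0, levels - 1]``.  With all ``mode_sds`` zero the distinct
    pixel values are exactly the specified modes.  Identical specs (including
    the seed) yield bit-identical images.
    """
    spec.validate()
    organ, tumor = _region_masks(spec)
    base = np.full(spec.image_size, float(spec.mode_intensities[0]))
    sd_map = np.full(spec.image_size, float(spec.mode_sds[0]))
    base[organ] = spec.mode_intensities[1]
    sd_map[organ] = spec.mode_sds[1]
    base[tumor] = spec.mode_intensities[2]
    sd_map[tumor] = spec.mode_sds[2]
    rng = np.random.default_rng(spec.seed)
    noisy = base + rng.standard_normal(spec.image_size) * sd_map
    pixels = np.clip(np.rint(noisy), 0, spec.levels - 1).astype(np.int64)
    return GrayImage(pixels, levels=spec.levels)


def _jitter_spec(
    base: PhantomSpec,
    jitter: PhantomJitter,
    label: int,
    rng: np.random.Generator,
    tumor_radius: float,
) -> PhantomSpec:
    h, w = base.image_size
    modes = list(base.mode_intensities)
    for i in range(3):
        modes[i] = modes[i] + rng.uniform(-jitter.intensity, jitter.intensity)
    # keep the modes ordered and inside range despite jitter
    modes[0] = float(np.clip(modes[0], 0, base.levels - 11))
    modes[1] = float(np.clip(modes[1], modes[0] + 5, base.levels - 6))
    modes[2] = float(np.clip(modes[2], modes[1] + 5, base.levels - 1))

    ell = base.organ_ellipse
    axes = tuple(
        float(np.clip(a + rng.uniform(-jitter.axes, jitter.axes), 8.0, min(h, w) / 2 - 2))
        for a in ell.semi_axes
    )
    angle = ell.angle + rng.uniform(-jitter.angle, jitter.angle)
    trial = Ellipse(ell.center, axes, angle)
    er, ec = trial.half_extents()
    center = (
        float(np.clip(ell.center[0] + rng.uniform(-jitter.shift, jitter.shift), er, h - 1 - er)),
        float(np.clip(ell.center[1] + rng.uniform(-jitter.shift, jitter.shift), ec, w - 1 - ec)),
    )
    ellipse = Ellipse(center, axes, angle)

    blob = None
    if label == 1:
        radius = float(
            np.clip(
                tumor_radius + rng.uniform(-jitter.radius, jitter.radius),
                2.0,
                0.5 * min(axes),
            )
        )
        # sample the blob center inside the (unrotated) half-axes box, then
        # rotate into the ellipse frame; rejection keeps it inside the ellipse
        c, s = math.cos(angle), math.sin(angle)
        for _ in range(64):
            u = rng.uniform(-0.5, 0.5) * axes[0]
            v = rng.uniform(-0.5, 0.5) * axes[1]
            bc = (center[0] + u * c - v * s, center[1] + u * s + v * c)
            if ellipse.contains(bc):
                blob = Blob(bc, radius)
                break
        if blob is None:  # pragma: no cover - rejection virtually never exhausts
            blob = Blob(center, radius)

    return replace(
        base,
        mode_intensities=tuple(modes),
        organ_ellipse=ellipse,
        tumor_blob=blob,
        has_tumor=(label == 1),
        seed=int(rng.integers(2**31)),
    )


def generate_dataset(
    n_per_class: int,
    base_spec: Optional[PhantomSpec] = None,
    jitter: Optional[PhantomJitter] = None,
    seed: int = 0,
    tumor_radius: float = 9.0,
) -> LabeledDataset:
    """Generate a balanced labeled phantom dataset.

    Returns ``2 * n_per_class`` items, exactly ``n_per_class`` per label,
    ordered non-tumor first.  Per-item specs are drawn reproducibly from
    ``seed`` by jittering ``base_spec``.
    """
    if n_per_class < 1:
        raise PhantomSpecError(f"n_per_class must be >= 1, got {n_per_class}")
    if base_spec is None:
        base_spec = PhantomSpec(mode_sds=(6.0, 6.0, 6.0))
    if jitter is None:
        jitter = PhantomJitter()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9E3779]))
    items = []
    meta = []
    for label in (0, 1):
        for _ in range(n_per_class):
            spec = _jitter_spec(base_spec, jitter, label, rng, tumor_radius)
            items.append((generate_phantom(spec), label))
            meta.append(spec)
    return LabeledDataset(items, meta=meta)


def generate_feature_clusters(
    n_per_class: int,
    dim: int = 8,
    centers: Optional[tuple[np.ndarray, np.ndarray]] = None,
    sd: float = 1.0,
    seed: int = 0,
) -> LabeledDataset:
    """Two isotropic Gaussian clusters of feature vectors, one per label.

    With the default centers the classes sit 10 standard deviations apart,
    making the dataset trivially separable — a controlled fixture for
    classifier training, not a realistic feature distribution.
    """
    if n_per_class < 1:
        raise PhantomSpecError(f"n_per_class must be >= 1, got {n_per_class}")
    if sd <= 0:
        raise PhantomSpecError(f"sd must be positive, got {sd}")
    if centers is None:
        c0 = np.zeros(dim)
        c1 = np.full(dim, 10.0 * sd / math.sqrt(dim))
    else:
        c0 = np.asarray(centers[0], dtype=float)
        c1 = np.asarray(centers[1], dtype=float)
    if c0.shape != (dim,) or c1.shape != (dim,):
        raise PhantomSpecError(f"centers must be length-{dim} vectors")
    if np.array_equal(c0, c1):
        raise PhantomSpecError("centers must be distinct")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5F356]))
    items = []
    for label, center in ((0, c0), (1, c1)):
        samples = center + sd * rng.standard_normal((n_per_class, dim))
        items.extend((samples[i], label) for i in range(n_per_class))
    return LabeledDataset(items)


def write_dataset(dataset: LabeledDataset, out_dir: str | Path) -> Path:
    """Write phantom images as 8-bit grayscale PNGs plus a CSV manifest.

    The manifest has one row per image: filename, label, and (when the
    dataset carries specs) seed and mode intensities.  Returns the manifest
    path.
    """
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "seed", "mode_intensities"])
        for i, (img, label) in enumerate(dataset.items):
            if not isinstance(img, GrayImage):
                raise PhantomSpecError("write_dataset requires image items")
            name = f"phantom_{i:04d}.png"
            scale = 255 // (img.levels - 1) if img.levels <= 256 else 1
            arr = (img.pixels * scale if img.levels < 256 else img.pixels).astype(
                np.uint8
            )
            Image.fromarray(arr, mode="L").save(out / name)
            spec = dataset.meta[i] if dataset.meta else None
            writer.writerow(
                [
                    name,
                    label,
                    getattr(spec, "seed", ""),
                    ";".join(f"{m:.1f}" for m in spec.mode_intensities)
                    if spec is not None
                    else "",
                ]
            )
    return manifest
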