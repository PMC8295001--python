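"""Synthetic brain-like phantoms with known ground truth and controllable noise.

A phantom is a piecewise-constant multi-class intensity image on the unit
intensity range [0, 1], together with its generating label map.  Phantoms stand
in for real MRI test images in the noise-robustness benchmark: every tissue
class has a single nominal intensity, and degradation is injected afterwards by
:func:`add_noise` at a controlled level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

GEOMETRIES = ("concentric", "blobs", "checker")
NOISE_KINDS = ("gaussian", "rician", "impulse")

#: Default class intensities: background / CSF / GM / WM-like tissue.
DEFAULT_CLASS_MEANS = (0.05, 0.35, 0.65, 0.95)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic phantom.

    Parameters
    ----------
    shape
        Grid dimensions in pixels, 2-D or 3-D, every axis >= 16.
    n_classes
        Number of tissue classes including background (2..10).
    class_means
        Per-class nominal intensity in [0, 1], pairwise distinct, ascending.
    geometry
        ``concentric`` (ring-like tissue shells), ``blobs`` (Voronoi cells of
        random sites) or ``checker`` (tiled pattern).
    min_region_fraction
        Smallest admissible pixel fraction for any class in the truth.
    seed
        RNG seed; the phantom is a pure function of the spec.
    """

    shape: tuple = (128, 128)
    n_classes: int = 4
    class_means: tuple = DEFAULT_CLASS_MEANS
    geometry: str = "concentric"
    min_region_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        means = tuple(float(v) for v in self.class_means)
        object.__setattr__(self, "class_means", means)
        if len(shape) not in (2, 3):
            raise ValueError("phantom shape must be 2-D or 3-D")
        if any(s < 16 for s in shape):
            raise ValueError("every phantom axis must be >= 16 pixels")
        if not (2 <= self.n_classes <= 10):
            raise ValueError("n_classes must be in 2..10")
        if len(means) != self.n_classes:
            raise ValueError("class_means must have one entry per class")
        if any(not (0.0 <= v <= 1.0) for v in means):
            raise ValueError("class_means must lie in [0, 1]")
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError("class_means must be pairwise distinct and ascending")
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}")
        if not (0.0 <= self.min_region_fraction <= 1.0):
            raise ValueError("min_region_fraction must be a fraction")


@dataclass(frozen=True)
class NoiseModel:
    """Noise injection recipe on the unit intensity scale.

    ``level`` is the noise standard deviation relative to the [0, 1] intensity
    range for ``gaussian`` and ``rician``, and the per-pixel corruption
    probability for ``impulse`` (salt-and-pepper).  ``level = 0`` leaves the
    image bit-identical.
    """

    kind: str = "gaussian"
    level: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"noise kind must be one of {NOISE_KINDS}")
        if self.level < 0:
            raise ValueError("noise level must be non-negative")
        if self.kind == "impulse" and self.level > 1:
            raise ValueError("impulse corruption fraction cannot exceed 1")


@dataclass(frozen=True)
class LabeledPhantom:
    """A generated phantom image together with its ground-truth label map."""

    image: np.ndarray
    truth: np.ndarray
    spec: PhantomSpec

    def __post_init__(self):
        if self.image.shape != self.truth.shape:
            raise ValueError("image and truth must have identical shape")


def _concentric_truth(spec: PhantomSpec) -> np.ndarray:
    # Equal-count distance bands around the grid centre: class n_classes-1
    # (brightest, WM-like) innermost, class 0 (background) outermost.  Equal
    # counts make every class fraction ~1/K exactly.
    grids = np.indices(spec.shape, dtype=float)
    center = [(s - 1) / 2.0 for s in spec.shape]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    flat = d2.ravel()
    n = flat.size
    order = np.argsort(flat, kind="stable")
    band = np.empty(n, dtype=np.int64)
    band[order] = (np.arange(n) * spec.n_classes) // n
    return (spec.n_classes - 1 - band).reshape(spec.shape)


def _blobs_truth(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    grids = np.indices(spec.shape, dtype=float)
    coords = np.stack([g.ravel() for g in grids], axis=1)
    for _ in range(200):
        sites = rng.uniform(0, 1, size=(spec.n_classes, len(spec.shape)))
        sites *= np.asarray(spec.shape, dtype=float)
        d2 = ((coords[:, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
        truth = d2.argmin(axis=1).reshape(spec.shape)
        counts = np.bincount(truth.ravel(), minlength=spec.n_classes)
        if counts.min() >= spec.min_region_fraction * truth.size:
            return truth
    raise ValueError(
        "could not place blobs satisfying min_region_fraction "
        f"{spec.min_region_fraction} for {spec.n_classes} classes"
    )


def _checker_truth(spec: PhantomSpec) -> np.ndarray:
    tile = max(4, min(spec.shape) // (2 * spec.n_classes))
    grids = np.indices(spec.shape)
    truth = sum(g // tile for g in grids) % spec.n_classes
    counts = np.bincount(truth.ravel(), minlength=spec.n_classes)
    if counts.min() < spec.min_region_fraction * truth.size:
        raise ValueError("checker tiling cannot satisfy min_region_fraction")
    return truth.astype(np.int64)


def generate_phantom(spec: PhantomSpec) -> LabeledPhantom:
    """Generate a noiseless piecewise-constant phantom from its spec.

    The returned image satisfies ``image == class_means[truth]`` pixelwise and
    is bit-reproducible given the spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.geometry == "concentric":
        truth = _concentric_truth(spec)
    elif spec.geometry == "blobs":
        truth = _blobs_truth(spec, rng)
    else:
        truth = _checker_truth(spec)
    counts = np.bincount(truth.ravel(), minlength=spec.n_classes)
    if counts.min() < spec.min_region_fraction * truth.size:
        raise ValueError("generated truth violates min_region_fraction")
    image = np.asarray(spec.class_means, dtype=np.float64)[truth]
    return LabeledPhantom(image=image, truth=truth, spec=spec)


def add_noise(image: np.ndarray, model: NoiseModel) -> np.ndarray:
    """Degrade an image on the unit scale; output is clipped to [0, 1].

    Gaussian: additive N(0, level^2).  Rician: magnitude of the complex signal
    with independent N(0, level^2) noise on both quadratures, the canonical
    noise model of magnitude MRI.  Impulse: each pixel independently replaced
    by 0 or 1 with probability ``level``.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.min() < -1e-12 or image.max() > 1 + 1e-12:
        raise ValueError("add_noise expects intensities in [0, 1]")
    if model.level == 0:
        return image.copy()
    rng = np.random.default_rng(model.seed)
    if model.kind == "gaussian":
        out = image + rng.normal(0.0, model.level, size=image.shape)
    elif model.kind == "rician":
        re = image + rng.normal(0.0, model.level, size=image.shape)
        im = rng.normal(0.0, model.level, size=image.shape)
        out = np.hypot(re, im)
    else:  # impulse
        mask = rng.random(image.shape) < model.level
        values = rng.integers(0, 2, size=image.shape).astype(np.float64)
        out = image.copy()
        out[mask] = values[mask]
    return np.clip(out, 0.0, 1.0)


def noise_level_grid(low: float, high: float, steps: int) -> list:
    """Evenly spaced inclusive grid of noise levels."""
    if steps < 2:
        raise ValueError("steps must be >= 2")
    if not (0 <= low < high):
        raise ValueError("need 0 <= low < high")
    return [float(v) for v in np.linspace(low, high, steps)]
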