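"""Classic fuzzy C-means clustering for grayscale image segmentation.

FCM partitions the pixel intensities X = {x_1..x_n} into b fuzzy classes by
minimizing

    G_FCM(U, V) = sum_k sum_i mu_ki^m * ||x_i - v_k||^2

subject to sum_k mu_ki = 1 for every pixel i, where U = (mu_ki) is the
membership matrix, V = (v_k) the cluster centers and m > 1 the fuzzifier.
Setting the Lagrangian's partial derivatives to zero yields the alternating
closed-form updates implemented here:

    v_k   = sum_i mu_ki^m x_i / sum_i mu_ki^m
    mu_ki = 1 / sum_l (c_ki / c_li)^(2/(m-1)),   c_ki = ||x_i - v_k||

Intensities are min-max normalized to [0, 1] before clustering so tolerances
and noise levels are scale-free; centers are reported on the normalized scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

INIT_METHODS = ("random-pixels", "quantile", "kmeans-like")


@dataclass(frozen=True)
class FCMConfig:
    """Parameters of the FCM iteration.

    ``fuzzifier`` m > 1 controls membership softness (m=2 is the universal
    default; m -> 1 approaches crisp k-means).  Convergence is declared when
    the largest absolute membership change over one sweep drops below ``tol``.
    ``distance_floor`` is the distance below which a pixel is treated as lying
    exactly on a center and receives crisp membership.
    """

    n_clusters: int = 4
    fuzzifier: float = 2.0
    tol: float = 1e-5
    max_iter: int = 200
    init: str = "quantile"
    seed: int = 0
    distance_floor: float = 1e-12

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.init not in INIT_METHODS:
            raise ValueError(f"init must be one of {INIT_METHODS}")
        if self.distance_floor < 0:
            raise ValueError("distance_floor must be non-negative")


@dataclass
class SegmentationResult:
    """Output of a fuzzy segmentation run.

    ``memberships`` is the b x n matrix on the flattened pixel grid,
    ``labels`` the defuzzified (argmax) label map in image shape, and
    ``objective_trace`` the objective value after initialization and after
    each iteration.
    """

    memberships: np.ndarray
    centers: np.ndarray
    labels: np.ndarray
    objective_trace: list
    n_iter: int
    converged: bool


def as_array(image) -> np.ndarray:
    """Accept a bare ndarray or any object carrying a ``values`` array."""
    arr = np.asarray(getattr(image, "values", image), dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def normalize_intensities(image) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant image maps to all zeros."""
    arr = as_array(image)
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        return (arr - lo) / (hi - lo)
    return np.zeros_like(arr)


def _make_distinct(centers: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Replace duplicate centers with unused candidate values, deterministically."""
    out = list(centers)
    seen: list = []
    for idx, v in enumerate(out):
        if any(abs(v - s) < 1e-15 for s in seen):
            for cand in candidates:
                if all(abs(cand - s) >= 1e-15 for s in seen):
                    out[idx] = float(cand)
                    break
        seen.append(out[idx])
    return np.asarray(out, dtype=np.float64)


def initialize_centers(image, config: FCMConfig) -> np.ndarray:
    """Pick b distinct initial centers from the pixel intensities.

    ``quantile`` places centers at the (2k+1)/(2b) quantiles, ``random-pixels``
    draws b distinct observed intensities, and ``kmeans-like`` refines the
    quantile start with a few Lloyd iterations.  All are deterministic given
    the seed.
    """
    x = as_array(image).ravel()
    b = config.n_clusters
    if x.size < b:
        raise ValueError("fewer pixels than clusters")
    uniq = np.unique(x)
    if uniq.size < b:
        raise ValueError(
            f"image has only {uniq.size} distinct intensities; need >= {b}"
        )
    if config.init == "random-pixels":
        rng = np.random.default_rng(config.seed)
        v = np.sort(rng.choice(uniq, size=b, replace=False))
    else:
        q = (2 * np.arange(b) + 1) / (2 * b)
        v = np.quantile(x, q)
        if config.init == "kmeans-like":
            for _ in range(10):
                labels = np.abs(x[None, :] - v[:, None]).argmin(axis=0)
                for k in range(b):
                    mask = labels == k
                    if mask.any():
                        v[k] = x[mask].mean()
    v = _make_distinct(np.asarray(v, dtype=np.float64), uniq)
    if np.unique(v).size < b:
        raise ValueError("could not find b distinct initial centers")
    return v


def _sqdist(x: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Squared distances c_ki^2, shape (b, n)."""
    return (x[None, :] - np.asarray(centers, dtype=np.float64)[:, None]) ** 2


def memberships_from_sqdist(d2: np.ndarray, m: float,
                            distance_floor: float = 1e-12) -> np.ndarray:
    """Normalized FCM memberships from (possibly penalized) squared distances.

    mu_ki = 1 / sum_l (d2_ki / d2_li)^(1/(m-1)); pixels with some distance at
    or below the floor get membership split equally over the touching centers.
    """
    expo = 1.0 / (m - 1.0)
    floor2 = distance_floor * distance_floor
    zero = d2 <= floor2
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        ratios = (d2[:, None, :] / d2[None, :, :]) ** expo
        mu = 1.0 / ratios.sum(axis=1)
    crisp_cols = zero.any(axis=0)
    if crisp_cols.any():
        z = zero[:, crisp_cols].astype(np.float64)
        mu[:, crisp_cols] = z / z.sum(axis=0)
    return mu


def update_memberships(image, centers, m: float,
                       distance_floor: float = 1e-12) -> np.ndarray:
    """Closed-form membership update for fixed centers (b x n matrix)."""
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    x = as_array(image).ravel()
    return memberships_from_sqdist(_sqdist(x, centers), m, distance_floor)


def update_centers(image, memberships: np.ndarray, m: float) -> np.ndarray:
    """Centers as the mu^m-weighted mean of the pixels."""
    x = as_array(image).ravel()
    mu = np.asarray(memberships, dtype=np.float64)
    if np.any(mu.sum(axis=1) <= 0):
        raise ValueError("membership matrix has an all-zero class row")
    w = mu ** m
    denom = w.sum(axis=1)
    if np.any(denom <= 0):
        raise ValueError("degenerate mu^m weights for some class")
    return (w @ x) / denom


def fcm_objective(image, memberships: np.ndarray, centers, m: float) -> float:
    """G_FCM = sum_k sum_i mu_ki^m c_ki^2 (non-negative)."""
    x = as_array(image).ravel()
    mu = np.asarray(memberships, dtype=np.float64)
    return float((mu ** m * _sqdist(x, centers)).sum())


def defuzzify(memberships: np.ndarray) -> np.ndarray:
    """Crisp labels by per-pixel argmax; ties go to the lowest class index."""
    return np.asarray(memberships).argmax(axis=0)


MembershipFn = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]


def _alternate(x: np.ndarray, shape: tuple, config: FCMConfig,
               membership_fn: MembershipFn,
               objective_fn: Callable[[np.ndarray, np.ndarray, np.ndarray], float],
               initial_centers: Optional[np.ndarray]) -> SegmentationResult:
    """Shared alternating-optimization loop for FCM and its spatial variant."""
    if initial_centers is None:
        v = initialize_centers(x, config)
    else:
        v = np.asarray(initial_centers, dtype=np.float64).copy()
        if v.size != config.n_clusters:
            raise ValueError("initial_centers size must equal n_clusters")
    mu = membership_fn(x, v, None)
    trace = [objective_fn(x, mu, v)]
    converged = False
    n_iter = 0
    for it in range(config.max_iter):
        v = update_centers(x, mu, config.fuzzifier)
        mu_new = membership_fn(x, v, mu)
        n_iter = it + 1
        trace.append(objective_fn(x, mu_new, v))
        delta = float(np.abs(mu_new - mu).max())
        mu = mu_new
        if delta < config.tol:
            converged = True
            break
    labels = defuzzify(mu).reshape(shape)
    return SegmentationResult(memberships=mu, centers=v, labels=labels,
                              objective_trace=trace, n_iter=n_iter,
                              converged=converged)


def run_fcm(image, config: FCMConfig,
            initial_centers: Optional[np.ndarray] = None) -> SegmentationResult:
    """Run FCM to convergence on a (min-max normalized) intensity image.

    Alternates center and membership updates until the largest membership
    change falls below ``config.tol`` or ``config.max_iter`` sweeps.  The
    objective trace is non-increasing (alternating optimization is a descent
    method).  Deterministic given the config seed.
    """
    arr = as_array(image)
    x = normalize_intensities(arr).ravel()

    def _memb(xv, v, prev):
        return update_memberships(xv, v, config.fuzzifier, config.distance_floor)

    def _obj(xv, mu, v):
        return fcm_objective(xv, mu, v, config.fuzzifier)

    return _alternate(x, arr.shape, config, _memb, _obj, initial_centers)
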