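"""Synthetic imagery: scaled step edges, multi-region scenes, white noise.

The scaled-edge model is a step edge of contrast ``c0`` on a base level
``b0`` blurred by an isotropic Gaussian of scale ``omega0``:

    f(x) = c0 * H([cos theta0, sin theta0] . x) + b0  convolved with  g(x; omega0)

where ``H`` is the Heaviside step.  Along the edge normal this equals the
closed form ``c0 * Phi(d / omega0) + b0`` with ``Phi`` the standard
normal CDF and ``d`` the signed distance to the centerline, which is what
:func:`scaled_edge_image` evaluates (exact for the continuous model).

Multi-region scenes are seeded Voronoi partitions with well separated
random colors; together with :func:`add_white_noise` they provide ground
truth for the segmentation metrics without any external dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import ndtr

__all__ = [
    "EdgeModelParams",
    "NoiseModel",
    "SyntheticScene",
    "heaviside",
    "scaled_edge_image",
    "piecewise_constant_scene",
    "add_white_noise",
]


@dataclass(frozen=True)
class EdgeModelParams:
    """Parameters of a Gaussian-blurred step edge.

    omega0 : blur scale of the edge in pixels (>= 1)
    theta0 : direction of the edge normal in [0, pi)
    c0     : contrast (step height) in [0, 1]
    b0     : base intensity level, with b0 + c0 <= 1
    """

    omega0: float
    theta0: float
    c0: float
    b0: float

    def __post_init__(self) -> None:
        if self.omega0 < 1:
            raise ValueError("omega0 must be >= 1 pixel")
        if not (0.0 <= self.theta0 < math.pi):
            raise ValueError("theta0 must lie in [0, pi)")
        if not (0.0 <= self.c0 <= 1.0):
            raise ValueError("c0 must lie in [0, 1]")
        if self.b0 < 0 or self.b0 + self.c0 > 1.0:
            raise ValueError("need b0 >= 0 and b0 + c0 <= 1")


@dataclass(frozen=True)
class NoiseModel:
    """Zero-mean white Gaussian noise of standard deviation ``epsilon0``."""

    epsilon0: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon0 < 0:
            raise ValueError("epsilon0 must be non-negative")


@dataclass(frozen=True)
class SyntheticScene:
    """A generated image with its ground-truth label map."""

    image: np.ndarray  # H x W x Q floats
    gt: np.ndarray  # H x W integer labels, contiguous from 1
    region_colors: np.ndarray  # n_regions x Q


def heaviside(u):
    """Heaviside step: 0 for u < 0, 1 otherwise (vectorized)."""
    return np.where(np.asarray(u, dtype=float) < 0, 0, 1)[()]


def scaled_edge_image(
    shape: tuple[int, int],
    params: EdgeModelParams,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Render the blurred-step edge model on a pixel grid.

    Parameters
    ----------
    shape
        (rows, cols); each dimension must be at least ``8 * omega0`` so
        the far field settles to its asymptotes.
    params
        Edge model parameters.
    center
        (x, y) point on the edge centerline; defaults to the integer
        pixel (cols // 2, rows // 2) so the centerline passes through a
        pixel column/row exactly.
    """
    rows, cols = shape
    if rows < 8 * params.omega0 or cols < 8 * params.omega0:
        raise ValueError("image must span at least 8 * omega0 in each dimension")
    if center is None:
        center = (cols // 2, rows // 2)
    cx, cy = center
    y, x = np.mgrid[0:rows, 0:cols].astype(float)
    d = math.cos(params.theta0) * (x - cx) + math.sin(params.theta0) * (y - cy)
    return params.c0 * ndtr(d / params.omega0) + params.b0


def add_white_noise(image: np.ndarray, noise: NoiseModel) -> np.ndarray:
    """Add i.i.d. N(0, epsilon0^2) noise per pixel/channel (not clipped)."""
    if noise.epsilon0 == 0:
        return np.array(image, dtype=float, copy=True)
    rng = np.random.default_rng(noise.seed)
    return np.asarray(image, dtype=float) + rng.normal(
        0.0, noise.epsilon0, size=np.shape(image)
    )


def piecewise_constant_scene(
    shape: tuple[int, int],
    n_regions: int,
    blur_scale: float = 0.0,
    noise: NoiseModel | None = None,
    n_channels: int = 3,
    seed: int | None = None,
    min_color_distance: float = 0.2,
    max_attempts: int = 1000,
) -> SyntheticScene:
    """Generate a Voronoi partition with distinct region colors.

    The frame is partitioned into ``n_regions`` Voronoi cells around
    seeded random sites; each cell gets a random color whose pairwise
    Euclidean distance to every other color is at least
    ``min_color_distance``.  The image may then be blurred by an
    isotropic Gaussian of scale ``blur_scale`` and corrupted by white
    noise.  The ground truth is the unblurred, noise-free partition.

    Fully deterministic given (shape, n_regions, blur_scale, seed); the
    seed defaults to ``noise.seed`` when a noise model is given.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    rows, cols = shape
    if n_regions > rows * cols:
        raise ValueError("more regions than pixels")
    if seed is None:
        seed = noise.seed if noise is not None else 0
    rng = np.random.default_rng(seed)

    # distinct pixel sites so every cell owns at least its own site
    flat_sites = rng.choice(rows * cols, size=n_regions, replace=False)
    sy, sx = np.divmod(flat_sites, cols)
    y, x = np.mgrid[0:rows, 0:cols]
    d2 = (y[..., None] - sy) ** 2 + (x[..., None] - sx) ** 2
    gt = np.argmin(d2, axis=-1).astype(np.int32) + 1

    for _ in range(max_attempts):
        colors = rng.uniform(0.0, 1.0, size=(n_regions, n_channels))
        diff = colors[:, None, :] - colors[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        if dist.min() >= min_color_distance:
            break
    else:
        raise RuntimeError(
            "could not draw region colors with the requested separation"
        )

    image = colors[gt - 1]
    if blur_scale > 0:
        image = gaussian_filter(image, sigma=(blur_scale, blur_scale, 0.0))
    if noise is not None:
        image = add_white_noise(image, noise)
    return SyntheticScene(image=image, gt=gt, region_colors=colors)
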