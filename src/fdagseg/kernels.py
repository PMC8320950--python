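"""Discrete anisotropic Gaussian and normalized FDAG kernel banks.

A directional anisotropic Gaussian at scale ``sigma``, anisotropy ``phi``
and orientation ``theta`` (measured from the +x axis toward +y) is

    g(x) = 1 / (2 pi phi sigma^2) * exp(-1/(2 sigma^2) x^T R^T diag(1, phi^-2) R x)

with R the rotation matrix by ``theta``.  Its first derivative along the
orientation axis (the FDAG kernel) is

    g'(x) = -([cos theta, sin theta] . x / sigma^2) * g(x)

and the scale-normalized version used for characteristic-scale selection
multiplies by 2 * sqrt(pi) * sigma^(1/2):

    g~'(x) = 2 * sqrt(pi) * sigma^(1/2) * g'(x).

With this normalization, the response to a Gaussian-blurred step edge of
blur scale ``omega0`` and contrast ``c0`` is
``sqrt(2) * c0 * sigma^(1/2) / sqrt(omega0^2 + sigma^2)``: it peaks in
scale space exactly at ``sigma = omega0`` with value
``c0 / sqrt(omega0)``, which is what makes per-pixel scale selection and
contrast recovery work.

The anisotropy of each bank member adapts to its scale: small scales,
which are noise-sensitive, are elongated (phi = (sigma_con/sigma)^2 for
sigma <= sigma_con), while scales at or above the control scale stay
isotropic (phi = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BankConfig",
    "Kernel",
    "KernelBank",
    "adaptive_anisotropy_factor",
    "anisotropic_gaussian_kernel",
    "normalized_fdag_kernel",
    "build_kernel_bank",
]

#: Default scale set: six scales from 1.0 to 1.5 in steps of 0.1.
DEFAULT_SCALES = tuple(round(1.0 + 0.1 * i, 1) for i in range(6))
#: Default number of filter directions spanning [0, pi).
DEFAULT_N_DIRECTIONS = 8
#: Default robustness control scale.
DEFAULT_CONTROL_SCALE = 1.2


def directions_from_count(n: int) -> tuple[float, ...]:
    """Return ``n`` equally spaced orientations in ``[0, pi)``."""
    if n < 1:
        raise ValueError("need at least one direction")
    return tuple(math.pi * j / n for j in range(n))


@dataclass(frozen=True)
class BankConfig:
    """Configuration of a multiscale, multidirection FDAG kernel bank.

    Parameters
    ----------
    scales
        Strictly increasing kernel scales (pixels).
    directions
        Strictly increasing orientations in ``[0, pi)`` (radians,
        measured from the +x axis toward +y).
    control_scale
        Robustness control scale ``sigma_con``; scales below it get an
        elongated (anisotropic) support.  Must lie within
        ``[min(scales), max(scales)]``.
    """

    scales: tuple[float, ...] = DEFAULT_SCALES
    directions: tuple[float, ...] = field(
        default_factory=lambda: directions_from_count(DEFAULT_N_DIRECTIONS)
    )
    control_scale: float = DEFAULT_CONTROL_SCALE

    def __post_init__(self) -> None:
        scales = tuple(float(s) for s in self.scales)
        directions = tuple(float(d) for d in self.directions)
        object.__setattr__(self, "scales", scales)
        object.__setattr__(self, "directions", directions)
        if not scales:
            raise ValueError("scale set must be non-empty")
        if not directions:
            raise ValueError("direction set must be non-empty")
        if any(s <= 0 for s in scales):
            raise ValueError("scales must be positive")
        if any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValueError("scales must be strictly increasing")
        if any(not (0.0 <= d < math.pi) for d in directions):
            raise ValueError("directions must lie in [0, pi)")
        if any(b <= a for a, b in zip(directions, directions[1:])):
            raise ValueError("directions must be strictly increasing")
        if not (scales[0] <= self.control_scale <= scales[-1]):
            raise ValueError(
                "control scale must lie within [min(scales), max(scales)]"
            )


@dataclass(frozen=True)
class Kernel:
    """A discrete kernel sampled on the integer grid.

    ``coefficients[iy, ix]`` holds the value at integer offset
    ``m = (mx, my) = (ix - half_width, iy - half_width)``; x is the
    column axis and y the row axis, so the array is directly usable in
    image convolution.
    """

    coefficients: np.ndarray
    sigma: float
    anisotropy: float
    direction: float
    half_width: int

    @property
    def side(self) -> int:
        return 2 * self.half_width + 1


@dataclass(frozen=True)
class KernelBank:
    """All FDAG kernels of a configuration, indexed by (scale, direction)."""

    config: BankConfig
    kernels: dict[tuple[int, int], Kernel]
    anisotropies: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.kernels)

    def __getitem__(self, key: tuple[int, int]) -> Kernel:
        return self.kernels[key]


def adaptive_anisotropy_factor(sigma: float, control_scale: float) -> float:
    """Anisotropy factor of a bank member at scale ``sigma``.

    Returns ``(control_scale / sigma)**2`` for ``sigma <= control_scale``
    and 1 otherwise, so small (noise-prone) scales are elongated and
    large scales stay isotropic.  The result is always >= 1.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if control_scale <= 0:
        raise ValueError("control_scale must be positive")
    return max((control_scale / sigma) ** 2, 1.0)


def _grid(half_width: int) -> tuple[np.ndarray, np.ndarray]:
    # mx along columns, my along rows; origin at the central sample
    r = np.arange(-half_width, half_width + 1, dtype=float)
    my, mx = np.meshgrid(r, r, indexing="ij")
    return mx, my


def _required_half_width(sigma: float, anisotropy: float) -> int:
    return math.ceil(3.0 * anisotropy * sigma)


def _gaussian_values(
    mx: np.ndarray, my: np.ndarray, sigma: float, anisotropy: float, direction: float
) -> np.ndarray:
    # Rotate into the kernel frame: u along the derivative axis (std sigma),
    # v along the elongated axis (std anisotropy*sigma).
    c, s = math.cos(direction), math.sin(direction)
    u = c * mx + s * my
    v = -s * mx + c * my
    norm = 1.0 / (2.0 * math.pi * anisotropy * sigma**2)
    return norm * np.exp(
        -0.5 / sigma**2 * (u**2 + v**2 / anisotropy**2)
    )


def anisotropic_gaussian_kernel(
    sigma: float, anisotropy: float, direction: float, half_width: int
) -> Kernel:
    """Sample the directional anisotropic Gaussian on the integer grid.

    ``half_width`` must cover at least three standard deviations of the
    elongated axis (``ceil(3 * anisotropy * sigma)``) so that the
    discrete coefficients sum to 1 within 1e-3.
    """
    if sigma <= 0 or anisotropy < 1:
        raise ValueError("require sigma > 0 and anisotropy >= 1")
    if half_width < _required_half_width(sigma, anisotropy):
        raise ValueError(
            f"half_width {half_width} too small; need >= "
            f"{_required_half_width(sigma, anisotropy)} for sigma={sigma}, "
            f"anisotropy={anisotropy}"
        )
    mx, my = _grid(half_width)
    coeff = _gaussian_values(mx, my, sigma, anisotropy, direction)
    return Kernel(coeff, float(sigma), float(anisotropy), float(direction), half_width)


def normalized_fdag_kernel(
    sigma: float, anisotropy: float, direction: float, half_width: int
) -> Kernel:
    """Sample the scale-normalized FDAG kernel on the integer grid.

    Coefficients are ``-2 sqrt(pi) * sigma^(1/2) * (u / sigma^2) * g(m)``
    with ``u`` the coordinate along the derivative axis; they sum to zero
    by odd symmetry.  The continuous normalization constant is used
    verbatim; the discrete sample is not renormalized.
    """
    if sigma <= 0 or anisotropy < 1:
        raise ValueError("require sigma > 0 and anisotropy >= 1")
    if half_width < _required_half_width(sigma, anisotropy):
        raise ValueError(
            f"half_width {half_width} too small; need >= "
            f"{_required_half_width(sigma, anisotropy)}"
        )
    mx, my = _grid(half_width)
    g = _gaussian_values(mx, my, sigma, anisotropy, direction)
    c, s = math.cos(direction), math.sin(direction)
    u = c * mx + s * my
    coeff = -2.0 * math.sqrt(math.pi) * math.sqrt(sigma) * (u / sigma**2) * g
    return Kernel(coeff, float(sigma), float(anisotropy), float(direction), half_width)


def build_kernel_bank(config: BankConfig) -> KernelBank:
    """Build one normalized FDAG kernel per (scale, direction) pair.

    The anisotropy of scale ``sigma_i`` is
    ``max((sigma_con / sigma_i)**2, 1)`` and the square support half-width
    is ``ceil(3 * phi_i * sigma_i)``, which covers the elongated axis at
    any rotation (>99.7% of the Gaussian mass).
    """
    anisotropies = tuple(
        adaptive_anisotropy_factor(s, config.control_scale) for s in config.scales
    )
    kernels: dict[tuple[int, int], Kernel] = {}
    for i, (sigma, phi) in enumerate(zip(config.scales, anisotropies)):
        hw = _required_half_width(sigma, phi)
        for j, theta in enumerate(config.directions):
            kernels[(i, j)] = normalized_fdag_kernel(sigma, phi, theta, hw)
    return KernelBank(config=config, kernels=kernels, anisotropies=anisotropies)
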