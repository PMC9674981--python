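"""Rayleigh-Gans scattering of a single rod-like filament at 90 degrees.

Static light scattering from a thin rigid rod of length ``l`` and radius
``r`` deviates from the point-scatterer (Rayleigh) prediction by a shape
factor ``P(90°) = F(r)² E(l)²``.  For intermediate filaments the radius is
well below λ/10, where ``F(r) → 1``, so only the length-dependent part

    E²(z) = Si(2z)/z − (sin z / z)²,       z = (2πl/λ)·sin(π/4),

matters.  Because ``E²`` falls off faster at shorter wavelengths, the ratio
of intensities recorded at 594 and 405 nm is a monotonic reporter of
filament length up to ~7 unit-length filaments (ULFs), which is the basis
of the dual-wavelength elongation assay implemented by this package.

Lengths are in nanometres throughout; ULF counts convert to length via
``l = ulf_length + ulf_increment·(n − 1)`` (60 nm for the first ULF, 43 nm
per additional ULF because annealing partners overlap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import sici

__all__ = [
    "LAMBDA_SHORT_NM",
    "LAMBDA_LONG_NM",
    "SCATTERING_ANGLE_DEG",
    "UlfGeometry",
    "RodGeometry",
    "size_parameter",
    "length_form_factor",
    "shape_factor",
    "single_length_ratio",
    "ulf_to_length",
    "length_to_ulf",
    "ratio_peak",
]

#: Wavelengths of the two lasers (vacuum values, nm).
LAMBDA_SHORT_NM = 405.0
LAMBDA_LONG_NM = 594.0

#: The detector sits perpendicular to the incident beam; the angle is a
#: property of the optical layout, not a free parameter.
SCATTERING_ANGLE_DEG = 90.0

_SIN_HALF_ANGLE = np.sin(np.pi / 4)

# Below this z the closed form 1/z·Si(2z) − (sin z/z)² is evaluated by its
# series 1 − z²/9 + O(z⁴) to avoid 0/0.
_SMALL_Z = 1e-3


@dataclass(frozen=True)
class UlfGeometry:
    """Length bookkeeping for unit-length filaments (ULFs).

    Parameters
    ----------
    ulf_length : float
        Physical length of a single ULF in nm (a ULF is as long as the
        tetramer it is built from, ~60 nm).
    ulf_increment : float
        Net length added per annealed ULF in nm.  Smaller than
        ``ulf_length`` because joining filaments partially overlap.
    """

    ulf_length: float = 60.0
    ulf_increment: float = 43.0

    def __post_init__(self) -> None:
        if self.ulf_length <= 0 or self.ulf_increment <= 0:
            raise ValueError("ULF length and increment must be positive")
        if self.ulf_increment > self.ulf_length:
            raise ValueError("ULF increment cannot exceed the ULF length")


@dataclass(frozen=True)
class RodGeometry:
    """A cylindrical scatterer of length ``l`` and radius ``r`` (nm)."""

    length: float
    radius: float = 5.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"rod length must be positive, got {self.length}")
        if self.radius < 0:
            raise ValueError(f"rod radius must be non-negative, got {self.radius}")

    def is_thin(self, wavelength_nm: float) -> bool:
        """True when the thin-rod (Rayleigh-Gans) condition r < λ/10 holds."""
        return self.radius < wavelength_nm / 10.0


def size_parameter(length_nm, wavelength_nm):
    """Dimensionless rod size parameter z = (2πl/λ)·sin(π/4) at 90°."""
    length_nm = np.asarray(length_nm, dtype=float)
    wavelength_nm = np.asarray(wavelength_nm, dtype=float)
    if np.any(length_nm <= 0):
        raise ValueError("length must be positive")
    if np.any(wavelength_nm <= 0):
        raise ValueError("wavelength must be positive")
    return 2.0 * np.pi * length_nm / wavelength_nm * _SIN_HALF_ANGLE


def length_form_factor(z):
    """Length part E²(z) of the rod shape factor.

    ``E²(z) = Si(2z)/z − (sin z/z)²`` with the analytic limit E²(0) = 1.
    Continuous and bounded in (0, 1] on z ≥ 0; for large z it decays like
    π/(2z).
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("z must be non-negative")
    scalar = z.ndim == 0
    z = np.atleast_1d(z)
    out = np.empty_like(z)
    small = z < _SMALL_Z
    out[small] = 1.0 - z[small] ** 2 / 9.0
    zb = z[~small]
    si = sici(2.0 * zb)[0]
    out[~small] = si / zb - (np.sin(zb) / zb) ** 2
    return out[0] if scalar else out


def shape_factor(geometry: RodGeometry, wavelength_nm: float) -> float:
    """Shape factor P(90°) = F(r)²·E(l)² for a rod, with F(r) taken as 1.

    For the radii handled here (< λ/10) the radius factor is
    indistinguishable from unity; a warning is issued when the thin-rod
    precondition is violated, but no correction is attempted.
    """
    if not geometry.is_thin(wavelength_nm):
        warnings.warn(
            f"rod radius {geometry.radius} nm >= lambda/10 "
            f"({wavelength_nm / 10:.1f} nm); Rayleigh-Gans thin-rod "
            "assumption violated, F(r)=1 may be inaccurate",
            stacklevel=2,
        )
    z = size_parameter(geometry.length, wavelength_nm)
    return float(length_form_factor(z))


def single_length_ratio(length_nm, lambda_long=LAMBDA_LONG_NM, lambda_short=LAMBDA_SHORT_NM):
    """594/405 nm intensity ratio of a single rod of the given length.

    Equals E²(z(l, λ_long)) / E²(z(l, λ_short)).  Tends to 1 for point-like
    scatterers and to λ_long/λ_short (≈1.467 for 594/405) for very long
    rods; in between it rises monotonically up to its first local maximum
    just short of the 8-ULF length.
    """
    num = length_form_factor(size_parameter(length_nm, lambda_long))
    den = length_form_factor(size_parameter(length_nm, lambda_short))
    return num / den


def ulf_to_length(n_ulf, geometry: UlfGeometry | None = None):
    """Contour length (nm) of a filament of ``n_ulf`` ULFs.

    ``n_ulf`` may be fractional (population means); it must be >= 1.
    """
    geometry = geometry or UlfGeometry()
    n_ulf = np.asarray(n_ulf, dtype=float)
    if np.any(n_ulf < 1):
        raise ValueError("ULF count must be >= 1")
    out = geometry.ulf_length + geometry.ulf_increment * (n_ulf - 1.0)
    return float(out) if out.ndim == 0 else out


def length_to_ulf(length_nm, geometry: UlfGeometry | None = None):
    """Inverse of :func:`ulf_to_length` (real-valued ULF equivalents)."""
    geometry = geometry or UlfGeometry()
    length_nm = np.asarray(length_nm, dtype=float)
    if np.any(length_nm < geometry.ulf_length):
        raise ValueError("length below a single ULF")
    out = 1.0 + (length_nm - geometry.ulf_length) / geometry.ulf_increment
    return float(out) if out.ndim == 0 else out


def ratio_peak(
    geometry: UlfGeometry | None = None,
    lambda_long: float = LAMBDA_LONG_NM,
    lambda_short: float = LAMBDA_SHORT_NM,
    n_max: float = 15.0,
    grid_points: int = 4000,
):
    """Locate the first local maximum of the single-length intensity ratio.

    The ratio rises monotonically with length while filaments stay short
    and attains a first local maximum; beyond it the ratio carries little
    length information, which bounds the useful range of the assay.

    Returns
    -------
    dict with keys
        ``length_nm`` : continuous peak location,
        ``ulf_equivalent`` : real-valued ULF count at the peak,
        ``ulf_count`` : number of complete ULFs at the peak (the last
        whole-ULF length through which the ratio is still rising),
        ``ratio`` : ratio value at the peak.
    """
    geometry = geometry or UlfGeometry()
    n_grid = np.linspace(1.0, n_max, grid_points)
    lengths = ulf_to_length(n_grid, geometry)
    r = single_length_ratio(lengths, lambda_long, lambda_short)
    d = np.diff(r)
    turning = np.where((d[:-1] > 0) & (d[1:] <= 0))[0]
    if turning.size == 0:
        raise RuntimeError("no local maximum found on the grid")
    i = turning[0] + 1
    # polish the bracketed maximum
    lo, hi = lengths[max(i - 2, 0)], lengths[min(i + 2, lengths.size - 1)]
    res = minimize_scalar(
        lambda l: -float(single_length_ratio(l, lambda_long, lambda_short)),
        bounds=(lo, hi),
        method="bounded",
    )
    peak_l = float(res.x)
    ulf_eq = length_to_ulf(peak_l, geometry)
    return {
        "length_nm": peak_l,
        "ulf_equivalent": float(ulf_eq),
        "ulf_count": int(np.floor(ulf_eq)),
        "ratio": float(-res.fun),
    }
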