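"""Laguerre-Gaussian (LG) vortex beam fields on sampled transverse grids.

Provides the paraxial LG mode :func:`lg_field`, its closed-form phase
:func:`lg_phase` (curvature + azimuthal + plane-wave + Gouy terms), and the
usual beam geometry helpers.  The phase convention is ``exp(-i*ell*phi)``
with ``phi`` measured counter-clockwise from +x; the sign of every measured
twist downstream is defined relative to this convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_genlaguerre, gammaln

__all__ = [
    "C_LIGHT",
    "BeamParameters",
    "GridSpec",
    "ComplexField",
    "UnderresolvedBeamError",
    "beam_waist",
    "doughnut_radius",
    "lg_field",
    "lg_phase",
    "lg_radial_amplitude",
    "fit_waist_from_intensity",
]

C_LIGHT = 299_792_458.0  # m/s


class UnderresolvedBeamError(ValueError):
    """Raised when a grid is too small/coarse to hold the requested beam."""


@dataclass(frozen=True)
class BeamParameters:
    """Physical parameters of an LG_p^ell beam.

    Parameters
    ----------
    wavelength : float
        Vacuum wavelength in metres.
    waist_w0 : float
        Zero-order Gaussian beam waist w(0) in metres.
    ell : int
        Topological charge (signed winding number of the helical phase).
    p : int
        Radial index (non-negative).
    """

    wavelength: float
    waist_w0: float
    ell: int
    p: int = 0

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.waist_w0 <= 0:
            raise ValueError("waist_w0 must be positive")
        if self.p < 0:
            raise ValueError("radial index p must be non-negative")
        if int(self.ell) != self.ell or int(self.p) != self.p:
            raise ValueError("ell and p must be integers")

    @property
    def k(self) -> float:
        """Wavenumber 2*pi/lambda in rad/m."""
        return 2.0 * math.pi / self.wavelength

    @property
    def rayleigh_range(self) -> float:
        """Rayleigh range z_R = pi*w0^2/lambda in metres."""
        return math.pi * self.waist_w0**2 / self.wavelength

    @property
    def omega(self) -> float:
        """Angular frequency 2*pi*c/lambda in rad/s."""
        return 2.0 * math.pi * C_LIGHT / self.wavelength


@dataclass(frozen=True)
class GridSpec:
    """Uniform transverse pixel grid with physical pitch.

    ``origin`` is the beam-axis position in (column, row) pixel coordinates;
    fractional values are allowed.  Defaults to the grid centre.
    """

    nx: int
    ny: int
    pitch: float
    origin: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.nx < 8 or self.ny < 8:
            raise ValueError("grid must be at least 8x8 pixels")
        if self.pitch <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def center(self) -> tuple[float, float]:
        if self.origin is not None:
            return self.origin
        return ((self.nx - 1) / 2.0, (self.ny - 1) / 2.0)

    def coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) meshes in metres, beam axis at (0, 0)."""
        cx, cy = self.center
        x = (np.arange(self.nx) - cx) * self.pitch
        y = (np.arange(self.ny) - cy) * self.pitch
        return np.meshgrid(x, y)

    def polar(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (rho, phi) meshes; phi counter-clockwise from +x."""
        xx, yy = self.coordinates()
        return np.hypot(xx, yy), np.arctan2(yy, xx)

    @property
    def extent(self) -> tuple[float, float]:
        """Full physical spans (x_span, y_span) in metres."""
        return (self.nx * self.pitch, self.ny * self.pitch)


@dataclass
class ComplexField:
    """Complex scalar field sampled on a transverse grid at distance z."""

    grid: GridSpec
    z: float
    amplitude: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.amplitude.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("amplitude shape does not match grid")

    def energy(self) -> float:
        """Discrete energy sum(|E|^2) * pitch^2."""
        return float(np.sum(np.abs(self.amplitude) ** 2) * self.grid.pitch**2)

    def intensity(self) -> np.ndarray:
        return np.abs(self.amplitude) ** 2

    def phase(self) -> np.ndarray:
        return np.angle(self.amplitude)


def beam_waist(params: BeamParameters, z: float) -> float:
    """Beam radius w(z) = w0*sqrt(1 + (z/zR)^2)."""
    return params.waist_w0 * math.sqrt(1.0 + (z / params.rayleigh_range) ** 2)


def doughnut_radius(params: BeamParameters, z: float = 0.0) -> float:
    """Radius of peak intensity w(z)*sqrt(|ell|/2) (w(z) itself for ell=0)."""
    w = beam_waist(params, z)
    if params.ell == 0:
        return w
    return w * math.sqrt(abs(params.ell) / 2.0)


def _norm_prefactor(params: BeamParameters, w: float) -> float:
    # sqrt(2 p! / (pi (|l|+p)! w^2)) via log-gamma; stable for large p, |l|
    p, la = params.p, abs(params.ell)
    log_ratio = gammaln(p + 1) - gammaln(la + p + 1)
    return math.sqrt(2.0 / (math.pi * w * w)) * math.exp(0.5 * log_ratio)


def lg_radial_amplitude(
    params: BeamParameters, rho: np.ndarray | float, z: float = 0.0
) -> np.ndarray:
    """|LG| radial envelope (no phase factors) at radius rho, distance z.

    The associated Laguerre polynomial is evaluated with scipy's stable
    recurrence-based routine; the factorial prefactor uses log-gamma so that
    large p and |ell| do not overflow.
    """
    rho = np.asarray(rho, dtype=float)
    w = beam_waist(params, z)
    la = abs(params.ell)
    u = 2.0 * rho**2 / (w * w)
    amp = (
        _norm_prefactor(params, w)
        * (rho * math.sqrt(2.0) / w) ** la
        * eval_genlaguerre(params.p, la, u)
        * np.exp(-(rho**2) / (w * w))
    )
    return amp


def lg_phase(
    params: BeamParameters,
    rho: np.ndarray | float,
    phi: np.ndarray | float,
    z: float,
) -> np.ndarray | float:
    """Closed-form LG phase: curvature, -ell*phi, -k*z and Gouy terms.

    Psi = -k rho^2 z / (2 (z^2 + zR^2)) - ell*phi - k z + G(z),
    G(z) = (2p + |ell| + 1) * arctan(z / zR).
    Agrees with arg(lg_field) modulo 2*pi wherever the envelope is positive.
    """
    rho = np.asarray(rho, dtype=float)
    k, zr = params.k, params.rayleigh_range
    gouy = (2 * params.p + abs(params.ell) + 1) * math.atan2(z, zr)
    psi = -k * rho**2 * z / (2.0 * (z * z + zr * zr)) - params.ell * np.asarray(phi) - k * z + gouy
    return psi if psi.shape else float(psi)


def lg_field(params: BeamParameters, grid: GridSpec, z: float = 0.0) -> ComplexField:
    """Evaluate the normalized LG_p^ell mode on ``grid`` at distance ``z``.

    Raises
    ------
    UnderresolvedBeamError
        If the grid does not span at least 3x the doughnut radius at z.
    """
    span = min(grid.extent)
    ring = doughnut_radius(params, z)
    if span < 3.0 * ring:
        raise UnderresolvedBeamError(
            f"grid span {span:.3e} m is below 3x the doughnut radius "
            f"{ring:.3e} m; enlarge the grid or reduce the beam"
        )
    rho, phi = grid.polar()
    w = beam_waist(params, z)
    k, zr = params.k, params.rayleigh_range
    la = abs(params.ell)

    envelope = (
        _norm_prefactor(params, w)
        * (rho * math.sqrt(2.0) / w) ** la
        * eval_genlaguerre(params.p, la, 2.0 * rho**2 / (w * w))
        * np.exp(-(rho**2) / (w * w))
    )
    gouy = (2 * params.p + la + 1) * math.atan2(z, zr)
    phase = (
        gouy
        - k * rho**2 * z / (2.0 * (z * z + zr * zr))
        - params.ell * phi
        - k * z
    )
    amp = envelope * np.exp(1j * phase)
    if la > 0:
        amp[rho == 0.0] = 0.0  # rho^|l| vanishes; make it exact
    return ComplexField(grid=grid, z=z, amplitude=amp)


def fit_waist_from_intensity(
    intensity: np.ndarray, grid: GridSpec, ell: int, nbins: int = 256
) -> float:
    """Least-squares doughnut-radius estimate of w(0) from an intensity image.

    Bins the image into a radial profile about the grid origin, locates the
    peak ring by a quadratic fit around the maximum bin, and converts the
    ring radius back to a waist through r_peak = w*sqrt(|ell|/2).
    """
    if ell == 0:
        raise ValueError("doughnut fit requires |ell| > 0")
    rho, _ = grid.polar()
    rmax = rho.max()
    edges = np.linspace(0.0, rmax, nbins + 1)
    idx = np.clip(np.digitize(rho.ravel(), edges) - 1, 0, nbins - 1)
    sums = np.bincount(idx, weights=intensity.ravel(), minlength=nbins)
    counts = np.maximum(np.bincount(idx, minlength=nbins), 1)
    prof = sums / counts
    centers = 0.5 * (edges[:-1] + edges[1:])
    i = int(np.argmax(prof))
    if 0 < i < nbins - 1:
        # quadratic interpolation of the peak position
        y0, y1, y2 = prof[i - 1], prof[i], prof[i + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        r_peak = centers[i] + shift * (centers[1] - centers[0])
    else:
        r_peak = centers[i]
    return float(r_peak / math.sqrt(abs(ell) / 2.0))
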