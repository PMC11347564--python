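"""Off-axis holographic phase retrieval and phase-memory mapping.

Retrieval is the classic single-shot scheme: 2-D FFT of the carrier-fringe
interferogram, crop of the +1-order sideband, recentre, inverse FFT; the
argument of the result is the sample phase (modulo 2*pi, up to piston).
The memory map regresses, per pixel, the retrieved phase change of a stack
of holograms against the phase offsets applied at the source, quantifying
how much of the injected phase survives scattering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .beam_optics import BeamParameters, GridSpec, lg_radial_amplitude

__all__ = [
    "PhaseMap",
    "AnnularMask",
    "MemoryMap",
    "retrieve_phase",
    "annular_mask",
    "annular_mask_from_intensity",
    "memory_map",
    "winding_number",
]


@dataclass
class PhaseMap:
    """Retrieved phase (principal interval) and amplitude per pixel."""

    phase: np.ndarray = field(repr=False)
    amplitude: np.ndarray = field(repr=False)
    grid: GridSpec | None = None
    sideband_center: tuple[int, int] | None = None
    crop_radius: int | None = None


@dataclass
class AnnularMask:
    """Boolean ring mask bounded by inner/outer pixel radii about a centre."""

    inner: float
    outer: float
    center: tuple[float, float]
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not (0 < self.inner < self.outer):
            raise ValueError("need 0 < inner < outer radius")
        if not self.mask.any():
            raise ValueError("annular mask is empty")


@dataclass
class MemoryMap:
    """Per-pixel linear response of retrieved phase to applied offset."""

    slope: np.ndarray = field(repr=False)
    intercept: np.ndarray = field(repr=False)
    r_squared: np.ndarray = field(repr=False)

    def summary(self, mask: np.ndarray, r2_floor: float = 0.0) -> dict:
        """Median slope and IQR inside vs outside ``mask``.

        Pixels with r^2 below ``r2_floor`` are excluded from the summary
        statistics but stay present in the map itself.
        """
        ok = self.r_squared >= r2_floor

        def stats(sel: np.ndarray) -> dict:
            vals = self.slope[sel & ok]
            if vals.size == 0:
                return {"median_slope": float("nan"), "iqr_slope": float("nan"), "n": 0}
            q1, q3 = np.percentile(vals, [25, 75])
            return {
                "median_slope": float(np.median(vals)),
                "iqr_slope": float(q3 - q1),
                "n": int(vals.size),
            }

        return {"inside": stats(mask), "outside": stats(~mask)}


class CarrierTooLowError(ValueError):
    """Sideband overlaps the DC term; the carrier frequency is too low."""


def _raised_cosine_window(n: int, edge_frac: float = 0.2) -> np.ndarray:
    """1-D flat-top window with raised-cosine edges (Tukey)."""
    w = np.ones(n)
    e = max(int(round(edge_frac * n)), 1)
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(e) / e))
    w[:e] = ramp
    w[-e:] = ramp[::-1]
    return w


def retrieve_phase(
    image: np.ndarray,
    sideband: tuple[int, int] | None = None,
    crop_radius: int | None = None,
    dc_exclude: int | None = None,
    apodize: bool = True,
    grid: GridSpec | None = None,
) -> PhaseMap:
    """Retrieve phase and amplitude from an off-axis interferogram.

    The +1-order sideband is auto-located as the strongest spectral peak
    outside a DC exclusion disk (unless ``sideband`` row/col offsets from
    centre are given), cropped with a square window of half-side equal to
    its distance from DC, recentred and inverse transformed.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    spec = np.fft.fftshift(np.fft.fft2(img - img.mean()))
    cy, cx = h // 2, w // 2
    if dc_exclude is None:
        dc_exclude = max(min(h, w) // 8, 4)

    if sideband is None:
        full_mag = np.abs(spec)
        mag = full_mag.copy()
        yy, xx = np.indices((h, w))
        rr = np.hypot(yy - cy, xx - cx)
        mag[rr <= dc_exclude] = 0.0
        mag[yy > cy] = 0.0  # keep the upper-half-plane order by convention
        iy, ix = np.unravel_index(np.argmax(mag), mag.shape)
        # a real carrier sideband is comparable to the DC halo; if the best
        # out-of-disk peak is tiny the actual sideband is buried under DC
        dc_peak = full_mag[rr <= dc_exclude].max()
        if mag[iy, ix] < 0.02 * dc_peak:
            raise CarrierTooLowError(
                "carrier too low: no sideband found outside the DC exclusion disk"
            )
        # a vortex-carrying sideband is a ring with a null at its centre, so
        # refine the peak to the local energy centroid before snapping to a bin
        half = max(int(math.hypot(iy - cy, ix - cx) / 4), 4)
        y0, y1 = max(iy - half, 0), min(iy + half + 1, h)
        x0, x1 = max(ix - half, 0), min(ix + half + 1, w)
        patch = mag[y0:y1, x0:x1] ** 2
        tot = patch.sum()
        if tot > 0:
            py, px = np.indices(patch.shape)
            iy = int(round(y0 + float((py * patch).sum() / tot)))
            ix = int(round(x0 + float((px * patch).sum() / tot)))
    else:
        iy, ix = cy + sideband[0], cx + sideband[1]

    dist = math.hypot(iy - cy, ix - cx)
    if dist <= dc_exclude:
        raise CarrierTooLowError("carrier too low: sideband overlaps the DC term")
    if crop_radius is None:
        # square side = distance to DC, i.e. half-side = dist/2, bounded by the edges
        crop_radius = int(min(dist / 2, iy, ix, h - 1 - iy, w - 1 - ix))
    r = crop_radius
    if r < 2:
        raise CarrierTooLowError("carrier too low: sideband too close to the spectrum edge")

    crop = spec[iy - r : iy + r, ix - r : ix + r].copy()
    if apodize:
        win = _raised_cosine_window(2 * r)
        crop *= win[:, None] * win[None, :]
    recentred = np.zeros_like(spec)
    recentred[cy - r : cy + r, cx - r : cx + r] = crop
    field_c = np.fft.ifft2(np.fft.ifftshift(recentred))
    return PhaseMap(
        phase=np.angle(field_c),
        amplitude=np.abs(field_c),
        grid=grid,
        sideband_center=(int(iy - cy), int(ix - cx)),
        crop_radius=r,
    )


def annular_mask(
    params: BeamParameters,
    grid: GridSpec,
    z: float = 0.0,
    fraction: float = math.exp(-2),
) -> AnnularMask:
    """Ring where the unscattered |LG|^2 exceeds ``fraction`` of its peak.

    Radii are found on a dense radial scan of the analytic profile, so the
    ring always contains the doughnut radius w(z)*sqrt(|ell|/2).
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    rho_max = max(grid.extent) * 0.75
    r = np.linspace(1e-9, rho_max, 8192)
    inten = np.abs(lg_radial_amplitude(params, r, z)) ** 2
    peak = inten.max()
    i_pk = int(np.argmax(inten))
    above = inten >= fraction * peak
    inner_i = np.nonzero(above[: i_pk + 1])[0][0]
    outer_i = i_pk + np.nonzero(above[i_pk:])[0][-1]
    inner_r, outer_r = r[inner_i], r[outer_i]
    rho, _ = grid.polar()
    mask = (rho >= inner_r) & (rho <= outer_r)
    return AnnularMask(
        inner=inner_r / grid.pitch,
        outer=outer_r / grid.pitch,
        center=grid.center,
        mask=mask,
    )


def annular_mask_from_intensity(
    intensity: np.ndarray,
    center: tuple[float, float],
    fraction: float = math.exp(-2),
    nbins: int = 256,
) -> AnnularMask:
    """Annular mask estimated from a measured (phase-free) intensity image."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    h, w = intensity.shape
    cy, cx = center[1], center[0]
    yy, xx = np.indices((h, w))
    rr = np.hypot(yy - cy, xx - cx)
    edges = np.linspace(0, rr.max(), nbins + 1)
    idx = np.clip(np.digitize(rr.ravel(), edges) - 1, 0, nbins - 1)
    sums = np.bincount(idx, weights=np.asarray(intensity, float).ravel(), minlength=nbins)
    counts = np.maximum(np.bincount(idx, minlength=nbins), 1)
    prof = sums / counts
    centers = 0.5 * (edges[:-1] + edges[1:])
    i_pk = int(np.argmax(prof))
    above = prof >= fraction * prof[i_pk]
    inner = centers[np.nonzero(above[: i_pk + 1])[0][0]]
    outer = centers[i_pk + np.nonzero(above[i_pk:])[0][-1]]
    mask = (rr >= inner) & (rr <= outer)
    return AnnularMask(inner=float(inner), outer=float(outer), center=center, mask=mask)


def memory_map(
    phases: np.ndarray | list,
    offsets: np.ndarray,
    amplitudes: np.ndarray | None = None,
) -> MemoryMap:
    """Regress retrieved phase change against applied offsets, per pixel.

    ``phases``: stack (K, H, W) of retrieved phase maps, one per offset;
    the frame whose offset is closest to 0 serves as reference.  Phase
    differences are taken on the unit circle (complex ratio) so no
    unwrapping is needed while |slope*offset| < pi.
    """
    if isinstance(phases, list):
        phases = np.stack([p.phase if isinstance(p, PhaseMap) else p for p in phases])
    offsets = np.asarray(offsets, dtype=float)
    if phases.shape[0] != offsets.size:
        raise ValueError("one phase map per offset required")
    if offsets.size < 3:
        raise ValueError("need at least 3 offsets")
    ref = int(np.argmin(np.abs(offsets)))
    diffs = np.angle(np.exp(1j * (phases - phases[ref][None])))
    x = offsets - offsets[ref]
    xm = x.mean()
    ym = diffs.mean(axis=0)
    sxx = float(np.sum((x - xm) ** 2))
    sxy = np.tensordot(x - xm, diffs - ym[None], axes=(0, 0))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = diffs - (slope[None] * x[:, None, None] + intercept[None])
    ss_res = np.sum(resid**2, axis=0)
    ss_tot = np.sum((diffs - ym[None]) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    r2 = np.clip(np.nan_to_num(r2, nan=0.0), 0.0, 1.0)
    return MemoryMap(slope=slope, intercept=intercept, r_squared=r2)


def winding_number(
    phase_or_field: np.ndarray,
    center: tuple[float, float],
    radius: float,
    n_samples: int = 2048,
) -> float:
    """Line integral of the phase gradient around a circle, in turns*2*pi.

    Accepts either a complex field or a phase map; samples the phase at
    ``n_samples`` points on the circle (bilinear interpolation for complex
    input, nearest pixel for a raw phase array) and sums wrapped
    differences.  For a clean vortex of charge ell (convention
    exp(-i*ell*phi)) the result is -2*pi*ell.
    """
    from scipy.ndimage import map_coordinates

    t = np.linspace(0.0, 2.0 * math.pi, n_samples, endpoint=False)
    cx, cy = center
    xs = cx + radius * np.cos(t)
    ys = cy + radius * np.sin(t)
    arr = np.asarray(phase_or_field)
    if np.iscomplexobj(arr):
        re = map_coordinates(arr.real, [ys, xs], order=1)
        im = map_coordinates(arr.imag, [ys, xs], order=1)
        ph = np.arctan2(im, re)
    else:
        ph = arr[np.round(ys).astype(int) % arr.shape[0], np.round(xs).astype(int) % arr.shape[1]]
    d = np.diff(np.concatenate([ph, ph[:1]]))
    d = np.angle(np.exp(1j * d))
    return float(np.sum(d))
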