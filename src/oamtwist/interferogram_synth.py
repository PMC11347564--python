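"""Synthesize on-axis (petal) and off-axis (carrier-fringe) interferograms.

A sample :class:`~oamtwist.beam_optics.ComplexField` is interfered with a
plane or expanded-Gaussian reference, run through a simple camera model
(exposure scaling, optional signal-proportional shot noise, quantization)
and returned as an unsigned-integer image, the common input format of the
two analysis modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .beam_optics import ComplexField, GridSpec

__all__ = ["ReferenceWave", "CameraModel", "reference_field", "interfere", "frame_stack"]


@dataclass(frozen=True)
class ReferenceWave:
    """Reference arm description.

    ``tilt`` is the transverse carrier (kx, ky) in rad/m; (0, 0) means the
    on-axis (petal) regime.  ``amplitude_ratio`` scales the reference peak
    amplitude relative to the sample field's peak amplitude.  An
    expanded-Gaussian kind approximates the plane wave it stands in for;
    ``waist`` defaults to 5x the grid span when unset.
    """

    kind: str = "plane"
    tilt: tuple[float, float] = (0.0, 0.0)
    amplitude_ratio: float = 1.0
    phase_offset: float = 0.0
    waist: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("plane", "expanded-gaussian"):
            raise ValueError("kind must be 'plane' or 'expanded-gaussian'")
        if self.amplitude_ratio <= 0:
            raise ValueError("amplitude_ratio must be positive")

    @property
    def on_axis(self) -> bool:
        return self.tilt == (0.0, 0.0)


@dataclass(frozen=True)
class CameraModel:
    """Quantizing camera: 16-bit by default, exposure to ~80% full scale."""

    bit_depth: int = 16
    exposure: float | None = None  # counts per unit intensity; None = auto
    shot_noise: bool = False
    dark_offset: float = 0.0
    seed: int | None = 0
    target_fill: float = 0.8

    @property
    def full_scale(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def dtype(self):
        return np.uint16 if self.bit_depth > 8 else np.uint8


def reference_field(ref: ReferenceWave, grid: GridSpec, peak_amplitude: float) -> np.ndarray:
    """Evaluate the reference wave on ``grid`` with given peak amplitude."""
    xx, yy = grid.coordinates()
    phase = ref.tilt[0] * xx + ref.tilt[1] * yy + ref.phase_offset
    amp = ref.amplitude_ratio * peak_amplitude * np.exp(1j * phase)
    if ref.kind == "expanded-gaussian":
        waist = ref.waist if ref.waist is not None else 5.0 * max(grid.extent)
        amp = amp * np.exp(-(xx**2 + yy**2) / waist**2)
    return amp


def interfere(
    sample: ComplexField,
    ref: ReferenceWave,
    cam: CameraModel,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Two-beam interference image |E_s + E_r|^2 through the camera model.

    Returns the quantized image and a metadata dict (exposure used,
    saturation fraction with a warning flag above 1%, seed).  Deterministic
    for a given camera seed.
    """
    peak = float(np.max(np.abs(sample.amplitude)))
    if peak == 0.0:
        peak = 1.0
    e_ref = reference_field(ref, sample.grid, peak)
    inten = np.abs(sample.amplitude + e_ref) ** 2

    if cam.exposure is None:
        top = float(inten.max())
        exposure = cam.target_fill * cam.full_scale / top if top > 0 else 1.0
    else:
        exposure = cam.exposure
    counts = cam.dark_offset + exposure * inten

    if cam.shot_noise:
        if rng is None:
            rng = np.random.default_rng(cam.seed)
        counts = rng.poisson(np.maximum(counts, 0.0)).astype(float)

    saturated = float(np.mean(counts > cam.full_scale))
    img = np.clip(np.round(counts), 0, cam.full_scale).astype(cam.dtype)
    meta = {
        "exposure": exposure,
        "saturation_fraction": saturated,
        "saturation_warning": saturated > 0.01,
        "bit_depth": cam.bit_depth,
        "shot_noise": cam.shot_noise,
        "seed": cam.seed,
        "on_axis": ref.on_axis,
    }
    return img, meta


def frame_stack(
    sample_series,
    ref: ReferenceWave,
    cam: CameraModel,
    fps: float = 10.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Interfere a sequence of sample fields into an image stack.

    ``sample_series`` is an iterable of ComplexField (or a callable taking
    the frame index).  Frames carry timestamps spaced 1/fps apart.
    """
    if rng is None:
        rng = np.random.default_rng(cam.seed)
    frames = []
    metas = []
    for f in sample_series:
        img, meta = interfere(f, ref, cam, rng=rng)
        frames.append(img)
        metas.append(meta)
    if not frames:
        raise ValueError("sample_series is empty")
    stack = np.stack(frames)
    times = np.arange(stack.shape[0]) / fps
    return stack, times, metas


def carrier_default(grid: GridSpec) -> tuple[float, float]:
    """Diagonal carrier at 1/4 of Nyquist, separable by the sideband crop."""
    f = 2.0 * math.pi / grid.pitch / 8.0  # Nyquist = pi/pitch; quarter of it, per axis
    return (f, f)
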