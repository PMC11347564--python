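"""Deterministic generators for every input the analysis pipeline consumes.

Thermal runs with a drifting refractive index, on-axis petal interferogram
stacks with stored ground-truth twist, and off-axis speckle stacks with a
controllable phase-memory fraction inside/outside the beam annulus.  All
outputs are bit-reproducible given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beam_optics import BeamParameters, ComplexField, GridSpec, lg_field
from .interferogram_synth import CameraModel, ReferenceWave, carrier_default, interfere
from .phase_retrieval import annular_mask
from .trajectory_model import MediumStack, mean_retardation_curve

__all__ = [
    "ThermalRun",
    "SpeckleSpec",
    "make_thermal_run",
    "make_twist_stack",
    "make_speckle_field",
    "make_speckle_stack",
    "default_offsets",
]

DEFAULT_DELTA_N = 3.69e-4


@dataclass
class ThermalRun:
    """Frame-gridded temperature and refractive-index trajectory."""

    t: np.ndarray = field(repr=False)
    temperature: np.ndarray = field(repr=False)
    n: np.ndarray = field(repr=False)
    n_ref: float = 1.3330
    c_nT: float = 0.0

    @property
    def delta_n(self) -> np.ndarray:
        return self.n - self.n[0]

    @property
    def total_delta_n(self) -> float:
        return float(self.n[-1] - self.n[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.t.size),
                "t_s": self.t,
                "T_C": self.temperature,
                "n": self.n,
            }
        )


def make_thermal_run(
    duration_s: float = 1500.0,
    fps: float = 10.0,
    t_start_c: float = 7.8,
    t_room_c: float = 21.0,
    tau_s: float = 420.0,
    n_ref: float = 1.3330,
    delta_n_total: float | None = DEFAULT_DELTA_N,
    c_nT: float | None = None,
) -> ThermalRun:
    """Exponential thermal relaxation with a linear n(T) response.

    Temperature relaxes from ``t_start_c`` toward ``t_room_c`` with time
    constant ``tau_s``; n(t) = n_ref + c_nT * (T(t) - T(0)).  When ``c_nT``
    is not given it is chosen so the run's total refractive-index change
    equals ``delta_n_total`` exactly.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n_frames = int(round(duration_s * fps))
    t = np.arange(n_frames) / fps
    temp = t_room_c + (t_start_c - t_room_c) * np.exp(-t / tau_s)
    if c_nT is None:
        if delta_n_total is None:
            raise ValueError("give either c_nT or delta_n_total")
        span = temp[-1] - temp[0]
        c_nT = delta_n_total / span if span != 0 else 0.0
    n = n_ref + c_nT * (temp - temp[0])
    return ThermalRun(t=t, temperature=temp, n=n, n_ref=n_ref, c_nT=float(c_nT))


def make_twist_stack(
    run: ThermalRun,
    params: BeamParameters,
    stack: MediumStack,
    grid: GridSpec | None = None,
    cam: CameraModel | None = None,
    varying_layer: int | None = None,
    n_traj: int = 50_000,
    seed: int = 0,
    n_frames: int | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render an on-axis petal stack for a thermal run, with ground truth.

    The ground-truth twist Theta*(t) comes from the trajectory-ensemble
    forward map (ensemble-mean retardation through the Snell-bent stack,
    interpolated smoothly over the run's delta-n range).  Each frame is the
    LG field advanced by the corresponding pattern rotation, interfered
    with a plane reference.  ``n_frames`` subsamples the run uniformly to
    keep desk-scale stacks small.

    Returns (stack_uint, times, truth) where truth holds ``theta_star``
    (radians), the per-frame delta_n, and the generator config.
    """
    if cam is None:
        cam = CameraModel(shot_noise=False)
    if grid is None:
        ring = params.waist_w0 * math.sqrt(max(abs(params.ell), 1) / 2.0)
        grid = GridSpec(256, 256, pitch=ring * 7.0 / 256)
    if varying_layer is None:
        varying_layer = int(np.argmax([la.d for la in stack.layers]))
    if n_frames is not None and n_frames < run.t.size:
        sel = np.linspace(0, run.t.size - 1, n_frames).round().astype(int)
    else:
        sel = np.arange(run.t.size)
    t = run.t[sel]
    dn = run.delta_n[sel]

    rng = np.random.default_rng(seed)
    dn_knots = np.linspace(min(dn.min(), 0.0), max(dn.max(), 0.0) + 1e-12, 33)
    _, psi_knots, _ = mean_retardation_curve(
        params, stack, varying_layer, dn_knots, n_traj, rng
    )
    from scipy.interpolate import CubicSpline

    forward = CubicSpline(dn_knots, psi_knots / params.ell)
    theta_star = forward(dn)
    theta_star = theta_star - theta_star[0]

    # Fast petal renderer: a global phase advance ell*Theta against a plane
    # reference gives I = A^2 + R^2 + 2AR*cos(arg(LG) + ell*Theta), so each
    # frame is three axpy operations on precomputed grids.  A fixed exposure
    # (from the largest possible intensity) keeps frames mutually consistent.
    base = lg_field(params, grid, z=0.0)
    amp = np.abs(base.amplitude)
    peak = float(amp.max())
    r_amp = 1.0 * peak  # plane reference at amplitude_ratio = 1
    c0 = amp**2 + r_amp**2
    cross = 2.0 * amp * r_amp
    cos_b = cross * np.cos(np.angle(base.amplitude))
    sin_b = cross * np.sin(np.angle(base.amplitude))
    exposure = cam.target_fill * cam.full_scale / float((amp.max() + r_amp) ** 2)
    cam_rng = np.random.default_rng(cam.seed)
    frames = np.empty((t.size, grid.ny, grid.nx), dtype=cam.dtype)
    for i in range(t.size):
        cd, sd = math.cos(params.ell * theta_star[i]), math.sin(params.ell * theta_star[i])
        counts = exposure * (c0 + cos_b * cd - sin_b * sd) + cam.dark_offset
        if cam.shot_noise:
            counts = cam_rng.poisson(np.maximum(counts, 0.0)).astype(float)
        frames[i] = np.clip(np.round(counts), 0, cam.full_scale).astype(cam.dtype)
    truth = {
        "theta_star_rad": theta_star,
        "delta_n": dn,
        "frame_indices": sel,
        "sensitivity_rad_per_dn": float(forward.derivative()(0.0)),
        "ell": params.ell,
        "seed": seed,
        "n_traj": n_traj,
    }
    return frames, t, truth


@dataclass(frozen=True)
class SpeckleSpec:
    """Synthetic speckle with a prescribed phase-memory fraction.

    ``memory_inside``/``memory_outside`` set the amplitude fraction m of
    the delta-following LG component inside and outside the beam annulus;
    the complement sqrt(1 - m^2) is frozen random speckle independent of
    the applied offset.  ``grain_px`` is the speckle grain size set by the
    Fourier-domain low-pass cutoff.
    """

    grain_px: float = 8.0
    memory_inside: float = 1.0
    memory_outside: float = 0.0
    seed: int = 0
    regime_label: str = ""

    def __post_init__(self) -> None:
        for m in (self.memory_inside, self.memory_outside):
            if not (0.0 <= m <= 1.0):
                raise ValueError("memory fractions must lie in [0, 1]")
        if self.grain_px <= 0:
            raise ValueError("grain size must be positive")


def default_offsets(n: int = 7) -> np.ndarray:
    """SLM phase offsets spanning [-3*pi/10, 3*pi/10]."""
    return np.linspace(-0.3 * math.pi, 0.3 * math.pi, n)


def _gaussian_speckle(shape: tuple[int, int], grain_px: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS circular-Gaussian speckle via low-pass filtered white noise."""
    white = rng.normal(size=shape) + 1j * rng.normal(size=shape)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    cutoff = 1.0 / (2.0 * grain_px)
    filt = np.exp(-(fx**2 + fy**2) / (2.0 * cutoff**2))
    spk = np.fft.ifft2(np.fft.fft2(white) * filt)
    return spk / np.sqrt(np.mean(np.abs(spk) ** 2))


def make_speckle_field(
    spec: SpeckleSpec,
    params: BeamParameters,
    grid: GridSpec,
    slm_offset: float = 0.0,
) -> tuple[np.ndarray, dict]:
    """Complex field with partial phase memory at a given SLM offset.

    field = m * LG * exp(i*offset) + sqrt(1 - m^2) * a0 * S with the frozen
    speckle S independent of the offset and m varying inside/outside the
    beam annulus.  ``a0`` is half the LG peak amplitude so the scrambled
    part stays comparable to the beam where both are present.
    """
    lg = lg_field(params, grid, z=0.0).amplitude
    mask = annular_mask(params, grid).mask
    m = np.where(mask, spec.memory_inside, spec.memory_outside)
    rng = np.random.default_rng(spec.seed)
    speckle = _gaussian_speckle((grid.ny, grid.nx), spec.grain_px, rng)
    a0 = 0.5 * float(np.max(np.abs(lg)))
    fieldv = m * lg * np.exp(1j * slm_offset) + np.sqrt(1.0 - m**2) * a0 * speckle
    truth = {"memory_map": m, "annulus": mask, "a0": a0, "slm_offset": slm_offset}
    return fieldv, truth


def make_speckle_stack(
    spec: SpeckleSpec,
    params: BeamParameters,
    grid: GridSpec,
    offsets: np.ndarray | None = None,
    cam: CameraModel | None = None,
    carrier: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Off-axis hologram stack over SLM offsets, plus generator ground truth."""
    if offsets is None:
        offsets = default_offsets()
    offsets = np.asarray(offsets, dtype=float)
    if cam is None:
        cam = CameraModel(shot_noise=False)
    if carrier is None:
        carrier = carrier_default(grid)
    ref = ReferenceWave(kind="plane", tilt=carrier, amplitude_ratio=1.0)
    frames = []
    truth: dict = {}
    cam_rng = np.random.default_rng(cam.seed)
    for d in offsets:
        fieldv, info = make_speckle_field(spec, params, grid, slm_offset=float(d))
        img, _ = interfere(ComplexField(grid=grid, z=0.0, amplitude=fieldv), ref, cam, rng=cam_rng)
        frames.append(img)
        truth = info
    truth["offsets"] = offsets
    truth["carrier"] = carrier
    truth["seed"] = spec.seed
    return np.stack(frames), offsets, truth
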