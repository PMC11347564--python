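"""End-to-end analyses: refractive-index sensing and phase-memory mapping.

``run_sensing`` chains synthetic (or ingested) petal stacks through the
twist measurement and inverts the monotone forward map Theta(delta_n) back
to a refractive-index trajectory.  ``run_memory`` chains a scattering run
(Monte Carlo or synthetic speckle) through off-axis holography and the
per-pixel memory regression, summarized inside/outside the beam annulus.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .beam_optics import BeamParameters, ComplexField, GridSpec
from .interferogram_synth import CameraModel, ReferenceWave, carrier_default, interfere
from .phase_retrieval import annular_mask, memory_map, retrieve_phase
from .scatter_transport import DetectorSpec, propagate
from .synthetic_data import (
    SpeckleSpec,
    default_offsets,
    make_speckle_stack,
    make_thermal_run,
    make_twist_stack,
)
from .trajectory_model import MediumStack, mean_retardation_curve
from .twist_analysis import analyze_stack

__all__ = [
    "RunManifest",
    "SensingReport",
    "MemoryReport",
    "regime_label",
    "forward_twist_map",
    "invert_twist",
    "run_sensing",
    "run_memory",
]


def regime_label(od: float, diffuse_threshold: float = 10.0, override: str | None = None) -> str:
    """Scattering-regime label from the optical depth d/l*.

    Follows the >= 10 guideline for "multiple/diffuse"; 6 <= d/l* < 10 is
    called "intermediate/near-diffuse" rather than overclaiming, and an
    explicit ``override`` wins (e.g. to keep an experiment's own naming).
    """
    if override:
        return override
    if od >= diffuse_threshold:
        return "multiple/diffuse"
    if od >= 6.0:
        return "intermediate/near-diffuse"
    return "low/intermediate"


@dataclass
class RunManifest:
    """Provenance record: config, seeds, versions, digests, timing."""

    config: dict
    seeds: dict
    version: str = __version__
    digests: dict = field(default_factory=dict)
    timing_s: float = 0.0

    def add_digest(self, name: str, arr: np.ndarray) -> None:
        self.digests[name] = hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config": self.config,
                    "seeds": self.seeds,
                    "version": self.version,
                    "digests": self.digests,
                    "timing_s": self.timing_s,
                },
                indent=2,
                default=str,
            )
        )


def forward_twist_map(
    params: BeamParameters,
    stack: MediumStack,
    dn_max: float,
    varying_layer: int | None = None,
    n_traj: int = 50_000,
    seed: int = 0,
    n_knots: int = 33,
):
    """Smooth monotone forward map delta_n -> Theta (rad) and its inverse grid."""
    from scipy.interpolate import CubicSpline

    if varying_layer is None:
        varying_layer = int(np.argmax([la.d for la in stack.layers]))
    rng = np.random.default_rng(seed)
    knots = np.linspace(0.0, dn_max, n_knots)
    _, psi, _ = mean_retardation_curve(params, stack, varying_layer, knots, n_traj, rng)
    theta = psi / params.ell
    if not (np.all(np.diff(theta) > 0) or np.all(np.diff(theta) < 0)):
        raise ValueError("forward map Theta(delta_n) is not monotone over the range")
    return CubicSpline(knots, theta), knots, theta


def invert_twist(theta_meas: np.ndarray, knots: np.ndarray, theta_knots: np.ndarray) -> np.ndarray:
    """Monotone 1-D inversion of the forward map by bracketing/interpolation."""
    sign = 1.0 if theta_knots[-1] > theta_knots[0] else -1.0
    return np.interp(sign * np.asarray(theta_meas), sign * theta_knots, knots)


@dataclass
class SensingReport:
    times: np.ndarray
    theta_rad: np.ndarray
    dn_hat: np.ndarray
    dn_true: np.ndarray | None
    sensitivity_dn_per_deg: float
    manifest: RunManifest

    @property
    def max_abs_error(self) -> float | None:
        if self.dn_true is None:
            return None
        return float(np.max(np.abs(self.dn_hat - self.dn_true)))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "t_s": self.times,
                "theta_rad": self.theta_rad,
                "theta_deg": np.degrees(self.theta_rad),
                "dn_hat": self.dn_hat,
            }
        )
        if self.dn_true is not None:
            df["dn_true"] = self.dn_true
        return df


def run_sensing(config: dict | None = None, seed: int = 0, outdir: str | Path | None = None) -> SensingReport:
    """Thermal run -> petal stack -> measured twist -> inverted delta-n.

    Config keys (all optional): beam {wavelength_nm, waist_mm, ell, p},
    cuvette {interior_n, interior_d_mm, wall_d_mm, wall_n}, run
    {duration_s, fps, delta_n_total, tau_s}, render {nx, pitch_um,
    n_frames, shot_noise}, n_traj.
    """
    t0 = time.time()
    cfg = config or {}
    beam_cfg = cfg.get("beam", {})
    params = BeamParameters(
        wavelength=float(beam_cfg.get("wavelength_nm", 640.0)) * 1e-9,
        waist_w0=float(beam_cfg.get("waist_mm", 1.5)) * 1e-3,
        ell=int(beam_cfg.get("ell", 5)),
        p=int(beam_cfg.get("p", 0)),
    )
    cuv = cfg.get("cuvette", {})
    stack = MediumStack.cuvette(
        interior_n=float(cuv.get("interior_n", 1.3330)),
        interior_d=float(cuv.get("interior_d_mm", 3.6)) * 1e-3,
        wall_d=float(cuv.get("wall_d_mm", 1.0)) * 1e-3,
        wall_n=float(cuv.get("wall_n", 1.52)),
    )
    run_cfg = cfg.get("run", {})
    run = make_thermal_run(
        duration_s=float(run_cfg.get("duration_s", 1500.0)),
        fps=float(run_cfg.get("fps", 10.0)),
        tau_s=float(run_cfg.get("tau_s", 420.0)),
        delta_n_total=float(run_cfg.get("delta_n_total", 3.69e-4)),
        n_ref=float(cuv.get("interior_n", 1.3330)),
    )
    render = cfg.get("render", {})
    n_traj = int(cfg.get("n_traj", 50_000))
    nx = int(render.get("nx", 256))
    ring = params.waist_w0 * math.sqrt(max(abs(params.ell), 1) / 2.0)
    grid = GridSpec(nx, nx, pitch=ring * 7.0 / nx)
    cam = CameraModel(shot_noise=bool(render.get("shot_noise", False)), seed=seed)
    frames, times, truth = make_twist_stack(
        run,
        params,
        stack,
        grid=grid,
        cam=cam,
        n_traj=n_traj,
        seed=seed,
        n_frames=render.get("n_frames"),
    )

    series = analyze_stack(frames, ell=params.ell, times=times)
    dn_range = abs(run.total_delta_n)
    spline, knots, theta_knots = forward_twist_map(
        params, stack, dn_range if dn_range > 0 else 1e-5, n_traj=n_traj, seed=seed
    )
    dn_hat = invert_twist(series.theta, knots, theta_knots)
    slope0 = float(spline.derivative()(0.0))  # rad per unit delta-n
    sensitivity = math.radians(1.0) / slope0  # delta-n per degree of twist

    manifest = RunManifest(config=cfg, seeds={"seed": seed})
    manifest.add_digest("frames", frames)
    manifest.timing_s = time.time() - t0
    report = SensingReport(
        times=times,
        theta_rad=series.theta,
        dn_hat=dn_hat,
        dn_true=run.delta_n[truth["frame_indices"]],
        sensitivity_dn_per_deg=sensitivity,
        manifest=manifest,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_frame().to_csv(outdir / "sensing.csv", index=False)
        manifest.write(outdir / "manifest.json")
    return report


@dataclass
class MemoryReport:
    summary: dict
    regime: str
    optical_depth: float
    slope_map: np.ndarray = field(repr=False)
    r2_map: np.ndarray = field(repr=False)
    manifest: RunManifest | None = None

    @property
    def inside_median(self) -> float:
        return self.summary["inside"]["median_slope"]

    @property
    def outside_median(self) -> float:
        return self.summary["outside"]["median_slope"]


def _sideband_bins(carrier: tuple[float, float], grid: GridSpec) -> tuple[int, int]:
    """Row/col sideband offsets (fftshifted bins) of the direct-order term.

    With reference phase +(kx*x + ky*y), the sample-times-conjugate-
    reference term sits at minus the carrier frequency.
    """
    kx, ky = carrier
    col = -round(kx * grid.pitch * grid.nx / (2.0 * math.pi))
    row = -round(ky * grid.pitch * grid.ny / (2.0 * math.pi))
    return (row, col)


def _retrieve_stack(holograms: np.ndarray, sideband: tuple[int, int] | None = None) -> np.ndarray:
    maps = [retrieve_phase(h, sideband=sideband) for h in holograms]
    return np.stack([m.phase for m in maps])


def run_memory(config: dict | None = None, seed: int = 0, outdir: str | Path | None = None) -> MemoryReport:
    """Scattering run -> off-axis holograms -> phase maps -> memory map.

    ``mode: synthetic`` uses the speckle generator (cheap, exact ground
    truth); ``mode: mc`` runs the Monte Carlo transport.  The annular mask
    comes from the unscattered beam profile in both cases.
    """
    t0 = time.time()
    cfg = config or {}
    mode = cfg.get("mode", "synthetic")
    beam_cfg = cfg.get("beam", {})
    params = BeamParameters(
        wavelength=float(beam_cfg.get("wavelength_nm", 640.0)) * 1e-9,
        waist_w0=float(beam_cfg.get("waist_mm", 1.0)) * 1e-3,
        ell=int(beam_cfg.get("ell", 3)),
        p=int(beam_cfg.get("p", 0)),
    )
    nx = int(cfg.get("nx", 192))
    ring = params.waist_w0 * math.sqrt(max(abs(params.ell), 1) / 2.0)
    grid = GridSpec(nx, nx, pitch=ring * 7.0 / nx)
    offsets = np.asarray(cfg.get("offsets", default_offsets()), dtype=float)
    cam = CameraModel(shot_noise=False)

    if mode == "synthetic":
        spec = SpeckleSpec(
            grain_px=float(cfg.get("grain_px", 8.0)),
            memory_inside=float(cfg.get("memory_inside", 0.8)),
            memory_outside=float(cfg.get("memory_outside", 0.0)),
            seed=seed,
        )
        holo, offsets, truth = make_speckle_stack(spec, params, grid, offsets=offsets, cam=cam)
        sideband = _sideband_bins(truth["carrier"], grid)
        od = float(cfg.get("optical_depth", 0.0))
    elif mode == "mc":
        layers_cfg = cfg.get(
            "layers", [{"d_mm": 8.0, "n": 1.4, "mus_per_mm": 6.0, "mua_per_mm": 0.01, "g": 0.8}]
        )
        from .trajectory_model import Layer

        layers = tuple(
            Layer(
                d=float(lc["d_mm"]) * 1e-3,
                n=float(lc.get("n", 1.4)),
                mus=float(lc.get("mus_per_mm", 0.0)) * 1e3,
                mua=float(lc.get("mua_per_mm", 0.0)) * 1e3,
                g=float(lc.get("g", 0.8)),
            )
            for lc in layers_cfg
        )
        stack = MediumStack(layers)
        det = DetectorSpec(grid=grid, na=float(cfg.get("na", 0.5)))
        result = propagate(
            params,
            stack,
            det,
            n_photons=int(float(cfg.get("nph", 1e6))),
            seed=seed,
            xi_mem_factor=float(cfg.get("xi_mem_factor", 20.0)),
            coherence_px=float(cfg.get("coherence_px", 2.5)),
        )
        od = result.summary.optical_depth
        carrier = carrier_default(grid)
        sideband = _sideband_bins(carrier, grid)
        ref = ReferenceWave(kind="plane", tilt=carrier, amplitude_ratio=1.0)
        holos = []
        for d in offsets:
            f = ComplexField(grid=grid, z=0.0, amplitude=result.sample_field(float(d)))
            img, _ = interfere(f, ref, cam)
            holos.append(img)
        holo = np.stack(holos)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    phases = _retrieve_stack(holo, sideband=sideband)
    mask = annular_mask(params, grid).mask
    mm = memory_map(phases, offsets)
    summary = mm.summary(mask, r2_floor=float(cfg.get("r2_floor", 0.0)))
    label = regime_label(od, override=cfg.get("regime_override"))

    manifest = RunManifest(config=cfg, seeds={"seed": seed})
    manifest.add_digest("holograms", holo)
    manifest.timing_s = time.time() - t0
    report = MemoryReport(
        summary=summary,
        regime=label,
        optical_depth=od,
        slope_map=mm.slope,
        r2_map=mm.r_squared,
        manifest=manifest,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "memory_summary.json").write_text(
            json.dumps({"summary": summary, "regime": label, "optical_depth": od}, indent=2)
        )
        manifest.write(outdir / "manifest.json")
    return report
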