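"""Spiral photon trajectories of an LG beam and the twist they predict.

The beam's energy flow follows spiral paths around the axis; in the
dimensionless coordinates r = rho/w0 and zeta = z/(k*w0^2) the path through
the waist is the closed form

    r(zeta)   = r0 * sqrt(1 + 4*zeta^2)
    phi(zeta) = ell / (2*r0^2) * arctan(2*zeta) + phi0

and the transverse arc length is the integral of
sqrt((dr/dzeta)^2 + r^2 (dphi/dzeta)^2).  Converting a pathlength increment
inside a layer of refractive index n into phase uses

    dPsi = 2*pi*n*dL / lambda.

A note on the longitudinal term: the transverse integrand above is written
in waist units while zeta advances in units of k*w0^2.  The true 3-D
geometric arc length per unit zeta is therefore
sqrt(1 + [(dr/dzeta)^2 + r^2(dphi/dzeta)^2] / (k*w0)^2) in zeta units,
which is what :func:`trajectory_length` computes by default
(``transverse_scale = 1/(k*w0)``); multiplied by k*w0^2 it reduces to the
straight-ray physical length for an axial ray, as phase retardation
bookkeeping requires.  Passing ``transverse_scale=1`` keeps the literal
dimensionless radical (with or without the +1) for fidelity checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .beam_optics import BeamParameters, GridSpec, lg_radial_amplitude

__all__ = [
    "TrajectoryStart",
    "Trajectory",
    "Layer",
    "MediumStack",
    "PathLengthRecord",
    "TwistPrediction",
    "trajectory_point",
    "trajectory_length",
    "poynting_direction",
    "make_trajectory",
    "refract_through_stack",
    "phase_retardation",
    "sample_starts",
    "stack_retardation",
    "mean_retardation_curve",
    "predict_twist_series",
]


@dataclass(frozen=True)
class TrajectoryStart:
    """Dimensionless launch point of a spiral trajectory at z = 0."""

    r0: float
    phi0: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.r0 < 0:
            raise ValueError("r0 must be non-negative")
        if self.weight < 0:
            raise ValueError("launch weight must be non-negative")


@dataclass(frozen=True)
class Layer:
    """One homogeneous slab: thickness d (m), index n, scattering/absorption."""

    d: float
    n: float
    mus: float = 0.0
    mua: float = 0.0
    g: float = 0.0

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("layer thickness must be positive")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")
        if not (0 <= self.g < 1):
            raise ValueError("anisotropy g must be in [0, 1)")
        if self.mus < 0 or self.mua < 0:
            raise ValueError("mus and mua must be non-negative")


@dataclass(frozen=True)
class MediumStack:
    """Ordered layers (e.g. cuvette wall / interior / wall) along +z."""

    layers: tuple[Layer, ...]
    z_offset: float = 0.0
    n_ambient: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if not self.layers:
            raise ValueError("stack needs at least one layer")

    @property
    def total_thickness(self) -> float:
        return sum(layer.d for layer in self.layers)

    def with_layer_index(self, i: int, n: float) -> "MediumStack":
        layers = list(self.layers)
        old = layers[i]
        layers[i] = Layer(old.d, n, old.mus, old.mua, old.g)
        return MediumStack(tuple(layers), self.z_offset, self.n_ambient)

    @staticmethod
    def cuvette(
        interior_n: float = 1.3330,
        interior_d: float = 3.6e-3,
        wall_d: float = 1.0e-3,
        wall_n: float = 1.52,
        z_offset: float = 0.0,
    ) -> "MediumStack":
        """Glass/liquid/glass cuvette; defaults give 5.6 mm total thickness."""
        return MediumStack(
            (Layer(wall_d, wall_n), Layer(interior_d, interior_n), Layer(wall_d, wall_n)),
            z_offset=z_offset,
        )


@dataclass
class PathLengthRecord:
    """Geometric pathlength inside one layer and its phase retardation."""

    delta_L: float
    delta_psi: float
    trajectory_id: int = 0


@dataclass
class Trajectory:
    """Sampled spiral trajectory, optionally with Snell bend records."""

    start: TrajectoryStart
    ell: int
    zeta_samples: np.ndarray
    points: np.ndarray = field(repr=False)  # (N, 2): r(zeta), phi(zeta)
    length_L: np.ndarray = field(repr=False)
    refracted: bool = False
    bends: list[dict] = field(default_factory=list)
    layer_paths: list[PathLengthRecord] = field(default_factory=list)


def trajectory_point(
    start: TrajectoryStart, zeta: np.ndarray | float, ell: int
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Closed-form spiral point (r, phi) at dimensionless distance zeta."""
    if start.r0 == 0 and ell != 0:
        raise ValueError("azimuthal term singular for r0 = 0 with ell != 0")
    zeta = np.asarray(zeta, dtype=float)
    r = start.r0 * np.sqrt(1.0 + 4.0 * zeta**2)
    if start.r0 == 0:
        phi = np.full_like(zeta, start.phi0)
    else:
        phi = ell / (2.0 * start.r0**2) * np.arctan(2.0 * zeta) + start.phi0
    if zeta.shape:
        return r, phi
    return float(r), float(phi)


def _speed_sq_transverse(r0: float, ell: int, zeta: np.ndarray) -> np.ndarray:
    # (dr/dzeta)^2 + r^2 (dphi/dzeta)^2 for the closed-form spiral
    one = 1.0 + 4.0 * zeta**2
    dr = 4.0 * r0 * zeta / np.sqrt(one)
    if r0 == 0:
        return dr**2
    rdphi = ell / (r0 * np.sqrt(one))
    return dr**2 + rdphi**2


def trajectory_length(
    start: TrajectoryStart,
    zeta_s: float,
    ell: int,
    include_longitudinal: bool = True,
    transverse_scale: float | None = None,
) -> float:
    """Arc length of the spiral from zeta = 0 to ``zeta_s``.

    With ``include_longitudinal=False`` this is exactly the transverse
    integral of sqrt((dr/dzeta)^2 + r^2 (dphi/dzeta)^2) (dimensionless,
    waist units).  With the default ``True`` a unit longitudinal term is
    added under the radical so the result measures 3-D path per unit zeta;
    ``transverse_scale`` (default 1) multiplies the transverse integrand
    terms and should be set to 1/(k*w0) when a physically scaled 3-D length
    is required (see module docstring).
    """
    if zeta_s < 0:
        raise ValueError("zeta_s must be non-negative")
    if start.r0 == 0 and ell != 0:
        raise ValueError("azimuthal term singular for r0 = 0 with ell != 0")
    if zeta_s == 0:
        return 0.0
    s = 1.0 if transverse_scale is None else float(transverse_scale)
    base = 1.0 if include_longitudinal else 0.0

    def integrand(z: float) -> float:
        return math.sqrt(base + s * s * float(_speed_sq_transverse(start.r0, ell, np.asarray(z))))

    val, _ = quad(integrand, 0.0, zeta_s, epsabs=1e-14, epsrel=1e-12, limit=200)
    return float(val)


def poynting_direction(
    params: BeamParameters,
    rho: float | np.ndarray,
    phi: float | np.ndarray,
    z: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cylindrical Poynting components (p_rho, p_phi, p_z) of the LG mode.

    All three share the local intensity factor |LG|^2; the ratios
    p_rho/p_z = rho*z/(zR^2+z^2) and p_phi/p_z = ell/(k*rho) are therefore
    intensity-independent.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("poynting_direction requires rho > 0")
    inten = np.abs(lg_radial_amplitude(params, rho, z)) ** 2
    w, k, zr = params.omega, params.k, params.rayleigh_range
    p_rho = w * k * rho * z / (zr * zr + z * z) * inten
    p_phi = w * params.ell / rho * inten
    p_z = w * k * inten
    return p_rho, p_phi, p_z


def phase_retardation(delta_L: float | np.ndarray, n: float, wavelength: float) -> float | np.ndarray:
    """Phase accumulated over geometric path delta_L in index n: 2*pi*n*dL/lambda."""
    delta_L = np.asarray(delta_L, dtype=float)
    if np.any(delta_L < 0):
        raise ValueError("delta_L must be non-negative")
    out = 2.0 * math.pi * n * delta_L / wavelength
    return out if out.shape else float(out)


def make_trajectory(
    start: TrajectoryStart, ell: int, zeta_samples: np.ndarray, params: BeamParameters | None = None
) -> Trajectory:
    """Sample the closed-form spiral at ``zeta_samples`` with running length."""
    zeta = np.asarray(zeta_samples, dtype=float)
    r, phi = trajectory_point(start, zeta, ell)
    scale = None if params is None else 1.0 / (params.k * params.waist_w0)
    lengths = np.array(
        [trajectory_length(start, zs, ell, transverse_scale=scale) for zs in zeta]
    )
    return Trajectory(start=start, ell=ell, zeta_samples=zeta, points=np.stack([r, phi], axis=-1), length_L=lengths)


# ---------------------------------------------------------------------------
# Snell refraction through a layered stack (paraxial planar interfaces)
# ---------------------------------------------------------------------------


def _inclination(start: TrajectoryStart, ell: int, zeta: float, params: BeamParameters) -> float:
    """Angle of the spiral tangent to the z axis (radians), from the analytic tangent."""
    t_sq = float(_speed_sq_transverse(start.r0, ell, np.asarray(zeta)))
    # transverse slope d(transverse)/dz = sqrt(t_sq) / (k*w0)
    return math.atan(math.sqrt(t_sq) / (params.k * params.waist_w0))


def _layer_pathlengths(
    sin_inc: np.ndarray, stack: MediumStack
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Per-layer slant pathlengths d/cos(theta) after Snell bending.

    ``sin_inc``: sine of the inclination to z in the ambient medium at the
    stack entrance, vectorized over trajectories.  Returns (sines_inside
    per layer, pathlengths per layer).
    """
    paths = []
    n_prev = stack.n_ambient
    s = np.asarray(sin_inc, dtype=float)
    sines = s.copy()
    for layer in stack.layers:
        sines = sines * (n_prev / layer.n)
        if np.any(np.abs(sines) >= 1.0):
            raise ValueError("total internal reflection: misconfigured stack/trajectory")
        cos_in = np.sqrt(1.0 - sines**2)
        paths.append(layer.d / cos_in)
        n_prev = layer.n
    return sines, paths


def refract_through_stack(traj: Trajectory, stack: MediumStack, params: BeamParameters) -> Trajectory:
    """Bend a trajectory through planar interfaces by Snell's law.

    The instantaneous inclination at the stack entrance comes from the
    analytic spiral tangent; within each layer the (tiny) bent path is a
    straight slant, so the per-layer pathlength is d/cos(theta_layer),
    never shorter than the layer thickness.
    """
    kw2 = params.k * params.waist_w0**2
    zeta_in = stack.z_offset / kw2
    inc = _inclination(traj.start, traj.ell, zeta_in, params)
    sin_in = math.sin(inc)
    bends: list[dict] = []
    records: list[PathLengthRecord] = []
    n_prev = stack.n_ambient
    s = sin_in
    for i, layer in enumerate(stack.layers):
        s_new = s * n_prev / layer.n
        if abs(s_new) >= 1.0:
            raise ValueError("total internal reflection: misconfigured stack/trajectory")
        bends.append(
            {"interface": i, "n_from": n_prev, "n_to": layer.n, "sin_before": s, "sin_after": s_new}
        )
        dl = layer.d / math.sqrt(1.0 - s_new * s_new)
        records.append(
            PathLengthRecord(
                delta_L=dl,
                delta_psi=float(phase_retardation(dl, layer.n, params.wavelength)),
            )
        )
        n_prev = layer.n
        s = s_new
    return Trajectory(
        start=traj.start,
        ell=traj.ell,
        zeta_samples=traj.zeta_samples,
        points=traj.points,
        length_L=traj.length_L,
        refracted=True,
        bends=bends,
        layer_paths=records,
    )


# ---------------------------------------------------------------------------
# Ensemble sampling and twist prediction
# ---------------------------------------------------------------------------


def sample_starts(
    params: BeamParameters, n: int, rng: np.random.Generator, r_max_w0: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (r0, phi0) with r0 ~ radial |LG|^2 density (inverse CDF), phi0 uniform."""
    r_grid = np.linspace(1e-6, r_max_w0, 4096)
    inten = np.abs(lg_radial_amplitude(params, r_grid * params.waist_w0, 0.0)) ** 2
    pdf = inten * r_grid  # 2-D measure
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]
    u = rng.random(n)
    r0 = np.interp(u, cdf, r_grid)
    phi0 = rng.uniform(0.0, 2.0 * math.pi, n)
    return r0, phi0


def stack_retardation(
    r0: np.ndarray,
    params: BeamParameters,
    stack: MediumStack,
) -> np.ndarray:
    """Total phase retardation through the stack per trajectory (vectorized).

    Inclination at the stack entrance from the analytic spiral tangent,
    Snell-bent straight slants inside each layer, Eq-style 2*pi*n*dL/lambda
    per layer summed.
    """
    kw2 = params.k * params.waist_w0**2
    zeta_in = stack.z_offset / kw2
    r0 = np.asarray(r0, dtype=float)
    one = 1.0 + 4.0 * zeta_in**2
    dr = 4.0 * r0 * zeta_in / math.sqrt(one)
    rdphi = np.where(r0 > 0, params.ell / (r0 * math.sqrt(one)), 0.0)
    t_sq = dr**2 + rdphi**2
    slope = np.sqrt(t_sq) / (params.k * params.waist_w0)
    sin_inc = slope / np.sqrt(1.0 + slope**2)
    _, paths = _layer_pathlengths(sin_inc, stack)
    psi = np.zeros_like(np.asarray(r0, dtype=float))
    for layer, dl in zip(stack.layers, paths):
        psi = psi + 2.0 * math.pi * layer.n * dl / params.wavelength
    return psi


def mean_retardation_curve(
    params: BeamParameters,
    stack: MediumStack,
    varying_layer: int,
    delta_n: np.ndarray,
    n_traj: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ensemble-mean retardation increase vs delta_n of the varying layer.

    Returns (delta_n, mean dPsi relative to delta_n = 0, r0 samples).
    Smooth in delta_n, so it doubles as the unwrap guide for petal-based
    twist extraction and as the monotone forward map for inversion.
    """
    r0, _ = sample_starts(params, n_traj, rng)
    base_n = stack.layers[varying_layer].n
    psi0 = stack_retardation(r0, params, stack).mean()
    out = np.empty_like(np.asarray(delta_n, dtype=float))
    for i, dn in enumerate(np.asarray(delta_n, dtype=float)):
        st = stack.with_layer_index(varying_layer, base_n + dn)
        out[i] = stack_retardation(r0, params, st).mean() - psi0
    return np.asarray(delta_n, dtype=float), out, r0


@dataclass
class TwistPrediction:
    """Predicted petal twist versus refractive-index change."""

    delta_n: np.ndarray
    theta_rad: np.ndarray
    theta_guide_rad: np.ndarray
    n_traj: int
    seed: int | None
    flagged: bool = False

    @property
    def theta_deg(self) -> np.ndarray:
        return np.degrees(self.theta_rad)


def _reconstruct_pattern(
    r_end: np.ndarray,
    phi_end: np.ndarray,
    psi: np.ndarray,
    params: BeamParameters,
    grid: GridSpec,
) -> np.ndarray:
    """Coherent binning of trajectory endpoints into a complex field image."""
    x = r_end * params.waist_w0 * np.cos(phi_end)
    y = r_end * params.waist_w0 * np.sin(phi_end)
    cx, cy = grid.center
    ix = np.round(x / grid.pitch + cx).astype(int)
    iy = np.round(y / grid.pitch + cy).astype(int)
    ok = (ix >= 0) & (ix < grid.nx) & (iy >= 0) & (iy < grid.ny)
    field = np.zeros((grid.ny, grid.nx), dtype=complex)
    np.add.at(field, (iy[ok], ix[ok]), np.exp(1j * psi[ok]))
    return field


def predict_twist_series(
    params: BeamParameters,
    stack: MediumStack,
    delta_n_series: np.ndarray,
    n_traj: int = 100_000,
    varying_layer: int | None = None,
    seed: int | None = 0,
    grid: GridSpec | None = None,
    smooth_px: float = 1.0,
) -> TwistPrediction:
    """Predict relative petal twist Theta for a monotone delta_n series.

    Launches ``n_traj`` spiral trajectories sampled from the annular |LG|^2
    profile, accumulates per-trajectory retardation through the Snell-bent
    stack for each delta_n, reconstructs the petal interference pattern and
    measures its rotation with the same petal algorithm used on measured
    stacks.  The petal angle is only defined modulo 2*pi/|ell|; the branch
    is selected with the ensemble-mean retardation as unwrap guide.
    """
    from scipy.ndimage import gaussian_filter

    from .beam_optics import ComplexField
    from .interferogram_synth import CameraModel, ReferenceWave, interfere
    from .twist_analysis import petal_pattern_angle

    delta_n_series = np.asarray(delta_n_series, dtype=float)
    if np.any(np.diff(delta_n_series) < 0) and np.any(np.diff(delta_n_series) > 0):
        raise ValueError("delta_n_series must be monotone")
    if n_traj < 1_000:
        raise ValueError("n_traj must be at least 1000")
    flagged = n_traj < 20_000
    if flagged:
        warnings.warn(
            f"n_traj = {n_traj} may be too small for stable petals; output flagged",
            RuntimeWarning,
            stacklevel=2,
        )
    if varying_layer is None:
        varying_layer = int(np.argmax([la.d for la in stack.layers]))
    if params.ell == 0:
        raise ValueError("petal twist is undefined for ell = 0")

    rng = np.random.default_rng(seed)
    r0, phi0 = sample_starts(params, n_traj, rng)
    base_n = stack.layers[varying_layer].n
    kw2 = params.k * params.waist_w0**2
    zeta_exit = (stack.z_offset + stack.total_thickness) / kw2
    one = 1.0 + 4.0 * zeta_exit**2
    r_end = r0 * np.sqrt(one)
    phi_end = params.ell / (2.0 * r0**2) * math.atan(2.0 * zeta_exit) + phi0

    if grid is None:
        ring = params.waist_w0 * math.sqrt(max(abs(params.ell), 1) / 2.0)
        grid = GridSpec(128, 128, pitch=ring * 7.0 / 128)

    psi_base = stack_retardation(r0, params, stack)
    mean_base = psi_base.mean()

    ref = ReferenceWave(kind="plane", amplitude_ratio=1.0)
    cam = CameraModel(shot_noise=False)

    theta = np.empty_like(delta_n_series)
    guide = np.empty_like(delta_n_series)
    psi_ref_pattern = None
    ref_angle = None
    period = 2.0 * math.pi / abs(params.ell)
    for i, dn in enumerate(delta_n_series):
        st = stack.with_layer_index(varying_layer, base_n + dn)
        psi = stack_retardation(r0, params, st)
        guide[i] = (psi.mean() - mean_base) / params.ell
        phase = -params.ell * phi0 + (psi - mean_base)
        field = _reconstruct_pattern(r_end, phi_end, phase, params, grid)
        field = gaussian_filter(field.real, smooth_px) + 1j * gaussian_filter(field.imag, smooth_px)
        img, _ = interfere(ComplexField(grid=grid, z=0.0, amplitude=field), ref, cam)
        ang = petal_pattern_angle(img, abs(params.ell), center=grid.center)
        if ref_angle is None:
            ref_angle = ang
            theta[i] = 0.0
            guide0 = guide[i]
        else:
            wrapped = (ang - ref_angle) % period
            target = guide[i] - guide0
            k = round((target - wrapped) / period)
            theta[i] = wrapped + k * period
    guide -= guide[0]
    return TwistPrediction(
        delta_n=delta_n_series,
        theta_rad=theta,
        theta_guide_rad=guide,
        n_traj=n_traj,
        seed=seed,
        flagged=flagged,
    )
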