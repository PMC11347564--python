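"""Config files, TIFF field export and sidecar metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .beam_optics import BeamParameters, ComplexField, GridSpec

__all__ = [
    "load_config",
    "beam_from_config",
    "grid_from_config",
    "save_field",
    "load_field",
    "save_stack",
    "load_stack",
]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def beam_from_config(cfg: dict) -> BeamParameters:
    """Beam parameters from flat keys: wavelength_nm, waist_mm, ell, p."""
    return BeamParameters(
        wavelength=float(cfg.get("wavelength_nm", 640.0)) * 1e-9,
        waist_w0=float(cfg.get("waist_mm", 1.0)) * 1e-3,
        ell=int(cfg.get("ell", 3)),
        p=int(cfg.get("p", 0)),
    )


def grid_from_config(cfg: dict) -> GridSpec:
    """Grid from flat keys nx, ny, pitch_um (origin defaults to centre)."""
    return GridSpec(
        nx=int(cfg.get("nx", 256)),
        ny=int(cfg.get("ny", 256)),
        pitch=float(cfg.get("pitch_um", 20.0)) * 1e-6,
    )


def save_field(fieldv: ComplexField, basepath: str | Path) -> None:
    """Write amplitude/phase float32 TIFF pair plus a JSON grid sidecar."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(base.with_suffix(".amplitude.tif"), np.abs(fieldv.amplitude).astype(np.float32))
    tifffile.imwrite(base.with_suffix(".phase.tif"), np.angle(fieldv.amplitude).astype(np.float32))
    meta = {
        "nx": fieldv.grid.nx,
        "ny": fieldv.grid.ny,
        "pitch_m": fieldv.grid.pitch,
        "origin": list(fieldv.grid.center),
        "z_m": fieldv.z,
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_field(basepath: str | Path) -> ComplexField:
    base = Path(basepath)
    amp = tifffile.imread(base.with_suffix(".amplitude.tif")).astype(float)
    ph = tifffile.imread(base.with_suffix(".phase.tif")).astype(float)
    meta = json.loads(base.with_suffix(".json").read_text())
    grid = GridSpec(
        nx=meta["nx"], ny=meta["ny"], pitch=meta["pitch_m"], origin=tuple(meta["origin"])
    )
    return ComplexField(grid=grid, z=meta.get("z_m", 0.0), amplitude=amp * np.exp(1j * ph))


def save_stack(
    stack: np.ndarray, times: np.ndarray, path: str | Path, sidecar: dict | None = None
) -> None:
    """16-bit TIFF stack plus CSV timestamp sidecar and optional JSON extras."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack))
    import pandas as pd

    pd.DataFrame({"frame": np.arange(len(times)), "t_s": times}).to_csv(
        path.with_suffix(".csv"), index=False
    )
    if sidecar is not None:
        clean = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in sidecar.items()
            if not isinstance(v, np.ndarray) or v.ndim <= 1
        }
        path.with_suffix(".json").write_text(json.dumps(clean, indent=2, default=str))


def load_stack(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    stack = tifffile.imread(path)
    csv = path.with_suffix(".csv")
    if csv.exists():
        import pandas as pd

        times = pd.read_csv(csv)["t_s"].to_numpy()
    else:
        times = np.arange(stack.shape[0]) / 10.0
    return stack, times
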