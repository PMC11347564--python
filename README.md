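# oamtwist

Forward models and image analysis for probing media with orbital-angular-momentum
(OAM) light. The package simulates how a Laguerre–Gaussian (LG) vortex beam's
helical phase twists when the refractive index of a medium drifts, and how it
degrades — but partially survives — under multiple scattering, and provides the
measurement algorithms that extract both effects from interferogram image
stacks.

## What's inside

| module | role |
| --- | --- |
| `oamtwist.beam_optics` | LG mode fields, closed-form phase (curvature, azimuthal, Gouy terms), beam geometry |
| `oamtwist.trajectory_model` | spiral photon trajectories, Snell refraction through layered stacks, pathlength → phase retardation, petal-twist prediction vs refractive-index change |
| `oamtwist.scatter_transport` | weighted Monte Carlo with Henyey–Greenstein scattering, semi-analytic coherent detection, optical-depth bookkeeping, polarization-degree law |
| `oamtwist.interferogram_synth` | on-axis (petal) and off-axis (carrier-fringe) interferograms with a quantizing camera model |
| `oamtwist.twist_analysis` | Otsu binarization, Moore-Neighbor boundary tracing (Jacob's stopping criterion), petal polygons/centroids, unwrapped frame-to-frame twist |
| `oamtwist.phase_retrieval` | FFT sideband phase retrieval, annular masks, per-pixel phase-memory regression |
| `oamtwist.synthetic_data` | deterministic generators: thermal runs, petal stacks with ground truth, partial-memory speckle |
| `oamtwist.pipeline` | end-to-end sensing (twist → index inversion) and phase-memory analyses with manifests |

## CLI

All stages are exposed through one entry point:

```bash
# synthetic inputs
oamtwist synth thermal --out run/                       # drifting-index thermal log (CSV)
oamtwist synth twist-stack --config run.yml --out run/  # petal stack + ground truth
oamtwist synth speckle --config run.yml --out run/      # off-axis speckle stacks

# forward model and transport
oamtwist predict --dn-stop 2e-5 --steps 50 --out twist.csv
oamtwist mc --config phantom.yml --nph 1e6 --seed 42 --out field

# analysis
oamtwist analyze --stack run/twist_stack.tif --ell 5 --out twist.csv
oamtwist retrieve --stack offaxis.tif --out phase.tif
oamtwist memory --stacks run_d.tif --offsets offsets.csv --out memory

# headline pipelines
oamtwist run-sensing --config sense.yml --seed 1 --out report/
oamtwist run-memory --config mem.yml --seed 1 --out report/
```

Configs are flat YAML; see the docstrings of `pipeline.run_sensing` /
`pipeline.run_memory` for the recognised keys. Image stacks are plain
16-bit TIFF with CSV timestamp sidecars; fields are float32 amplitude/phase
TIFF pairs with a JSON grid sidecar.

## Conventions

* Helical phase `exp(-i*ell*phi)` with `phi` counter-clockwise from +x;
  a positive index increase rotates petals counter-clockwise by
  `delta_Psi / ell`.
* All lengths SI metres internally; CLI/configs use nm, mm and µm where
  conventional.
* Every stochastic routine takes an explicit seed and is bit-reproducible.
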