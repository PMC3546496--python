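# bladdereit

3D electrical impedance tomography (EIT) of bladder filling with a planar
8 × 8 electrode array: complete-electrode-model forward simulation,
combined Tikhonov + NOSER regularized difference imaging, steplike-edge
boundary-surface extraction on tetrahedral meshes, and voxel-based volume
and position quantification — exercised end to end on synthetic cuboid
phantoms.

## The problem and who this is for

Continuous, non-invasive monitoring of bladder volume matters for
patients who cannot sense or signal bladder filling. EIT estimates the
internal conductivity distribution from boundary voltages under applied
currents; urine (saline, ≈0.892 S/m) against tissue-like background
(≈0.1 S/m) is a strong conductive anomaly, so its *change* relative to a
reference state can be imaged and its volume estimated. This package is
for researchers studying that measurement chain in simulation: the
planar-array geometry, the regularized one-step inverse problem, and —
the distinctive part — extracting an explicit closed boundary surface of
the anomaly from the volumetric image and counting its volume on a 1 mm
grid.

## The method

A frame is 64 sequential 10 mA injections (each array electrode against
a grounded back electrode) with voltages read from the 63 non-driven
electrodes: 64 × 63 = 4032 measurements. With `x_p` the homogeneous
reference conductivity, `F(x_p)` its simulated frame, `V` the measured
frame and `J` the sensitivity (Jacobian) matrix of the complete
electrode model, the linearized difference image is

    δx = x_p − x = (JᵀJ + λI + ε·diag(JᵀJ))⁻¹ Jᵀ (F(x_p) − V)

(the combined penalty; pure Tikhonov `λI` and pure NOSER
`ε·diag(JᵀJ)` are available separately). The anomaly boundary is then
treated as a steplike edge of the image `f = |δx|`: the surface where
`∇²f = 0` while `‖∇f‖ ≥ T`. Tetrahedra crossed by that surface (≥ 3 of
their 6 edges intersected) are detected, small spurious components are
removed, the set is grown through face neighbours, and the zero-crossing
is triangulated by marching tetrahedra into a crack-free closed shell.
Volume is counted on a 1 mm voxel grid (a cube counts when ≥ 4
non-coplanar vertices are enclosed, 10⁻³ mL per cube); position is the
half-amplitude centre of mass Σ|δx_m|·p_m / Σ|δx_m|, with per-axis
errors as a percentage of the tank extent.

See `docs/methods.md` for discretizations, parameter defaults and
limitations.

## Worked example

Simulate the 4 × 4 × 4 cm (64 mL) saline model in the 18 × 15 × 10 cm
tank, reconstruct, extract the surface and quantify — noiseless, on the
default desk-scale mesh:

```python
from bladdereit.pipeline import PipelineConfig, run_full

config = PipelineConfig.model_validate({
    "phantom": {
        "preset": "desk",
        "inclusions": [{"model": "cube40"}],
        "noise_snr_db": None,
        "seed": 7,
    },
    "output_dir": "out",
})
stats = run_full(config)
print(f"estimated volume: {stats.volume_ml:.1f} mL (true {stats.true_volume_ml:.0f} mL)")
print(f"volume error:     {stats.volume_error_pct:+.1f} %")
pe = stats.position_error_pct
print(f"position error:   x {pe[0]:+.2f} %, y {pe[1]:+.2f} %, z {pe[2]:+.2f} %")
```

prints

```
estimated volume: 90.8 mL (true 64 mL)
volume error:     +41.9 %
position error:   x +0.32 %, y +0.48 %, z +7.53 %
```

Reading the numbers: the anomaly is found almost exactly in plane
(x, y errors below 1% of the tank extent) and somewhat high in z — the
centre of mass is pulled toward the electrode array, where sensitivity
is larger. The volume overshoot is the localization blur of a one-step
linearized reconstruction at desk-scale mesh density; the finer `paper`
mesh preset (`"preset": "paper"`, the scale of the physical experiment)
roughly halves it. Every stage's artifacts land in `out/`: measurement
frames (CSV), mesh and per-element fields (legacy VTK), the extracted
surface (STL/PLY), and stats (JSON + a cumulative `results.csv`).

The same pipeline is scriptable from the shell:

```bash
bladder-eit init-config run.yaml     # write the default config
bladder-eit full -c run.yaml -o out  # simulate -> reconstruct -> extract -> quantify
```

with subcommands `simulate`, `reconstruct`, `extract`, `quantify`, and
`full`.

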