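# foamct

Foam-like mathematical phantoms for comparing tomography algorithms.

Tomographic algorithm comparisons need test objects that are challenging
(fine structure at many scales), representative (like the foam samples
routinely scanned at synchrotron beamlines), flexible (any acquisition
geometry, noise level, or object complexity), and available in unlimited
seeded variations for data-driven methods. Classic phantoms with a handful
of ellipses satisfy none of this, and reconstructions of real scans reused
as phantoms drag their artifacts along and invite the *inverse crime* —
simulating data with the same discretized model used to reconstruct.

`foamct` generates foam phantoms — a unit cylinder of attenuation 1 pierced
by up to ~10⁵ non-overlapping spherical voids — and simulates projections
**analytically in the continuous domain**, so the simulation shares no
discretization with any reconstruction algorithm under test. It targets
tomography researchers benchmarking reconstruction, artifact-removal, or
segmentation algorithms, in 3D or 4D (time-evolving samples).

## The model

Each void is a vector `s_i = (x_i, y_i, z_i, r_i, c_i)` (center, radius,
attenuation); a phantom is the set `S = {s_1, …, s_N}` subject to
`√(x²+y²) + r ≤ 1`, `d(p_i, p_j) ≥ r_i + r_j`, `r ≤ r_max`, `|z| ≤ z_max`.
Generation keeps a pool of `N_p` random *trial points* carrying the largest
feasible radius

    r(p) = min( 1 − √(x²+y²),  min_j [ d(p, p_j) − r_j ],  r_max ),

and repeatedly places a void at the pool's argmax — so every void touches
`r_max`, the cylinder wall, or a neighbor, and the structure is a
deterministic function of `(N, N_p, r_max, z_max, seed)`.

A measurement is the Radon line integral

    P_i = L_i − Σ_j l(i, j) · (1 − c_j),

with exact chord lengths `L_i = 2√(r_C² − dz_i²)` through the cylinder and
`l(i, j) = 2√(r_j² − dv(i,j)²)` through the voids, for parallel- and
cone-beam geometries, with `s×s` rays per detector pixel and Beer–Lambert
Poisson noise (`I = I0·e^{−γP}`, `P̂ = −ln(Î/I0)/γ`). Three 4D extensions
evolve a phantom over time: common vertical motion with randomly changing
velocity, uniform void growth, and neighbor-to-neighbor infiltration by a
second material. A benchmark harness reconstructs the central slice with
FBP, SIRT, CGLS and SART (± nonnegativity) and scores RMSE, PSNR, MS-SSIM
and per-size-class Dice against a supersampled ground truth.

## Worked example

```python
import foamct

# a 2000-void foam, reproducible from its parameter tuple
phantom = foamct.generate_foam(
    n_voids=2000, n_trial_points=10_000,
    max_radius=0.2, max_height=1.5, seed=1,
)
print(len(foamct.validate_phantom(phantom)))          # 0
print(foamct.touching_report(phantom).mean())         # 1.0
print(round(phantom.radii.max(), 3))                  # 0.2

# analytic central-slice sinogram, 4x4 rays per pixel
geom = foamct.ParallelGeometry(
    n_angles=128, angular_range=180.0, det_rows=1,
    det_cols=512, pixel_width=3 / 512, supersampling=4,
)
stack = foamct.project_parallel(phantom, geom)

# Poisson noise at 250 photons/ray, gamma tuned for 50% absorption
gamma = foamct.calibrate_gamma(stack, 0.5)
noisy = foamct.apply_noise(stack, foamct.NoiseModel(250.0, gamma, seed=1))
print(round(gamma, 3))                                # 1.17

# reconstruct and score against the supersampled ground-truth slice
from foamct.recon import SCENARIOS, run_scenario
rows = run_scenario(
    phantom, SCENARIOS["few-projections"].scaled(0.25),  # 32 angles
    algorithms=("fbp", "sirt+"), det_cols=512, supersampling=4,
)
for r in rows:
    print(f"{r.algorithm:6s} rmse={r.rmse:.3f} ms_ssim={r.ms_ssim:.3f}")
# fbp    rmse=0.344 ms_ssim=0.302
# sirt+  rmse=0.098 ms_ssim=0.953
```

The zero violation count and all-true touching report confirm the packing
invariants; the maximum radius hits the `r_max` cap. In the undersampled
scenario the streak-ridden FBP slice has more than 3× the RMSE of the
nonnegativity-constrained SIRT reconstruction at its RMSE-optimal iterate —
the characteristic ordering this phantom family was built to expose.

The same pipeline is scriptable from a shell:

```sh
foamct generate --n-voids 2000 --seed 1 --out foam.h5
foamct project --angles 128 --cols 512 --supersampling 4 foam.h5 projs.h5
foamct noise --flux 250 --absorption 0.5 --seed 1 projs.h5 noisy.h5
foamct benchmark --scenario few-projections --scale 0.2 foam.h5 report.csv
```

Every file carries a provenance record; `foamct regenerate file.h5`
rebuilds its payload from that record and verifies bit-identity.

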