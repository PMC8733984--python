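# Methods

## The phantom model

A foam phantom is an infinite vertical cylinder of radius 1 and attenuation 1
containing `N` non-overlapping spherical voids. All lengths are expressed in
units of the cylinder radius and all attenuations relative to the foam
material; conversion to physical units (e.g. µm per unit radius) is left to
the user. Void `i` is the vector `(x_i, y_i, z_i, r_i, c_i)`; by default
voids hold the non-absorbing background material (`c = 0`), but each void may
carry its own attenuation, which is what the infiltration model exploits.

Constraints: `√(x²+y²) + r ≤ 1` (containment), `d(p_i, p_j) ≥ r_i + r_j`
(non-overlap), `r ≤ r_max`, and `|z| ≤ z_max` — the height bound applies to
the void *center* only, so voids may protrude past `±z_max` and the volume
that can contain void material extends to `±(z_max + r_max)`.

Boundary semantics are a measure-zero choice fixed once: points exactly on a
void or cylinder surface belong to the foam (containment uses `≤`, interior
membership uses `<`). Validation (`validate_phantom`) treats violations as
data with signed magnitudes, not exceptions, because the expanding 4D model
legitimately produces overlaps that callers want reported. The default
geometric tolerance is 1e−9 unit radii; overlap and containment checks are
one-sided because the generator produces *exact* touching by construction.

## Generation

Voids are placed greedily: a pool of `N_p` trial points (uniform on the valid
region: strictly inside the cylinder, strictly outside every void,
`|z| ≤ z_max`) carries the feasible radius

    r(p) = min(1 − √(x²+y²), min_j [d(p, p_j) − r_j], r_max),

and each iteration places a void of exactly that radius at the pool's argmax,
ties broken uniformly at random. Every void therefore touches whatever bound
it: `r_max`, the cylinder wall, or a neighboring void ("touching property"),
and void sizes decay naturally as the foam fills. The phantom is a
deterministic function of `(N, N_p, r_max, z_max, seed)`.

Reproducibility contract: one `numpy.random.Generator` (PCG64) drives
everything, consumed in a fixed order — initial pool fill, then per iteration
a tie-break draw *only when two or more maxima tie within 1e−12* (keeping the
common path draw-free is documented because it affects stream alignment),
then the refill draws. Self-reproducibility is promised; bit-compatibility
across NumPy versions or other implementations is not. Rejection sampling
gives up after 10⁶ consecutive rejections, which distinguishes a nearly
jammed phantom from an infinite loop.

Data structures: feasible radii live in a flat NumPy array; retrieve-max is a
vectorized scan. A pointer-based priority structure with O(log N_p) updates
was considered and rejected — at the pool sizes in use (≤ 10⁶) a vectorized
O(N_p) scan costs ~0.3 ms and beats Python-level pointer chasing, and tie
detection needs an array scan regardless. Spatial queries (is a candidate
inside a void; which voids can bound a feasible radius) use a uniform cell
grid of size `2·r_max` with numba kernels: since feasible radii are capped at
`r_max`, a void can only matter within distance `2·r_max`, so the 27
surrounding cells are sufficient and the grid returns *exactly* the
brute-force result (asserted by test). The grid is rebuilt every 64
insertions; newer voids are scanned brute-force.

## Projection

Measurements are Radon line integrals computed analytically in the continuous
domain — the phantom is never voxelized for simulation, so reconstruction
(which discretizes) can never commit the inverse crime. For ray `i`:

    P_i = L_i − Σ_j l(i,j) · (1 − c_j),

`L_i` the cylinder chord and `l(i,j)` the chord through void `j`. A
horizontal ray at distance `a` from the axis has `L = 2√(r_C² − a²)`; oblique
(cone-beam) rays divide the chord of their horizontal projection by the
cosine of their inclination. Sphere chords are `2√(r² − dv²)` with `dv` from
projecting the center onto the ray direction. For large source distances the
sphere distance is computed after re-originating the ray at the rotation-axis
plane: forming `|w|² − (w·d)²` with `|w| ≈ sod` loses `sod²·ε` of absolute
precision, which is visible already at `sod ~ 10³`.

Conventions (bit-exact, stored in file metadata): angle θ rotates the sample
counter-clockwise about +z; angles equally spaced on `[0, range)` with the
endpoint excluded, so 1024 projections over 180° do not duplicate 0°/180°;
detector u-axis `(cos θ, −sin θ, 0)` in the sample frame, v-axis +z, row 0 at
the top, detector center on the rotation axis; `s×s` rays per pixel at the
subpixel centers, averaged.

Performance: per projection angle the detector coordinates of all void
centers are computed once; each void then only touches the rays inside its
projected disk (plus a margin), so cost scales with projected void area.
For cone beams the patch is sized by the magnified radius
`r·(sod+odd)/(depth−r)`.

Noise follows Beer–Lambert: `I = I0·exp(−γP)`, one Poisson draw per ray,
`P̂ = −ln(Î/I0)/γ`. Zero counts are clamped to one count before the log —
propagating +∞ would poison every downstream metric — and the clamp count is
reported on the stack. `calibrate_gamma` solves
`mean(1 − exp(−γ P_i)) = target` by bracketed Brent root-finding (1e−10
relative); the mean runs over sample-intersecting rays (`P_i > 0`) by
default, reading "the sample absorbed" as photons that traverse the sample —
`all_rays=True` switches to the whole detector.

## 4D models

All three models leave the base phantom untouched and return snapshots.

* **Moving**: one piecewise-constant z-velocity shared by all voids, redrawn
  per interval (`MovingModel.random` uses i.i.d. N(0, scale²)); displacement
  is the exact integral, zero at t=0. Height validation is disabled on
  snapshots — the sample streams through a fixed scan region.
* **Expanding**: radii scale by a non-decreasing `g(t)` with `g(0)=1`
  (default `1 + rate·t`, rate 0.5/unit time). Growth may create overlaps;
  snapshots report them via `validate_phantom` rather than rescaling,
  because silently shrinking radii would falsify the prescribed growth law.
* **Infiltration**: voids within `|z − z0| ≤ h` fill with the new material at
  t=0; every other void fills one random interval (i.i.d. Exponential, rate
  1/unit time by default) after the earliest fill among its ε-neighbors
  (surface gap ≤ ε, default 0.01). This is a shortest-arrival propagation
  with one delay per node, computed Dijkstra-style; fill times are
  deterministic given the seed and non-decreasing along the propagation tree
  (each void's argmin predecessor). Note this monotonicity holds along the
  propagation tree, not along arbitrary hop-count (BFS) trees: a child can be
  reached earlier through a sibling than through a slow BFS parent.
  ε-unreachable voids never fill unless a global `fallback_time` is set.
  The velocity scale, growth law, interval rate and ε are exposed parameters
  with these documented defaults — nothing in the underlying study pins them.

Dynamic scans map projection `k` to the time interval `[k, k+1)/n_angles` of
the experiment (in acquisition order) and average `n` snapshots at the
midpoints of `n` equal sub-intervals (`n = 1` → interval midpoint), while the
sample rotates per the geometry's angle schedule.

## Discretization

Ground-truth images are point-sampled: each voxel averages the attenuation at
`s³` subvoxel centers (`s²` for slices), consistent with the projector's
supersampling. Because voids are disjoint and inside the cylinder, the mean
splits exactly into a 2D cylinder-coverage term minus per-void coverage
patches, so cost scales with void volume rather than grid volume; boundary
voxels converge as O(1/s). Analytic sphere–cube partial volumes are out of
scope. The grid is centered on the rotation axis, voxel (0,0,0) at the
most-negative corner; the world coordinate of voxel centers is stored in
file metadata, and reconstruction shares the same convention — metrics are
meaningless otherwise. Void masks mark voxel centers inside large
(`r ≥ 0.1`) or small (`r < 0.05`) voids; intermediate radii belong to
neither class.

## Reconstruction benchmark

The forward operator inside reconstruction is a *discretized* Joseph
(linear-interpolation) projector with an exact adjoint, written as matched
numba kernels — deliberately not the analytic simulator. FBP uses the
sampled Ram-Lak impulse response (`h(0)=1/4du²`, `h(k)=−1/π²k²du²` for odd
k) transformed to the frequency domain with zero-padding to the next power
of two ≥ 2×cols; a naive `|ν|` ramp biases the DC level by ~1% on the
uniform-disk oracle, the sampled kernel reconstructs the disk interior to
1.0003. Backprojection weights each filtered projection by Δθ (the angular
Riemann measure), so limited-range scans are simply missing-data FBP.

Iterative methods: SIRT (row/column-balanced Landweber, optional relaxation
ω < 2), SART (sequential single-angle blocks), CGLS (no nonnegativity
variant, matching the benchmark's algorithm set); `+` clamps negatives after
each iteration. Divergence (residual > 10× initial) raises. Iteration counts
for the benchmark tables are chosen to minimize RMSE against the ground
truth, evaluated at every iteration; `select_iterations` provides the
general grid-search (geometric ladder + local refinement, ties to the
smallest count, budget-exhaustion flagged) for callers with an opaque
reconstruction callable.

Metrics: RMSE; PSNR with peak = max(ground truth) (convention-sensitive,
hence documented) capped at 300 dB for exact matches; MS-SSIM with the
standard 11-tap Gaussian window (σ=1.5), 5 scales and the published scale
weights, on unnormalized images (both operands share the attenuation scale,
data range 1) — small images use as many scales as the window permits with
renormalized weights, and negative scale scores clamp to 0 so the result
stays in [0, 1]. Dice scores segment by thresholding at 0.5 (the midpoint of
foam = 1 and empty void = 0; exposed as a flag) and by default restrict both
operands to the support of the radius-class mask, so a false void far from
any true void does not affect either class; `global_dice=True` switches to
comparing the whole segmentation against each class mask. Empty masks yield
an undefined (None) Dice, never 0.

Scenario harness: the four named scenarios (high-dose 1024/180°; noise
1024/180°, I0=250, γ calibrated for 50% absorption; few-projections 128/180°;
limited-range 682/120°) run against a 2560-column detector of width 3
(pixel 3/2560, 4×4 rays per pixel) at full scale; `Scenario.scaled(f)`
shrinks the angle count for desk-scale runs. The reconstruction grid is
cols × cols at detector-pixel size, centered on the axis, so the unit-radius
sample covers two-thirds of the field. In the harness SIRT/SART run with
ω = 1.9: relaxed and plain SIRT converge to the same limit, but the relaxed
iteration reaches the RMSE-optimal iterate in roughly half the sweeps, which
is what bounds benchmark runtime. Default iteration budgets are 50 for CGLS
(Krylov; its optimum sits near iteration 20 at desk scale) and 250 for
SIRT/SART. At the noise-free desk-scale settings the SIRT⁺ RMSE curve is
still descending at 250 iterations; the reported row is then the best
iterate found, flagged by `iterations == budget`.

## Problem sizes and what the tests show

The test suite runs the geometry suite at N=2000 over 20 seeds, the
projection oracle at 10³ rays over a 500-void phantom, and the benchmark
ordering at 512 detector columns / 256 angles / N=10⁴ over 3 seeds — sizes
chosen so the whole suite completes in minutes on one core. The full-scale
study (N=150 000, N_p=10⁶ trial points, 2560×2160 detector) runs through the
identical code path via `foamct benchmark --scale 1.0` but takes hours on one
core; nothing in the desk-scale configuration is special-cased. The
synthetic phantoms exercise every geometric regime of real foams (wall
contact, void-void contact, r_max saturation, both Dice size classes), but
they remain mathematically ideal: no beam hardening, phase effects, optical
blur or detector defects are simulated, so passing tests say nothing about
robustness to those artifacts. Poisson noise is the only modeled
degradation.

## Known limitations

* Cone-beam reconstruction (FDK) is not implemented; cone data can be
  simulated but the benchmark is parallel-beam only.
* `discretize` assumes disjoint voids; expanded (overlapping) phantoms can
  produce undershooting voxel values at overlaps.
* MS-SSIM on images narrower than 176 pixels silently uses fewer scales.
* The infiltration interval distribution, growth law and velocity law are
  package defaults, not values prescribed by the underlying study.
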