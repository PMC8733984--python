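"""Analytic projection simulation for foam phantoms.

Projections are computed ray-by-ray in the continuous domain — no voxel
grid is ever involved, which avoids the *inverse crime* of sharing a
discretized forward model between simulation and reconstruction.  The line
integral of ray ``i`` is the chord through the unit cylinder minus the
weighted chords through every void,

    P_i = L_i − Σ_j l(i, j) · (1 − c_j),

where ``L_i = 2 sqrt(r_C² − dz_i²)`` (``dz_i`` = distance from the ray to
the rotation axis; oblique rays divide the horizontal chord by the cosine
of their inclination) and ``l(i, j) = 2 sqrt(r_j² − dv(i, j)²)`` with
``dv(i, j)`` the distance from the void center to the ray, obtained by
projecting the center onto the ray direction.

Conventions (bit-exact, reconstruction depends on them):

* Projection angle θ rotates the *sample* counter-clockwise about +z;
  angles are equally spaced on ``[0, range)``, endpoint excluded.
* All computation happens in the sample frame, where the detector u-axis is
  ``û(θ) = (cos θ, −sin θ, 0)``, the ray direction (parallel beam) is
  ``(sin θ, cos θ, 0)`` and the v-axis is ``+z``.
* The detector plane contains the rotation axis (parallel) with its center
  on it; column ``c`` has ``u = (c − (cols−1)/2)·pixel_width``, row ``r``
  has ``v = ((rows−1)/2 − r)·pixel_height`` (row 0 = top = largest z).
* Supersampling ``s`` places an s×s ray grid at the centers of the s²
  equal subpixels; the pixel value is the mean over its rays.

Poisson noise follows the Beer–Lambert law: ``I = I0 exp(−γ P)``, a Poisson
draw per measurement, then ``P̂ = −ln(Î/I0)/γ``; zero counts are clamped to
one count before the log and the number of clamps is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .phantom import FoamPhantom


# --------------------------------------------------------------------------
# rays and chord primitives
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Ray:
    """A ray: origin plus unit direction (|direction| = 1 within 1e-12)."""

    origin: tuple[float, float, float]
    direction: tuple[float, float, float]

    def __post_init__(self) -> None:
        n = math.sqrt(sum(c * c for c in self.direction))
        if abs(n - 1.0) > 1e-12:
            raise ValueError(f"direction must be a unit vector, |d| = {n}")

    @classmethod
    def through(cls, origin, toward) -> "Ray":
        """Ray from ``origin`` pointing at ``toward`` (direction normalized)."""
        o = np.asarray(origin, float)
        d = np.asarray(toward, float) - o
        d = d / np.linalg.norm(d)
        return cls(tuple(o), tuple(d))


def ray_cylinder_length(ray: Ray, cylinder_radius: float = 1.0) -> float:
    """Exact chord length of the infinite vertical cylinder along a ray.

    The chord of the ray's horizontal projection, ``2 sqrt(r_C² − a²)``
    with ``a`` the 2D distance from the axis, divided by the cosine of the
    ray's inclination to the horizontal plane.  A perfectly vertical ray
    inside the cylinder has an infinite chord.
    """
    ox, oy, _ = ray.origin
    dx, dy, _ = ray.direction
    dxy = math.hypot(dx, dy)
    if dxy < 1e-300:
        return math.inf if math.hypot(ox, oy) < cylinder_radius else 0.0
    a = abs(ox * dy - oy * dx) / dxy
    if a >= cylinder_radius:
        return 0.0
    return 2.0 * math.sqrt(cylinder_radius**2 - a * a) / dxy


def ray_sphere_length(ray: Ray, center, radius: float) -> float:
    """Chord length of a sphere along a ray: ``2 sqrt(r² − dv²)``.

    ``dv`` is found by projecting the center onto the ray direction; a
    grazing ray (``dv ≥ r``) returns 0.
    """
    w = np.asarray(center, float) - np.asarray(ray.origin, float)
    d = np.asarray(ray.direction, float)
    t = float(w @ d)
    dv2 = float(w @ w) - t * t
    if dv2 >= radius * radius:
        return 0.0
    return 2.0 * math.sqrt(radius * radius - dv2)


def project_ray(ray: Ray, phantom: FoamPhantom) -> float:
    """Exact line integral of the phantom's attenuation along one ray."""
    p = ray_cylinder_length(ray, phantom.cylinder_radius)
    if phantom.n_voids == 0 or p == 0.0:
        return p
    o = np.asarray(ray.origin, float)
    d = np.asarray(ray.direction, float)
    w = phantom.centers - o
    t = w @ d
    dv2 = np.einsum("ij,ij->i", w, w) - t * t
    r2 = phantom.radii**2
    hit = dv2 < r2
    if hit.any():
        chords = 2.0 * np.sqrt(r2[hit] - dv2[hit])
        p -= float(chords @ (1.0 - phantom.attenuations[hit]))
    return p


# --------------------------------------------------------------------------
# geometries
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ParallelGeometry:
    """Parallel-beam circular geometry (angles in degrees)."""

    n_angles: int
    angular_range: float = 180.0
    det_rows: int = 1
    det_cols: int = 256
    pixel_width: float = 3.0 / 256
    pixel_height: float | None = None
    supersampling: int = 1
    #: constant added to every projection angle (used by the dynamic scan
    #: driver to project single angles); 0 for ordinary circular scans.
    angle_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if self.supersampling < 1:
            raise ValueError("supersampling must be >= 1")
        if self.pixel_width <= 0:
            raise ValueError("pixel_width must be > 0")
        if self.pixel_height is None:
            object.__setattr__(self, "pixel_height", self.pixel_width)
        if self.pixel_height <= 0:
            raise ValueError("pixel_height must be > 0")

    @property
    def angles_deg(self) -> np.ndarray:
        """Equally spaced on [0, angular_range), endpoint excluded."""
        return self.angle_offset + np.arange(self.n_angles) * (
            self.angular_range / self.n_angles
        )

    def _su_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Supersampled (u, v) ray coordinates: u ascending, v descending."""
        s = self.supersampling
        nu, nv = self.det_cols * s, self.det_rows * s
        u = (np.arange(nu) - (nu - 1) / 2.0) * (self.pixel_width / s)
        v = ((nv - 1) / 2.0 - np.arange(nv)) * (self.pixel_height / s)
        return u, v


@dataclass(frozen=True)
class ConeGeometry(ParallelGeometry):
    """Cone-beam geometry: point source at distance ``sod`` from the
    rotation axis, flat detector at distance ``odd`` behind it.  The
    magnification ``(sod + odd)/sod`` emerges geometrically."""

    sod: float = 10.0
    odd: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.sod <= 1.0:
            raise ValueError("sod must be > 1 (source outside the sample)")
        if self.odd < 0.0:
            raise ValueError("odd must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Beer–Lambert Poisson noise: flux ``I0`` photons/ray, absorption
    scale ``gamma``, and the RNG seed."""

    flux: float
    gamma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flux <= 0:
            raise ValueError("flux must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class ProjectionStack:
    """Simulated measurements: ``values`` is (n_angles, rows, cols) in
    line-integral units; ``noise`` is None for a clean stack."""

    values: np.ndarray
    geometry: ParallelGeometry
    angles_deg: np.ndarray
    noise: NoiseModel | None = None
    n_clamped: int = 0
    provenance: dict = field(default_factory=dict)

    @property
    def is_clean(self) -> bool:
        return self.noise is None

    def sinogram(self, row: int | None = None) -> np.ndarray:
        """(n_angles, cols) view of one detector row (default: central)."""
        if row is None:
            row = self.geometry.det_rows // 2
        return self.values[:, row, :]


# --------------------------------------------------------------------------
# parallel beam
# --------------------------------------------------------------------------


def _downsample(su: np.ndarray, s: int) -> np.ndarray:
    if s == 1:
        return su
    nv, nu = su.shape
    return su.reshape(nv // s, s, nu // s, s).mean(axis=(1, 3))


def project_parallel(phantom: FoamPhantom, geometry: ParallelGeometry) -> ProjectionStack:
    """Analytic parallel-beam projection stack.

    Per angle, the detector-plane coordinates of every void center are
    precomputed once (all rays share one direction); each void then touches
    only the rays within its projected disk, so work scales with the
    projected void area rather than the full detector.
    """
    if isinstance(geometry, ConeGeometry):
        raise TypeError("use project_cone for cone-beam geometries")
    u, v = geometry._su_grid()
    s = geometry.supersampling
    du = geometry.pixel_width / s
    dv = geometry.pixel_height / s
    nu, nv = len(u), len(v)

    # cylinder chord depends on u only
    l_cyl = np.zeros(nu)
    inside = np.abs(u) < phantom.cylinder_radius
    l_cyl[inside] = 2.0 * np.sqrt(phantom.cylinder_radius**2 - u[inside] ** 2)

    # v_j = z_j for every angle: cull voids that never reach the detector
    z = phantom.voids[:, 2]
    r = phantom.radii
    act = np.nonzero((z + r > v[-1] - dv) & (z - r < v[0] + dv))[0]
    cx, cy, cz = (phantom.voids[act, k] for k in range(3))
    cr = r[act]
    cc = phantom.attenuations[act]

    theta = np.deg2rad(geometry.angles_deg)
    out = np.empty((geometry.n_angles, geometry.det_rows, geometry.det_cols))
    for a, th in enumerate(theta):
        su = np.broadcast_to(l_cyl, (nv, nu)).copy()
        uj = cx * math.cos(th) - cy * math.sin(th)
        for j in range(len(act)):
            _subtract_void_patch(
                su, u, v, du, dv, uj[j], cz[j], cr[j], 1.0 - cc[j]
            )
        out[a] = _downsample(su, s)
    return ProjectionStack(out, geometry, geometry.angles_deg.copy())


def _subtract_void_patch(su, u, v, du, dv, uj, vj, rj, weight) -> None:
    """Subtract ``weight * chord`` of one sphere on its detector patch.

    ``u`` ascends with column index, ``v`` descends with row index.
    """
    nu, nv = len(u), len(v)
    c0 = max(0, math.ceil((uj - rj - u[0]) / du))
    c1 = min(nu - 1, math.floor((uj + rj - u[0]) / du))
    r0 = max(0, math.ceil((v[0] - (vj + rj)) / dv))
    r1 = min(nv - 1, math.floor((v[0] - (vj - rj)) / dv))
    if c0 > c1 or r0 > r1:
        return
    dv2 = (u[c0 : c1 + 1] - uj) ** 2 + (v[r0 : r1 + 1, None] - vj) ** 2
    np.subtract(
        su[r0 : r1 + 1, c0 : c1 + 1],
        weight * 2.0 * np.sqrt(np.maximum(rj * rj - dv2, 0.0)),
        out=su[r0 : r1 + 1, c0 : c1 + 1],
    )


# --------------------------------------------------------------------------
# cone beam
# --------------------------------------------------------------------------


def project_cone(phantom: FoamPhantom, geometry: ConeGeometry) -> ProjectionStack:
    """Analytic cone-beam projection stack.

    Rays run from the point source through each supersampled detector
    position; the same chord composition applies with the oblique-ray
    cylinder formula.  Work per void is restricted to the patch of rays
    inside its (magnified) projected disk.
    """
    u, v = geometry._su_grid()
    s = geometry.supersampling
    du, dvv = geometry.pixel_width / s, geometry.pixel_height / s
    nu, nv = len(u), len(v)
    sod, odd = geometry.sod, geometry.odd
    sdd = sod + odd

    theta = np.deg2rad(geometry.angles_deg)
    out = np.empty((geometry.n_angles, geometry.det_rows, geometry.det_cols))
    centers = phantom.centers
    radii = phantom.radii
    att = phantom.attenuations

    for a, th in enumerate(theta):
        u_axis = np.array([math.cos(th), -math.sin(th), 0.0])
        beam = np.array([math.sin(th), math.cos(th), 0.0])
        src = -sod * beam
        # detector point of su-ray (iv, iu): src + sdd*beam + u*u_axis + v*ez
        su = np.empty((nv, nu))
        # cylinder chord, row by row (rows share nothing but memory limits)
        for iv in range(nv):
            d = (
                sdd * beam[None, :]
                + u[:, None] * u_axis[None, :]
                + np.array([0.0, 0.0, 1.0])[None, :] * v[iv]
            )
            norm = np.linalg.norm(d, axis=1)
            dxy = np.hypot(d[:, 0], d[:, 1])
            # distance from z-axis to the ray's horizontal projection
            aa = np.abs(src[0] * d[:, 1] - src[1] * d[:, 0]) / dxy
            chord = np.zeros(nu)
            hit = aa < phantom.cylinder_radius
            chord[hit] = (
                2.0
                * np.sqrt(phantom.cylinder_radius**2 - aa[hit] ** 2)
                * norm[hit]
                / dxy[hit]
            )
            su[iv] = chord

        for j in range(phantom.n_voids):
            w = centers[j] - src
            depth = float(w @ beam)
            rj = radii[j]
            if depth - rj <= 0:
                continue  # behind or enclosing the source: cannot happen for valid phantoms
            mag = sdd / depth
            ujc = float(w @ u_axis) * mag
            vjc = float(w[2]) * mag
            margin = rj * sdd / (depth - rj) + max(du, dvv)
            c0 = max(0, math.ceil((ujc - margin - u[0]) / du))
            c1 = min(nu - 1, math.floor((ujc + margin - u[0]) / du))
            r0 = max(0, math.ceil((v[0] - (vjc + margin)) / dvv))
            r1 = min(nv - 1, math.floor((v[0] - (vjc - margin)) / dvv))
            if c0 > c1 or r0 > r1:
                continue
            d = (
                sdd * beam[None, None, :]
                + u[None, c0 : c1 + 1, None] * u_axis[None, None, :]
                + v[r0 : r1 + 1, None, None] * np.array([0.0, 0.0, 1.0])[None, None, :]
            )
            d = d / np.linalg.norm(d, axis=2, keepdims=True)
            # re-origin each ray where it crosses the rotation-axis plane:
            # subtracting |w|² ~ sod² quantities would lose ~sod²·eps of
            # absolute precision in dv², which matters for large sod
            t0 = sod / (d @ beam)
            w_local = (centers[j] - src)[None, None, :] - t0[..., None] * d
            t = np.einsum("abk,abk->ab", w_local, d)
            dv2 = np.einsum("abk,abk->ab", w_local, w_local) - t * t
            chord = 2.0 * np.sqrt(np.maximum(rj * rj - dv2, 0.0))
            su[r0 : r1 + 1, c0 : c1 + 1] -= (1.0 - att[j]) * chord
        out[a] = _downsample(su, s)
    return ProjectionStack(out, geometry, geometry.angles_deg.copy())


def project(phantom: FoamPhantom, geometry: ParallelGeometry) -> ProjectionStack:
    """Dispatch to the parallel- or cone-beam projector by geometry type."""
    if isinstance(geometry, ConeGeometry):
        return project_cone(phantom, geometry)
    return project_parallel(phantom, geometry)


# --------------------------------------------------------------------------
# noise
# --------------------------------------------------------------------------


def apply_noise(stack: ProjectionStack, model: NoiseModel) -> ProjectionStack:
    """Poisson detector noise on a clean stack (seeded, reproducible).

    ``I = I0 exp(−γ P)``; ``Î ~ Poisson(I)``; ``P̂ = −ln(Î/I0)/γ``.  Zero
    counts are clamped to one count before the log; the clamp count is
    reported on the returned stack.
    """
    if not stack.is_clean:
        raise ValueError("apply_noise expects a clean stack")
    if model.gamma <= 0:
        raise ValueError("gamma must be > 0 to apply noise")
    rng = np.random.default_rng(model.seed)
    expected = model.flux * np.exp(-model.gamma * stack.values)
    counts = rng.poisson(expected).astype(np.float64)
    n_clamped = int(np.count_nonzero(counts == 0))
    np.maximum(counts, 1.0, out=counts)
    noisy = -np.log(counts / model.flux) / model.gamma
    return replace(
        stack, values=noisy, noise=model, n_clamped=n_clamped,
        angles_deg=stack.angles_deg.copy(),
    )


def calibrate_gamma(
    stack: ProjectionStack,
    target_absorbed_fraction: float,
    flux: float | None = None,
    *,
    all_rays: bool = False,
) -> float:
    """γ such that the sample absorbs the target fraction of photons.

    Solves ``mean(1 − exp(−γ P_i)) = target`` over the rays of the *clean*
    stack, by monotone bracketing to 1e−10 relative accuracy.  By default
    the mean runs over sample-intersecting rays (``P_i > 0``), reading "the
    sample absorbed" as photons that traverse the sample; ``all_rays=True``
    averages over the whole detector instead.  The fraction is independent
    of the flux, which is accepted for interface symmetry only.
    """
    del flux
    if not (0.0 < target_absorbed_fraction < 1.0):
        raise ValueError("target_absorbed_fraction must be in (0, 1)")
    p = stack.values[stack.values > 0] if not all_rays else stack.values.ravel()
    if p.size == 0 or not np.any(p > 0):
        raise ValueError("no absorbing rays: target unreachable")

    def f(g: float) -> float:
        return float(np.mean(1.0 - np.exp(-g * p))) - target_absorbed_fraction

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("target unreachable")
    return float(brentq(f, lo, hi, rtol=1e-10, maxiter=200))
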