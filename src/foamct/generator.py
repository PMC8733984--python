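"""Seeded foam-phantom generation by greedy trial-point sphere packing.

The generator keeps a pool of ``N_p`` random *trial points* — valid void
positions (strictly inside the cylinder, strictly outside every void,
``|z| ≤ z_max``).  Each point carries its *feasible radius*: the largest
sphere that fits there,

    r(p) = min( 1 − sqrt(x² + y²),  min_j [ d(p, p_j) − r_j ],  r_max ).

One iteration places a void at the trial point with the largest feasible
radius (ties broken uniformly at random), removes trial points swallowed by
the new void, shrinks the feasible radii of the survivors, and refills the
pool to ``N_p`` by rejection sampling.  Because each void is made as large
as possible, every void either reaches ``r_max``, touches the cylinder
wall, or touches a neighbor — and void sizes naturally shrink as the foam
fills up.

The whole process is a deterministic function of
``(N, N_p, r_max, z_max, seed)``.  Randomness comes from a single
``numpy.random.Generator`` (PCG64); the draw order is fixed as: initial
pool fill (position draws), then per iteration a tie-break draw only when
two or more maxima tie (within ``TIE_TOL``), followed by the refill draws.
Self-reproducibility is promised; bit-compatibility across NumPy versions
is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .phantom import FoamPhantom, Void

#: Absolute tolerance when detecting ties among maximal feasible radii.
TIE_TOL = 1e-12

#: Consecutive rejected position draws before sampling gives up — this
#: distinguishes a nearly jammed phantom from an infinite loop.
REJECTION_CAP = 10**6


class PoolExhaustedError(RuntimeError):
    """Raised when valid trial positions cannot be found (phantom jammed)."""


@njit(cache=True, fastmath=True)
def _grid_filter_contained(pts, ok, centers, radii, x0, y0, z0, inv, nx, ny, nz,
                           cell_start, cell_items, n_recent):  # pragma: no cover
    """Clear ``ok`` for points strictly inside any void.

    Voids are split into a CSR cell grid (all but the most recent) and a
    brute-force tail of the last ``n_recent`` entries.
    """
    n = centers.shape[0]
    for k in range(pts.shape[0]):
        if not ok[k]:
            continue
        px, py, pz = pts[k, 0], pts[k, 1], pts[k, 2]
        inside = False
        for j in range(n - n_recent, n):
            dx = px - centers[j, 0]
            dy = py - centers[j, 1]
            dz = pz - centers[j, 2]
            if dx * dx + dy * dy + dz * dz < radii[j] * radii[j]:
                inside = True
                break
        if not inside:
            ix = int((px - x0) * inv)
            iy = int((py - y0) * inv)
            iz = int((pz - z0) * inv)
            for cx in range(max(0, ix - 1), min(nx, ix + 2)):
                for cy in range(max(0, iy - 1), min(ny, iy + 2)):
                    for cz in range(max(0, iz - 1), min(nz, iz + 2)):
                        c = (cx * ny + cy) * nz + cz
                        for t in range(cell_start[c], cell_start[c + 1]):
                            j = cell_items[t]
                            dx = px - centers[j, 0]
                            dy = py - centers[j, 1]
                            dz = pz - centers[j, 2]
                            if dx * dx + dy * dy + dz * dz < radii[j] * radii[j]:
                                inside = True
                                break
                        if inside:
                            break
                    if inside:
                        break
                if inside:
                    break
        if inside:
            ok[k] = False


@njit(cache=True, fastmath=True)
def _grid_min_margin(pts, caps, centers, radii, x0, y0, z0, inv, nx, ny, nz,
                     cell_start, cell_items, n_recent):  # pragma: no cover
    """For each point: min(cap, min_j d(p, p_j) − r_j), exact for caps ≤ r_max
    because the grid cell size is 2·r_max."""
    n = centers.shape[0]
    out = np.empty(pts.shape[0])
    for k in range(pts.shape[0]):
        px, py, pz = pts[k, 0], pts[k, 1], pts[k, 2]
        best = caps[k]
        for j in range(n - n_recent, n):
            dx = px - centers[j, 0]
            dy = py - centers[j, 1]
            dz = pz - centers[j, 2]
            m = np.sqrt(dx * dx + dy * dy + dz * dz) - radii[j]
            if m < best:
                best = m
        ix = int((px - x0) * inv)
        iy = int((py - y0) * inv)
        iz = int((pz - z0) * inv)
        for cx in range(max(0, ix - 1), min(nx, ix + 2)):
            for cy in range(max(0, iy - 1), min(ny, iy + 2)):
                for cz in range(max(0, iz - 1), min(nz, iz + 2)):
                    c = (cx * ny + cy) * nz + cz
                    for t in range(cell_start[c], cell_start[c + 1]):
                        j = cell_items[t]
                        dx = px - centers[j, 0]
                        dy = py - centers[j, 1]
                        dz = pz - centers[j, 2]
                        m = np.sqrt(dx * dx + dy * dy + dz * dz) - radii[j]
                        if m < best:
                            best = m
        out[k] = best
    return out


class _VoidIndex:
    """Spatial acceleration for inside-a-void and feasible-radius queries.

    Every feasible radius is capped at ``r_max``, so a void ``j`` can only
    tighten the bound at a point when ``d(p, p_j) − r_j < r_max``, i.e.
    ``d < r_max + r_j ≤ 2 r_max`` — which confines both validity checks and
    feasible-radius minima to the 27 grid cells (cell size ``2 r_max``)
    around a query point.  Voids placed since the last grid rebuild are
    scanned brute-force; the grid is rebuilt every ``REBUILD`` insertions.
    Results are exactly those of the brute-force scan over all voids.
    """

    REBUILD = 64

    def __init__(self, r_max: float, z_max: float, capacity: int) -> None:
        self.cell = 2.0 * r_max
        self.inv = 1.0 / self.cell
        self.x0 = self.y0 = -1.0 - self.cell
        self.z0 = -z_max - self.cell
        self.nx = self.ny = int(np.ceil((2.0 + 2 * self.cell) * self.inv)) + 1
        self.nz = int(np.ceil((2 * z_max + 2 * self.cell) * self.inv)) + 1
        self.centers = np.empty((capacity, 3))
        self.radii = np.empty(capacity)
        self.n = 0
        self.built = 0
        ncells = self.nx * self.ny * self.nz
        self.cell_start = np.zeros(ncells + 1, dtype=np.int64)
        self.cell_items = np.empty(0, dtype=np.int64)

    def add(self, center, radius: float) -> None:
        if self.n == len(self.radii):  # grow if used beyond planned capacity
            self.centers = np.vstack([self.centers, np.empty_like(self.centers)])
            self.radii = np.concatenate([self.radii, np.empty_like(self.radii)])
        self.centers[self.n] = center
        self.radii[self.n] = radius
        self.n += 1
        if self.n - self.built >= self.REBUILD:
            self._rebuild()

    def _rebuild(self) -> None:
        c = self.centers[: self.n]
        ix = ((c[:, 0] - self.x0) * self.inv).astype(np.int64)
        iy = ((c[:, 1] - self.y0) * self.inv).astype(np.int64)
        iz = ((c[:, 2] - self.z0) * self.inv).astype(np.int64)
        keys = (ix * self.ny + iy) * self.nz + iz
        order = np.argsort(keys, kind="stable")
        counts = np.bincount(keys, minlength=len(self.cell_start) - 1)
        self.cell_start = np.concatenate(
            [[0], np.cumsum(counts)]
        ).astype(np.int64)
        self.cell_items = order
        self.built = self.n

    def _args(self):
        return (
            self.centers[: self.n], self.radii[: self.n],
            self.x0, self.y0, self.z0, self.inv, self.nx, self.ny, self.nz,
            self.cell_start, self.cell_items, self.n - self.built,
        )

    def filter_contained(self, pts: np.ndarray, ok: np.ndarray) -> None:
        """In-place: clear ``ok`` where the point lies strictly inside a void."""
        if self.n:
            _grid_filter_contained(pts, ok, *self._args())

    def min_margin(self, pts: np.ndarray, caps: np.ndarray) -> np.ndarray:
        """Per point: min(cap, min_j d(p, p_j) − r_j); exact for caps ≤ r_max."""
        if self.n == 0:
            return np.asarray(caps, float).copy()
        return _grid_min_margin(
            np.atleast_2d(pts), np.asarray(caps, float), *self._args()
        )


def max_feasible_radius(
    point,
    centers: np.ndarray,
    radii: np.ndarray,
    r_max: float,
    *,
    check: bool = True,
) -> float:
    """Largest void radius admissible at ``point`` given existing voids.

    ``min(1 − sqrt(x²+y²), min_j [d(point, p_j) − r_j], r_max)``; with no
    voids the middle term is +inf.  A negative result means the point is
    invalid (inside the cylinder wall margin or inside a void) and is
    flagged, not clamped.
    """
    point = np.asarray(point, dtype=np.float64)
    r = 1.0 - float(np.hypot(point[0], point[1]))
    if len(radii):
        d = np.linalg.norm(np.asarray(centers) - point, axis=1)
        r = min(r, float(np.min(d - radii)))
    r = min(r, float(r_max))
    if check and r < 0:
        raise ValueError(f"point {point.tolist()} admits negative radius {r}")
    return r


def _sample_batch(rng: np.random.Generator, n: int, z_max: float) -> np.ndarray:
    """Draw ``n`` candidate points uniform on the bounding box of the slab."""
    pts = np.empty((n, 3))
    pts[:, 0] = rng.uniform(-1.0, 1.0, n)
    pts[:, 1] = rng.uniform(-1.0, 1.0, n)
    pts[:, 2] = rng.uniform(-z_max, z_max, n) if z_max > 0 else 0.0
    return pts


def sample_valid_points(
    rng: np.random.Generator,
    n: int,
    centers: np.ndarray,
    radii: np.ndarray,
    z_max: float,
    rejection_cap: int = REJECTION_CAP,
    index: _VoidIndex | None = None,
) -> np.ndarray:
    """``n`` points uniform on the valid region, by rejection sampling.

    Uniform proposals on the box ``[-1,1]² × [-z_max, z_max]`` are accepted
    when strictly inside the cylinder and strictly outside every void.
    ``index`` (when supplied) answers the inside-a-void test from its
    spatial hash — the accept/reject decisions, and hence the RNG stream,
    are identical either way.  Raises :class:`PoolExhaustedError` after
    ``rejection_cap`` consecutive rejections.
    """
    out = np.empty((n, 3))
    got = 0
    consecutive = 0
    centers = np.asarray(centers, dtype=np.float64).reshape(-1, 3)
    radii = np.asarray(radii, dtype=np.float64)
    have_voids = len(radii) > 0
    while got < n:
        batch = max(64, 2 * (n - got))
        cand = _sample_batch(rng, batch, z_max)
        ok = cand[:, 0] ** 2 + cand[:, 1] ** 2 < 1.0
        if have_voids:
            if index is not None:
                index.filter_contained(cand, ok)
            else:
                sub = cand[ok]
                if len(sub):
                    d2 = np.sum(
                        (sub[:, None, :] - centers[None, :, :]) ** 2, axis=2
                    )
                    ok[ok] = ~np.any(d2 < radii[None, :] ** 2, axis=1)
        idx = np.nonzero(ok)[0]
        take = idx[: n - got]
        out[got : got + len(take)] = cand[take]
        got += len(take)
        if len(idx) == 0:
            consecutive += batch
            if consecutive >= rejection_cap:
                raise PoolExhaustedError(
                    f"no valid trial position found in {consecutive} draws; "
                    "the phantom is (nearly) jammed"
                )
        else:
            consecutive = 0
    return out


def sample_valid_point(
    rng: np.random.Generator,
    centers: np.ndarray,
    radii: np.ndarray,
    z_max: float,
    rejection_cap: int = REJECTION_CAP,
) -> np.ndarray:
    """Single-point convenience wrapper around :func:`sample_valid_points`."""
    return sample_valid_points(rng, 1, centers, radii, z_max, rejection_cap)[0]


@dataclass
class TrialPool:
    """The ``N_p`` candidate positions with their current feasible radii.

    Retrieve-max is a vectorized scan over the radius array; deletes and
    radius updates are in-place array edits.  The arrays are authoritative:
    ``self.radii[k]`` always equals the from-scratch feasible radius of
    ``self.points[k]`` (the generator maintains this incrementally; tests
    check it against brute-force recomputation).
    """

    points: np.ndarray  # (N_p, 3)
    radii: np.ndarray  # (N_p,)

    @property
    def size(self) -> int:
        return len(self.radii)

    @classmethod
    def initial(
        cls,
        rng: np.random.Generator,
        n_points: int,
        r_max: float,
        z_max: float,
    ) -> "TrialPool":
        """Initial fill of an empty phantom: ``N_p`` position draws."""
        pts = sample_valid_points(rng, n_points, np.empty((0, 3)), np.empty(0), z_max)
        radii = np.minimum(1.0 - np.hypot(pts[:, 0], pts[:, 1]), r_max)
        return cls(pts, radii)

    def retrieve_max(self, rng: np.random.Generator) -> int:
        """Index of the point with the largest feasible radius.

        Ties within :data:`TIE_TOL` are broken by one uniform draw; the
        draw is consumed only when two or more points tie.
        """
        if self.size == 0:
            raise PoolExhaustedError("trial pool is empty")
        best = float(np.max(self.radii))
        tied = np.nonzero(self.radii >= best - TIE_TOL)[0]
        if len(tied) > 1:
            return int(tied[rng.integers(len(tied))])
        return int(tied[0])

    def delete(self, index: int) -> None:
        self.points = np.delete(self.points, index, axis=0)
        self.radii = np.delete(self.radii, index)


def place_best_void(
    pool: TrialPool, r_max: float, rng: np.random.Generator
) -> Void:
    """Place a void at the best trial point and remove that point.

    The void's radius is the point's feasible radius (already capped at
    ``r_max`` by construction).
    """
    k = pool.retrieve_max(rng)
    x, y, z = pool.points[k]
    r = float(pool.radii[k])
    pool.delete(k)
    return Void(float(x), float(y), float(z), r, 0.0)


def update_pool(
    pool: TrialPool,
    new_void: Void,
    centers: np.ndarray,
    radii: np.ndarray,
    r_max: float,
    z_max: float,
    rng: np.random.Generator,
    index: _VoidIndex | None = None,
) -> TrialPool:
    """Maintain the pool after a placement.

    (a) delete points strictly inside the new void; (b) shrink surviving
    feasible radii to ``min(previous, d − r_new)``; (c) refill to the
    previous size with fresh valid points (checked against *all* voids,
    the new one included).  ``index`` must already contain the new void
    when supplied.
    """
    target = pool.size + 1  # the chosen point was already removed
    p_new = np.array([new_void.x, new_void.y, new_void.z])
    d = np.linalg.norm(pool.points - p_new, axis=1)
    keep = d >= new_void.r  # strictly inside is deleted; surface survives
    pool.points = pool.points[keep]
    pool.radii = np.minimum(pool.radii[keep], d[keep] - new_void.r)

    n_new = target - pool.size
    if n_new > 0:
        fresh = sample_valid_points(rng, n_new, centers, radii, z_max, index=index)
        fr = np.minimum(1.0 - np.hypot(fresh[:, 0], fresh[:, 1]), r_max)
        if index is not None:
            fr = index.min_margin(fresh, fr)
        elif len(radii):
            d2 = np.sum(
                (fresh[:, None, :] - np.asarray(centers)[None, :, :]) ** 2, axis=2
            )
            fr = np.minimum(fr, np.min(np.sqrt(d2) - radii[None, :], axis=1))
        pool.points = np.vstack([pool.points, fresh])
        pool.radii = np.concatenate([pool.radii, fr])
    return pool


def generate_foam(
    n_voids: int,
    n_trial_points: int = 10**4,
    max_radius: float = 0.2,
    max_height: float = 1.5,
    seed: int = 0,
) -> FoamPhantom:
    """Generate a foam phantom with exactly ``n_voids`` voids.

    Deterministic in ``(n_voids, n_trial_points, max_radius, max_height,
    seed)``.  Raises :class:`PoolExhaustedError` if the phantom jams before
    ``n_voids`` placements.
    """
    if n_voids < 1:
        raise ValueError("n_voids must be >= 1")
    if n_trial_points < 1:
        raise ValueError("n_trial_points must be >= 1")
    if not (0.0 < max_radius <= 1.0):
        raise ValueError("max_radius must be in (0, 1]")
    if max_height < 0:
        raise ValueError("max_height must be >= 0")

    rng = np.random.default_rng(seed)
    pool = TrialPool.initial(rng, n_trial_points, max_radius, max_height)
    index = _VoidIndex(max_radius, max_height, n_voids)

    table = np.empty((n_voids, 5))
    centers = table[:, :3]
    radii_col = table[:, 3]
    for i in range(n_voids):
        void = place_best_void(pool, max_radius, rng)
        table[i] = (void.x, void.y, void.z, void.r, void.c)
        index.add((void.x, void.y, void.z), void.r)
        update_pool(
            pool, void, centers[: i + 1], radii_col[: i + 1], max_radius,
            max_height, rng, index=index,
        )

    return FoamPhantom(
        table.copy(),
        n_trial_points=n_trial_points,
        max_radius=max_radius,
        max_height=max_height,
        seed=seed,
    )


def touching_report(phantom: FoamPhantom, tolerance: float = 1e-7) -> np.ndarray:
    """Boolean mask: void i is maximal (r = r_max, touches the cylinder, or
    touches another void) within ``tolerance``.

    The greedy generator makes every void as large as its tightest
    constraint allows, so this should hold for all voids of any generated
    phantom.
    """
    v = phantom.voids
    r = phantom.radii
    ok = np.abs(r - phantom.max_radius) <= tolerance
    ok |= np.abs(np.hypot(v[:, 0], v[:, 1]) + r - 1.0) <= tolerance

    todo = np.nonzero(~ok)[0]
    if len(todo):
        tree = phantom._kdtree()
        pairs = tree.query_pairs(2.0 * float(r.max()) + tolerance, output_type="ndarray")
        if len(pairs):
            d = np.linalg.norm(v[pairs[:, 0], :3] - v[pairs[:, 1], :3], axis=1)
            touch = np.abs(d - (r[pairs[:, 0]] + r[pairs[:, 1]])) <= tolerance
            for i, j in pairs[touch]:
                ok[i] = True
                ok[j] = True
    return ok
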