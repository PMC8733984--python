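"""Time-evolving (4D) foam phantoms.

Three evolution models act on a static base phantom:

* **moving** — every void translates along z with a common piecewise-
  constant velocity that is redrawn at random per time interval; the
  displacement is the exact integral of the velocity, zero at t = 0.
  Height validation is deliberately disabled for evolved phantoms: the
  sample streams through a fixed scan region.
* **expanding** — every radius is multiplied by a non-decreasing scale
  ``g(t)`` with ``g(0) = 1``.  Growth may create overlaps; those are
  reported by ``validate_phantom``, never forbidden or rescaled.
* **infiltration** — voids fill with a new material over time.  Voids whose
  center height lies in a band around a start height fill at t = 0; an
  unfilled void whose surface gap to a filled void is at most ε fills one
  random interval after its earliest-filling neighbor.  Unreachable voids
  either never fill or fill at an optional global fallback time.

A dynamic scan is simulated by assigning each projection a time interval
(default: projection k occupies ``[k, k+1)/n_angles`` of the experiment
duration, in acquisition order) and averaging projections of the evolved
phantom at equally spaced times inside the interval (time supersampling;
one substep uses the interval midpoint).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from .phantom import FoamPhantom
from .projection import (
    ConeGeometry,
    ParallelGeometry,
    ProjectionStack,
    project_cone,
    project_parallel,
)


@dataclass
class MovingModel:
    """Common z-motion with per-interval random velocity.

    ``times`` are the n+1 edges of n intervals; ``velocities`` holds one
    z-velocity (unit radii per unit time) per interval.
    """

    times: np.ndarray
    velocities: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.velocities = np.asarray(self.velocities, float)
        if len(self.times) != len(self.velocities) + 1:
            raise ValueError("need len(times) == len(velocities) + 1")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @classmethod
    def random(
        cls,
        duration: float,
        n_intervals: int,
        velocity_scale: float,
        seed: int = 0,
    ) -> "MovingModel":
        """Velocities drawn i.i.d. N(0, scale²), intervals of equal length."""
        rng = np.random.default_rng(seed)
        times = np.linspace(0.0, duration, n_intervals + 1)
        return cls(times, rng.normal(0.0, velocity_scale, n_intervals), seed)

    @property
    def t_min(self) -> float:
        return float(self.times[0])

    @property
    def t_max(self) -> float:
        return float(self.times[-1])

    def displacement(self, t: float) -> float:
        """Exact integral of the piecewise-constant velocity from t=0."""
        self._check_t(t)
        dt = np.diff(self.times)
        full = np.clip(t - self.times[:-1], 0.0, dt)
        return float(self.velocities @ full)

    def _check_t(self, t: float) -> None:
        if not (self.t_min <= t <= self.t_max):
            raise ValueError(f"t={t} outside model time grid "
                             f"[{self.t_min}, {self.t_max}]")


@dataclass
class ExpandingModel:
    """Void growth by a radius scale g(t): g(0)=1, non-decreasing."""

    growth: Callable[[float], float] | None = None
    rate: float = 0.5
    duration: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.growth is None:
            rate = self.rate
            self.growth = lambda t: 1.0 + rate * t
        if abs(self.growth(0.0) - 1.0) > 1e-12:
            raise ValueError("growth scale must satisfy g(0) = 1")

    t_min: float = field(default=0.0, init=False)

    @property
    def t_max(self) -> float:
        return self.duration

    def _check_t(self, t: float) -> None:
        if not (0.0 <= t <= self.duration):
            raise ValueError(f"t={t} outside model time grid [0, {self.duration}]")


@dataclass
class InfiltrationModel:
    """Neighbor-to-neighbor material infiltration.

    ``start_height``/``band_halfwidth`` select the seed voids (center z in
    ``|z − z0| ≤ h``), ``fill_attenuation`` is the infiltrating material,
    ``epsilon`` the surface-gap adjacency distance, and intervals are drawn
    i.i.d. Exponential(rate).  ``fallback_time`` (if set) fills every void
    unreachable through ε-adjacency at that absolute time.
    """

    start_height: float = 0.0
    band_halfwidth: float = 0.1
    fill_attenuation: float = 0.5
    epsilon: float = 0.01
    rate: float = 1.0
    seed: int = 0
    fallback_time: float | None = None
    duration: float = np.inf
    fill_times: np.ndarray | None = None

    t_min: float = field(default=0.0, init=False)

    @property
    def t_max(self) -> float:
        return self.duration

    def _check_t(self, t: float) -> None:
        if not (0.0 <= t <= self.duration):
            raise ValueError(f"t={t} outside model time grid [0, {self.duration}]")

    def schedule_for(self, phantom: FoamPhantom) -> np.ndarray:
        """Fill times for ``phantom``, computed once and cached."""
        if self.fill_times is None or len(self.fill_times) != phantom.n_voids:
            self.fill_times = build_infiltration_schedule(phantom, self)
        return self.fill_times


def adjacency_pairs(phantom: FoamPhantom, epsilon: float) -> np.ndarray:
    """(M, 2) index pairs of voids whose surface gap is ≤ epsilon."""
    if phantom.n_voids < 2:
        return np.empty((0, 2), dtype=np.intp)
    r = phantom.radii
    tree = cKDTree(phantom.centers)
    pairs = tree.query_pairs(2.0 * float(r.max()) + epsilon, output_type="ndarray")
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    d = np.linalg.norm(
        phantom.centers[pairs[:, 0]] - phantom.centers[pairs[:, 1]], axis=1
    )
    gap = d - r[pairs[:, 0]] - r[pairs[:, 1]]
    return pairs[gap <= epsilon]


def build_infiltration_schedule(
    phantom: FoamPhantom,
    model: InfiltrationModel,
    intervals: np.ndarray | None = None,
) -> np.ndarray:
    """Per-void fill times by discrete-event propagation.

    Seed voids (center height within the start band) fill at time 0; every
    other void fills one random interval after the earliest fill among its
    ε-neighbors — a shortest-arrival propagation with one i.i.d. delay per
    void (``intervals`` overrides the Exponential(rate) draws, mainly for
    hand-worked tests).  Unreachable voids get the fallback time, or +inf
    when no fallback is configured.  Deterministic given the model seed.
    """
    n = phantom.n_voids
    seeds = np.abs(phantom.voids[:, 2] - model.start_height) <= model.band_halfwidth
    if not seeds.any():
        raise ValueError("no seed voids at the start height")

    if intervals is None:
        rng = np.random.default_rng(model.seed)
        intervals = rng.exponential(1.0 / model.rate, n)
    else:
        intervals = np.asarray(intervals, float)

    neigh: list[list[int]] = [[] for _ in range(n)]
    for i, j in adjacency_pairs(phantom, model.epsilon):
        neigh[i].append(int(j))
        neigh[j].append(int(i))

    fill = np.full(n, np.inf)
    heap: list[tuple[float, int]] = []
    for i in np.nonzero(seeds)[0]:
        fill[i] = 0.0
        heapq.heappush(heap, (0.0, int(i)))
    while heap:
        t, i = heapq.heappop(heap)
        if t > fill[i]:
            continue  # stale entry
        for j in neigh[i]:
            cand = t + intervals[j]
            if cand < fill[j]:
                fill[j] = cand
                heapq.heappush(heap, (cand, j))

    if model.fallback_time is not None:
        fill[np.isinf(fill)] = model.fallback_time
    return fill


Model = MovingModel | ExpandingModel | InfiltrationModel


def phantom_at_time(base: FoamPhantom, model: Model, t: float) -> FoamPhantom:
    """Snapshot of the evolved phantom at time ``t`` (within the model grid).

    Moving phantoms may carry voids beyond ±z_max; height validation is
    disabled on the returned phantom.  Expanding phantoms may overlap —
    run ``validate_phantom`` on the snapshot to get the overlap report.
    """
    model._check_t(t)
    voids = base.voids.copy()
    if isinstance(model, MovingModel):
        voids[:, 2] += model.displacement(t)
        return base.with_voids(voids, enforce_height=False)
    if isinstance(model, ExpandingModel):
        voids[:, 3] *= model.growth(t)
        return base.with_voids(voids)
    if isinstance(model, InfiltrationModel):
        filled = model.schedule_for(base) <= t
        voids[filled, 4] = model.fill_attenuation
        return base.with_voids(voids)
    raise TypeError(f"unknown model type {type(model)!r}")


def default_schedule(n_angles: int, duration: float) -> np.ndarray:
    """(n_angles, 2) time intervals: projection k gets [k, k+1)/n · T."""
    edges = np.linspace(0.0, duration, n_angles + 1)
    return np.column_stack([edges[:-1], edges[1:]])


def project_dynamic(
    base: FoamPhantom,
    model: Model,
    geometry: ParallelGeometry,
    n_time_substeps: int = 1,
    schedule: np.ndarray | None = None,
    duration: float | None = None,
) -> ProjectionStack:
    """Dynamic scan: the sample rotates per the geometry's angle schedule
    while it evolves; each projection averages ``n_time_substeps`` phantom
    snapshots equally spaced within its time interval.
    """
    if n_time_substeps < 1:
        raise ValueError("n_time_substeps must be >= 1")
    if schedule is None:
        if duration is None:
            duration = min(model.t_max, 1.0) if np.isfinite(model.t_max) else 1.0
        schedule = default_schedule(geometry.n_angles, duration)
    schedule = np.asarray(schedule, float)
    if schedule.shape != (geometry.n_angles, 2):
        raise ValueError("schedule must map every projection to an interval")

    projector = project_cone if isinstance(geometry, ConeGeometry) else project_parallel
    angles = geometry.angles_deg
    out = None
    for k in range(geometry.n_angles):
        t0, t1 = schedule[k]
        # midpoints of n equal slices of [t0, t1]
        ts = t0 + (np.arange(n_time_substeps) + 0.5) * (t1 - t0) / n_time_substeps
        single = _single_angle_geometry(geometry, float(angles[k]))
        acc = None
        for t in ts:
            snap = phantom_at_time(base, model, float(t))
            p = projector(snap, single).values[0]
            acc = p if acc is None else acc + p
        if out is None:
            out = np.empty((geometry.n_angles,) + acc.shape)
        out[k] = acc / n_time_substeps
    stack = ProjectionStack(out, geometry, angles.copy())
    stack.provenance["time_schedule"] = schedule
    stack.provenance["n_time_substeps"] = n_time_substeps
    return stack


def _single_angle_geometry(geometry: ParallelGeometry, angle_deg: float):
    """One-projection copy of ``geometry`` whose single angle is ``angle_deg``."""
    kw = dict(
        n_angles=1,
        angular_range=geometry.angular_range,
        angle_offset=angle_deg,
        det_rows=geometry.det_rows,
        det_cols=geometry.det_cols,
        pixel_width=geometry.pixel_width,
        pixel_height=geometry.pixel_height,
        supersampling=geometry.supersampling,
    )
    if isinstance(geometry, ConeGeometry):
        return ConeGeometry(**kw, sod=geometry.sod, odd=geometry.odd)
    return ParallelGeometry(**kw)
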