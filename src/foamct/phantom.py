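"""Foam phantom domain model.

A foam phantom is an infinite vertical cylinder of unit radius and unit
attenuation, pierced by ``N`` non-overlapping spherical *voids*.  Void ``i``
is fully described by the five numbers ``(x_i, y_i, z_i, r_i, c_i)`` — its
center, radius and attenuation coefficient — all lengths expressed in units
of the cylinder radius and all attenuations relative to the foam material.
Outside the cylinder the attenuation is 0; by default voids are empty
(``c = 0``) but each void may be filled with its own material.

Geometric constraints:

* containment: ``sqrt(x² + y²) + r ≤ 1`` — no part of a void may leave the
  cylinder;
* non-overlap: ``d(p_i, p_j) ≥ r_i + r_j`` for every pair;
* ``r ≤ r_max`` and ``|z| ≤ z_max``; the height bound applies to the void
  *center* only, so voids may protrude past ``±z_max``.

Boundary semantics are measure-zero choices fixed here once: a point exactly
on a void surface or exactly on the cylinder surface belongs to the foam.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

#: Default absolute tolerance (in unit-radius lengths) for all geometric
#: comparisons.  The generator may produce exact touching, so overlap and
#: containment checks are one-sided.
GEOM_TOL = 1e-9

VOID_COLUMNS = ("x", "y", "z", "r", "c")


@dataclass(frozen=True)
class Void:
    """One spherical void: center, radius and attenuation coefficient."""

    x: float
    y: float
    z: float
    r: float
    c: float = 0.0

    @property
    def center(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    def as_row(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z, self.r, self.c])


@dataclass
class FoamPhantom:
    """A set of voids plus the parameters that generated it.

    ``voids`` is an ``(N, 5)`` float64 array with columns ``(x, y, z, r, c)``
    kept in placement order so that seeded regeneration is bit-comparable.
    The cylinder radius, foam attenuation and background attenuation are
    fixed to 1, 1 and 0 — every other length/attenuation is relative to them.
    """

    voids: np.ndarray
    n_trial_points: int = 0
    max_radius: float = np.inf
    max_height: float = np.inf
    seed: int | None = None
    rng_name: str = "numpy.random.PCG64"
    #: set for time-evolved phantoms: |z| <= z_max validation is disabled
    #: (a moving sample streams through the fixed scan region).
    enforce_height: bool = True

    cylinder_radius: float = field(default=1.0, init=False)
    foam_attenuation: float = field(default=1.0, init=False)
    background_attenuation: float = field(default=0.0, init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.voids, dtype=np.float64)
        if v.size == 0:
            v = v.reshape(0, 5)
        if v.ndim != 2 or v.shape[1] != 5:
            raise ValueError(f"voids must be an (N, 5) array, got shape {v.shape}")
        self.voids = v
        self._tree: cKDTree | None = None

    # -- container protocol over Void views --------------------------------
    @property
    def n_voids(self) -> int:
        return self.voids.shape[0]

    def __len__(self) -> int:
        return self.n_voids

    def __getitem__(self, i: int) -> Void:
        return Void(*self.voids[i])

    def __iter__(self) -> Iterator[Void]:
        for row in self.voids:
            yield Void(*row)

    @classmethod
    def from_voids(cls, voids: Sequence[Void], **kwargs) -> "FoamPhantom":
        rows = np.array([v.as_row() for v in voids]).reshape(-1, 5)
        return cls(rows, **kwargs)

    def with_voids(self, voids: np.ndarray, **kwargs) -> "FoamPhantom":
        """Copy of this phantom with a replaced void table."""
        return replace(self, voids=np.asarray(voids, dtype=np.float64), **kwargs)

    # -- derived quantities -------------------------------------------------
    @property
    def centers(self) -> np.ndarray:
        return self.voids[:, :3]

    @property
    def radii(self) -> np.ndarray:
        return self.voids[:, 3]

    @property
    def attenuations(self) -> np.ndarray:
        return self.voids[:, 4]

    def void_volume(self) -> float:
        """Total analytic volume of all voids."""
        return float(4.0 / 3.0 * np.pi * np.sum(self.radii**3))

    def _kdtree(self) -> cKDTree:
        if self._tree is None or self._tree.n != self.n_voids:
            self._tree = cKDTree(self.centers)
        return self._tree


@dataclass(frozen=True)
class Violation:
    """One violated geometric constraint.

    ``kind`` is one of ``overlap``, ``containment``, ``max_radius``,
    ``max_height``, ``nonpositive_radius``; ``indices`` names the offending
    void(s); ``magnitude`` is the signed excess (positive = violated).
    """

    kind: str
    indices: tuple[int, ...]
    magnitude: float


def validate_phantom(
    phantom: FoamPhantom, tolerance: float = GEOM_TOL
) -> list[Violation]:
    """Check every geometric constraint; violations are data, not errors.

    Returns an empty list iff containment, pairwise non-overlap, ``r_max``
    and ``z_max`` all hold within ``tolerance``.
    """
    out: list[Violation] = []
    v = phantom.voids
    n = phantom.n_voids
    if n == 0:
        return out

    rho = np.hypot(v[:, 0], v[:, 1])
    r = v[:, 3]

    for i in np.nonzero(r <= 0)[0]:
        out.append(Violation("nonpositive_radius", (int(i),), float(-r[i])))

    exc = rho + r - phantom.cylinder_radius
    for i in np.nonzero(exc > tolerance)[0]:
        out.append(Violation("containment", (int(i),), float(exc[i])))

    if np.isfinite(phantom.max_radius):
        exc = r - phantom.max_radius
        for i in np.nonzero(exc > tolerance)[0]:
            out.append(Violation("max_radius", (int(i),), float(exc[i])))

    if phantom.enforce_height and np.isfinite(phantom.max_height):
        exc = np.abs(v[:, 2]) - phantom.max_height
        for i in np.nonzero(exc > tolerance)[0]:
            out.append(Violation("max_height", (int(i),), float(exc[i])))

    # pairwise overlap via KD-tree: only pairs closer than r_i + r_j can
    # violate, and r_i + r_j <= 2 max(r), so query within that ball.
    tree = phantom._kdtree()
    pairs = tree.query_pairs(2.0 * float(r.max()) + tolerance, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(v[pairs[:, 0], :3] - v[pairs[:, 1], :3], axis=1)
        exc = r[pairs[:, 0]] + r[pairs[:, 1]] - d
        for k in np.nonzero(exc > tolerance)[0]:
            i, j = pairs[k]
            out.append(Violation("overlap", (int(i), int(j)), float(exc[k])))
    return out


def attenuation_at(x, y, z, phantom: FoamPhantom) -> np.ndarray | float:
    """Point-wise attenuation of the phantom.

    Returns 0 outside the cylinder (``sqrt(x²+y²) > 1``), the void's ``c``
    strictly inside a void, and 1 (foam) otherwise — points exactly on a
    void or cylinder surface count as foam.  Accepts scalars or
    broadcastable arrays; non-overlap guarantees at most one containing
    void per point.
    """
    x, y, z = np.broadcast_arrays(
        np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)
    )
    scalar = x.ndim == 0
    pts = np.column_stack([np.ravel(x), np.ravel(y), np.ravel(z)])
    out = np.where(
        pts[:, 0] ** 2 + pts[:, 1] ** 2 <= phantom.cylinder_radius**2,
        phantom.foam_attenuation,
        phantom.background_attenuation,
    )

    if phantom.n_voids:
        r = phantom.radii
        rmax = float(r.max())
        tree = phantom._kdtree()
        neighbors = tree.query_ball_point(pts, rmax, return_sorted=False)
        for k, cand in enumerate(neighbors):
            if not cand:
                continue
            cand = np.asarray(cand)
            d2 = np.sum((phantom.centers[cand] - pts[k]) ** 2, axis=1)
            inside = d2 < r[cand] ** 2  # strict: surface belongs to foam
            if inside.any():
                out[k] = phantom.attenuations[cand[np.argmax(inside)]]
    if scalar:
        return float(out[0])
    return out.reshape(x.shape)
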