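"""Shared fixtures and the independent line-integral oracle.

The oracle integrates the point-wise attenuation along a ray using only
point membership queries: it samples the attenuation on a dense parameter
grid (plus one hint point at each object's closest approach, so no
intersection is missed), refines every value change by bisection, and sums
value × segment length.  It never uses the analytic chord formulas it is
used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from foamct import generate_foam
from foamct.phantom import FoamPhantom


def _region_labels(phantom: FoamPhantom, pts: np.ndarray) -> np.ndarray:
    """Point membership: −1 outside the cylinder, 0 foam, j+1 inside void j."""
    lab = np.where(pts[:, 0] ** 2 + pts[:, 1] ** 2 <= 1.0, 0, -1)
    if phantom.n_voids:
        d2 = np.sum(
            (pts[:, None, :] - phantom.centers[None, :, :]) ** 2, axis=2
        )
        inside = d2 < phantom.radii[None, :] ** 2
        hit = inside.any(axis=1)
        lab[hit] = np.argmax(inside[hit], axis=1) + 1
    return lab


def line_integral_oracle(
    phantom: FoamPhantom,
    origin,
    direction,
    t_min: float = -4.0,
    t_max: float = 4.0,
    n_coarse: int = 1001,
    n_bisect: int = 50,
) -> float:
    """Exact-to-bisection line integral from point membership only.

    Every region (outside, foam-complement of each convex body) meets the
    ray in one interval, and a hint sample at each body's closest-approach
    parameter guarantees no intersection hides between grid nodes.  Label
    changes between adjacent samples are bisected to machine width; a
    bisection endpoint landing in a third region (e.g. a thin foam sliver
    between two touching voids) surfaces as a new label change and is
    refined in the next round.
    """
    o = np.asarray(origin, float)
    d = np.asarray(direction, float)

    ts = np.linspace(t_min, t_max, n_coarse)
    hints = []
    dxy2 = d[0] ** 2 + d[1] ** 2
    if dxy2 > 0:
        hints.append(-(o[0] * d[0] + o[1] * d[1]) / dxy2)
    if phantom.n_voids:
        hints.extend(((phantom.centers - o) @ d).tolist())
    hints = [h for h in hints if t_min < h < t_max]
    ts = np.unique(np.concatenate([ts, np.asarray(hints, float)]))

    def labels_at(t: np.ndarray) -> np.ndarray:
        p = o[None, :] + t[:, None] * d[None, :]
        return _region_labels(phantom, p)

    labs = labels_at(ts)
    for _ in range(6):  # rounds of boundary refinement
        diff = np.nonzero((labs[:-1] != labs[1:]) & (np.diff(ts) > 1e-12))[0]
        if len(diff) == 0:
            break
        lo, hi = ts[diff].copy(), ts[diff + 1].copy()
        l_lo = labs[diff].copy()
        for _ in range(n_bisect):
            mid = 0.5 * (lo + hi)
            is_left = labels_at(mid) == l_lo
            lo[is_left] = mid[is_left]
            hi[~is_left] = mid[~is_left]
        ts = np.unique(np.concatenate([ts, lo, hi]))
        labs = labels_at(ts)

    att = np.concatenate([[0.0, 1.0], phantom.attenuations])  # label + 1
    return float(np.sum(att[labs[:-1] + 1] * np.diff(ts)))


@pytest.fixture(scope="session")
def tiny_phantom() -> FoamPhantom:
    """Small seeded foam: fast to project, rich enough to be interesting."""
    return generate_foam(n_voids=150, n_trial_points=800, max_radius=0.2,
                         max_height=0.5, seed=11)


@pytest.fixture(scope="session")
def medium_phantom() -> FoamPhantom:
    """A 500-void phantom for projection-oracle and cone-limit checks."""
    return generate_foam(n_voids=500, n_trial_points=2000, max_radius=0.2,
                         max_height=1.0, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    # function-scoped: every test sees the same deterministic stream
    # regardless of execution order
    return np.random.default_rng(1234)
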