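"""Supersampled discretization of phantoms onto voxel/pixel grids.

Ground-truth images are produced by point sampling: each voxel value is the
mean of the point-wise attenuation over an ``s × s × s`` grid of sample
points at the subvoxel centers (consistent with the ray supersampling of
the projector).  The grid is centered on the rotation axis: voxel
``(0, 0, 0)`` sits at the most-negative corner and the center of voxel
``(i, j, k)`` is at ``((i+0.5) - n/2) * voxel_size`` per axis.

Because voids are disjoint and contained in the cylinder, the sampled mean
decomposes exactly into a cylinder term minus per-void coverage terms, so
the cost scales with total void volume, not grid volume.  Partial-volume
*analytic* sphere–cube intersection is out of scope; convergence is
O(1/s) on boundary voxels.
"""

from __future__ import annotations

import numpy as np

from .phantom import FoamPhantom


def _axis_centers(n: int, voxel_size: float) -> np.ndarray:
    return (np.arange(n) - (n - 1) / 2.0) * voxel_size


def _sub_offsets(s: int, voxel_size: float) -> np.ndarray:
    """Subvoxel-center offsets relative to the voxel center."""
    return ((np.arange(s) + 0.5) / s - 0.5) * voxel_size


def _disk_fraction(x: np.ndarray, y: np.ndarray, s: int, voxel_size: float) -> np.ndarray:
    """Fraction of each pixel's s×s sample points inside the unit disk."""
    off = _sub_offsets(s, voxel_size)
    acc = np.zeros((len(x), len(y)))
    for ox in off:
        for oy in off:
            acc += (x[:, None] + ox) ** 2 + (y[None, :] + oy) ** 2 <= 1.0
    return acc / (s * s)


def _sphere_patch_fraction(
    centers_1d: tuple[np.ndarray, ...],
    slices: tuple[slice, ...],
    void_center: np.ndarray,
    radius: float,
    s: int,
    voxel_size: float,
) -> tuple[tuple[slice, ...], np.ndarray]:
    """Sampled coverage fraction of one sphere over its voxel patch."""
    off = _sub_offsets(s, voxel_size)
    axes = [centers_1d[a][slices[a]] - void_center[a] for a in range(len(slices))]
    shape = tuple(len(ax) for ax in axes)
    acc = np.zeros(shape)
    r2 = radius * radius
    if len(axes) == 3:
        for ox in off:
            dx2 = (axes[0] + ox) ** 2
            for oy in off:
                dy2 = (axes[1] + oy) ** 2
                for oz in off:
                    dz2 = (axes[2] + oz) ** 2
                    acc += (
                        dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
                    ) < r2
        acc /= s**3
    else:
        for ox in off:
            dx2 = (axes[0] + ox) ** 2
            for oy in off:
                dy2 = (axes[1] + oy) ** 2
                acc += (dx2[:, None] + dy2[None, :]) < r2
        acc /= s**2
    return slices, acc


def _patch_slices(
    centers_1d: tuple[np.ndarray, ...],
    void_center: np.ndarray,
    radius: float,
    voxel_size: float,
) -> tuple[slice, ...] | None:
    margin = radius + voxel_size  # sample points stay within half a voxel
    out = []
    for a, ax in enumerate(centers_1d):
        lo = int(np.searchsorted(ax, void_center[a] - margin, side="left"))
        hi = int(np.searchsorted(ax, void_center[a] + margin, side="right"))
        if lo >= hi:
            return None
        out.append(slice(lo, hi))
    return tuple(out)


def discretize(
    phantom: FoamPhantom,
    shape: tuple[int, int, int],
    voxel_size: float,
    subsamples: int = 4,
) -> np.ndarray:
    """Supersampled ground-truth volume, indexed ``[ix, iy, iz]``.

    Each voxel holds the mean attenuation over ``subsamples³`` sample
    points.  Assumes non-overlapping voids (values of overlapping evolved
    phantoms may undershoot).
    """
    nx, ny, nz = shape
    if min(shape) < 1 or subsamples < 1:
        raise ValueError("invalid grid shape or subsampling")
    xs = _axis_centers(nx, voxel_size)
    ys = _axis_centers(ny, voxel_size)
    zs = _axis_centers(nz, voxel_size)

    vol = np.empty((nx, ny, nz))
    vol[:] = _disk_fraction(xs, ys, subsamples, voxel_size)[:, :, None]

    for j in range(phantom.n_voids):
        c = phantom.centers[j]
        sl = _patch_slices((xs, ys, zs), c, phantom.radii[j], voxel_size)
        if sl is None:
            continue
        sl, frac = _sphere_patch_fraction(
            (xs, ys, zs), sl, c, phantom.radii[j], subsamples, voxel_size
        )
        vol[sl] -= (1.0 - phantom.attenuations[j]) * frac
    return vol


def central_slice(
    phantom: FoamPhantom,
    plane: str = "axial",
    n: int = 256,
    pixel_size: float | None = None,
    subsamples: int = 4,
) -> np.ndarray:
    """Supersampled central slice image, ``n × n`` pixels.

    ``axial`` is the z = 0 plane (image ``[ix, iy]``), ``sagittal`` the
    y = 0 plane (image ``[ix, iz]``); ``pixel_size`` defaults to ``3/n``
    so the slice spans the detector width used throughout.
    """
    if pixel_size is None:
        pixel_size = 3.0 / n
    a = _axis_centers(n, pixel_size)
    if plane == "axial":
        img = _disk_fraction(a, a, subsamples, pixel_size)
        axes = (a, a)
        to2d = lambda c: np.array([c[0], c[1]])
        perp = lambda c, r: abs(c[2]) < r
        perp_d2 = lambda c: c[2] ** 2
    elif plane == "sagittal":
        # pixel (ix, iz); inside-cylinder along x only at y=0: |x| <= 1
        off = _sub_offsets(subsamples, pixel_size)
        col = np.mean([(np.abs(a[:, None] + o) <= 1.0) for o in off], axis=0)[:, 0]
        img = np.repeat(col[:, None], n, axis=1).astype(float)
        axes = (a, a)
        to2d = lambda c: np.array([c[0], c[2]])
        perp = lambda c, r: abs(c[1]) < r
        perp_d2 = lambda c: c[1] ** 2
    else:
        raise ValueError("plane must be 'axial' or 'sagittal'")

    for j in range(phantom.n_voids):
        c = phantom.centers[j]
        r = phantom.radii[j]
        if not perp(c, r + pixel_size):
            continue
        r_eff2 = r * r - perp_d2(c)
        # sample points live in the slice plane: use the in-plane radius
        if r_eff2 <= 0:
            # only off-plane sample points could hit; none exist in-plane
            continue
        c2 = to2d(c)
        sl = _patch_slices(axes, c2, r, pixel_size)
        if sl is None:
            continue
        sl, frac = _sphere_patch_fraction(
            axes, sl, c2, float(np.sqrt(r_eff2)), subsamples, pixel_size
        )
        img[sl] -= (1.0 - phantom.attenuations[j]) * frac
    return img


def void_masks(
    phantom: FoamPhantom,
    shape: tuple[int, ...],
    voxel_size: float,
    large_threshold: float = 0.1,
    small_threshold: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of voxel centers inside large / small voids.

    Large voids have ``r ≥ large_threshold``, small ``r < small_threshold``;
    voids in between belong to neither mask.  ``shape`` of length 3 marks a
    volume; length 2 marks the axial central slice (z = 0 plane).
    """
    if not (0 < small_threshold <= large_threshold):
        raise ValueError("need 0 < small_threshold <= large_threshold")
    axes = tuple(_axis_centers(n, voxel_size) for n in shape)
    large = np.zeros(shape, dtype=bool)
    small = np.zeros(shape, dtype=bool)
    for j in range(phantom.n_voids):
        r = phantom.radii[j]
        if small_threshold <= r < large_threshold:
            continue
        c3 = phantom.centers[j]
        if len(shape) == 2:
            if abs(c3[2]) >= r:
                continue
            c = np.array([c3[0], c3[1]])
            r_eff = float(np.sqrt(r * r - c3[2] ** 2))
        else:
            c = c3
            r_eff = r
        sl = _patch_slices(axes, c, r_eff, voxel_size)
        if sl is None:
            continue
        grids = np.meshgrid(*[axes[a][sl[a]] - c[a] for a in range(len(shape))],
                            indexing="ij")
        inside = sum(g * g for g in grids) < r_eff * r_eff
        tgt = large if r >= large_threshold else small
        tgt[sl] |= inside
    return large, small
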