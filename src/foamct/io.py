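"""HDF5 containers for phantoms, projection stacks and volumes.

Single-file layout (no sidecar JSON): one main dataset plus root
attributes, ``format_version`` starting at "1.0" with semantic
compatibility (readers reject unknown majors).  Every file carries a
provenance record — the operation, all parameters including seeds and RNG
name, tool version, timestamp and parent-file checksums — sufficient to
regenerate the payload: phantoms exactly, noisy stacks exactly given the
stored seed.

Phantom files: dataset ``voids`` of shape (N, 5), columns (x, y, z, r, c);
attributes ``n_trial_points``, ``max_radius``, ``max_height``, ``seed``,
``format_version``.  Legacy four-column void tables read with c = 0.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import asdict, dataclass, field

import h5py
import numpy as np

from . import __version__
from .phantom import FoamPhantom
from .projection import (
    ConeGeometry,
    NoiseModel,
    ParallelGeometry,
    ProjectionStack,
)

FORMAT_VERSION = "1.0"


class FormatError(ValueError):
    """Missing/invalid dataset or attribute; the message names the field."""


@dataclass
class ProvenanceRecord:
    """How a file's payload was produced."""

    operation: str
    parameters: dict
    tool_version: str = __version__
    rng_name: str = "numpy.random.PCG64"
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )
    parents: dict = field(default_factory=dict)  # path/label -> sha256

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, payload: str) -> "ProvenanceRecord":
        return cls(**json.loads(payload))


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _check_version(f: h5py.File, path) -> None:
    if "format_version" not in f.attrs:
        raise FormatError(f"{path}: missing attribute 'format_version'")
    major = str(f.attrs["format_version"]).split(".")[0]
    if major != FORMAT_VERSION.split(".")[0]:
        raise FormatError(
            f"{path}: unsupported format_version major "
            f"{f.attrs['format_version']!r} (reader supports {FORMAT_VERSION})"
        )


def _write_provenance(f: h5py.File, record: ProvenanceRecord | None) -> None:
    if record is not None:
        f.attrs["provenance"] = record.to_json()


def _read_provenance(f: h5py.File) -> ProvenanceRecord | None:
    if "provenance" in f.attrs:
        return ProvenanceRecord.from_json(str(f.attrs["provenance"]))
    return None


# -- phantoms ---------------------------------------------------------------


def write_phantom(
    path, phantom: FoamPhantom, provenance: ProvenanceRecord | None = None
) -> None:
    if provenance is None and phantom.seed is not None:
        provenance = ProvenanceRecord(
            operation="generate",
            parameters=dict(
                n_voids=int(phantom.n_voids),
                n_trial_points=int(phantom.n_trial_points),
                max_radius=float(phantom.max_radius),
                max_height=float(phantom.max_height),
                seed=int(phantom.seed),
            ),
            rng_name=phantom.rng_name,
        )
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.create_dataset("voids", data=phantom.voids)
        f.attrs["n_trial_points"] = int(phantom.n_trial_points)
        f.attrs["max_radius"] = float(phantom.max_radius)
        f.attrs["max_height"] = float(phantom.max_height)
        f.attrs["seed"] = -1 if phantom.seed is None else int(phantom.seed)
        f.attrs["rng_name"] = phantom.rng_name
        _write_provenance(f, provenance)


def read_phantom(path) -> FoamPhantom:
    with h5py.File(path, "r") as f:
        _check_version(f, path)
        if "voids" not in f:
            raise FormatError(f"{path}: missing dataset 'voids'")
        voids = np.asarray(f["voids"], dtype=np.float64)
        if voids.ndim != 2 or voids.shape[1] not in (4, 5):
            raise FormatError(
                f"{path}: dataset 'voids' must have 4 or 5 columns, "
                f"got shape {voids.shape}"
            )
        if voids.shape[1] == 4:  # legacy: no attenuation column
            voids = np.column_stack([voids, np.zeros(len(voids))])
        for attr in ("n_trial_points", "max_radius", "max_height", "seed"):
            if attr not in f.attrs:
                raise FormatError(f"{path}: missing attribute '{attr}'")
        seed = int(f.attrs["seed"])
        return FoamPhantom(
            voids,
            n_trial_points=int(f.attrs["n_trial_points"]),
            max_radius=float(f.attrs["max_radius"]),
            max_height=float(f.attrs["max_height"]),
            seed=None if seed < 0 else seed,
            rng_name=str(f.attrs.get("rng_name", "unknown")),
        )


# -- projection stacks ------------------------------------------------------

_GEOM_ATTRS = (
    "n_angles", "angular_range", "det_rows", "det_cols",
    "pixel_width", "pixel_height", "supersampling", "angle_offset",
)


def write_projections(
    path, stack: ProjectionStack, provenance: ProvenanceRecord | None = None
) -> None:
    g = stack.geometry
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.create_dataset("projs", data=stack.values)
        f.create_dataset("angles_deg", data=stack.angles_deg)
        f.attrs["geometry_type"] = (
            "cone" if isinstance(g, ConeGeometry) else "parallel"
        )
        for a in _GEOM_ATTRS:
            f.attrs[a] = getattr(g, a)
        if isinstance(g, ConeGeometry):
            f.attrs["sod"] = g.sod
            f.attrs["odd"] = g.odd
        f.attrs["clean"] = stack.is_clean
        if stack.noise is not None:
            f.attrs["noise_flux"] = stack.noise.flux
            f.attrs["noise_gamma"] = stack.noise.gamma
            f.attrs["noise_seed"] = stack.noise.seed
            f.attrs["n_clamped"] = stack.n_clamped
        _write_provenance(f, provenance)


def read_projections(path, expect: str | None = None) -> ProjectionStack:
    with h5py.File(path, "r") as f:
        _check_version(f, path)
        for ds in ("projs", "angles_deg"):
            if ds not in f:
                raise FormatError(f"{path}: missing dataset '{ds}'")
        for a in ("geometry_type",) + _GEOM_ATTRS:
            if a not in f.attrs:
                raise FormatError(f"{path}: missing attribute '{a}'")
        gtype = str(f.attrs["geometry_type"])
        if expect is not None and gtype != expect:
            raise FormatError(
                f"{path}: geometry type {gtype!r} does not match expected {expect!r}"
            )
        kw = {a: f.attrs[a].item() for a in _GEOM_ATTRS}
        kw["n_angles"] = int(kw["n_angles"])
        kw["det_rows"] = int(kw["det_rows"])
        kw["det_cols"] = int(kw["det_cols"])
        kw["supersampling"] = int(kw["supersampling"])
        if gtype == "cone":
            geom = ConeGeometry(**kw, sod=float(f.attrs["sod"]), odd=float(f.attrs["odd"]))
        else:
            geom = ParallelGeometry(**kw)
        noise = None
        n_clamped = 0
        if not bool(f.attrs["clean"]):
            noise = NoiseModel(
                flux=float(f.attrs["noise_flux"]),
                gamma=float(f.attrs["noise_gamma"]),
                seed=int(f.attrs["noise_seed"]),
            )
            n_clamped = int(f.attrs.get("n_clamped", 0))
        return ProjectionStack(
            values=np.asarray(f["projs"], dtype=np.float64),
            geometry=geom,
            angles_deg=np.asarray(f["angles_deg"], dtype=np.float64),
            noise=noise,
            n_clamped=n_clamped,
        )


# -- volumes ----------------------------------------------------------------


def write_volume(
    path, volume: np.ndarray, voxel_size: float,
    provenance: ProvenanceRecord | None = None,
) -> None:
    volume = np.asarray(volume)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.create_dataset("volume", data=volume)
        f.attrs["voxel_size"] = float(voxel_size)
        # world coordinate of the center of voxel (0, ..): grid centered on axis
        f.attrs["origin"] = [
            -(n - 1) / 2.0 * voxel_size for n in volume.shape
        ]
        _write_provenance(f, provenance)


def read_volume(path) -> tuple[np.ndarray, float]:
    with h5py.File(path, "r") as f:
        _check_version(f, path)
        if "volume" not in f:
            raise FormatError(f"{path}: missing dataset 'volume'")
        if "voxel_size" not in f.attrs:
            raise FormatError(f"{path}: missing attribute 'voxel_size'")
        return np.asarray(f["volume"]), float(f.attrs["voxel_size"])


# -- regeneration -----------------------------------------------------------


def regenerate(path) -> object:
    """Recompute a file's payload from its provenance record.

    Returns the regenerated object (phantom or projection stack); raises
    :class:`FormatError` when no provenance is stored or the operation is
    not regenerable.
    """
    from .generator import generate_foam  # local import to avoid cycles
    from .projection import apply_noise, project

    with h5py.File(path, "r") as f:
        _check_version(f, path)
        rec = _read_provenance(f)
    if rec is None:
        raise FormatError(f"{path}: no provenance record stored")
    if rec.operation == "generate":
        p = rec.parameters
        return generate_foam(
            n_voids=p["n_voids"], n_trial_points=p["n_trial_points"],
            max_radius=p["max_radius"], max_height=p["max_height"],
            seed=p["seed"],
        )
    if rec.operation == "project":
        p = rec.parameters
        phantom = generate_foam(**p["phantom"])
        stack = read_projections(path)
        clean = project(phantom, stack.geometry)
        if stack.noise is not None:
            clean = apply_noise(clean, stack.noise)
        return clean
    raise FormatError(f"{path}: operation {rec.operation!r} is not regenerable")
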