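"""Deterministic small objects for tests and examples.

Each fixture builds in well under a second and exercises one module end to
end: a tiny foam phantom, a toy central-slice sinogram of it, and a
dynamic (moving) toy whose t = 0 snapshot equals its base.
"""

from __future__ import annotations

from .dynamics import MovingModel
from .generator import generate_foam
from .projection import ParallelGeometry, project_parallel

KINDS = ("tiny-phantom", "toy-sinogram", "dynamic-toy")


def make_fixture(kind: str, seed: int = 0):
    """Build one of the named fixture objects, deterministic in ``seed``."""
    if kind == "tiny-phantom":
        return generate_foam(
            n_voids=150, n_trial_points=800, max_radius=0.2,
            max_height=0.5, seed=seed,
        )
    if kind == "toy-sinogram":
        phantom = make_fixture("tiny-phantom", seed)
        geometry = ParallelGeometry(
            n_angles=32, angular_range=180.0, det_rows=1, det_cols=64,
            pixel_width=3.0 / 64, supersampling=2,
        )
        return phantom, project_parallel(phantom, geometry)
    if kind == "dynamic-toy":
        phantom = make_fixture("tiny-phantom", seed)
        model = MovingModel.random(
            duration=1.0, n_intervals=4, velocity_scale=0.3, seed=seed
        )
        return phantom, model
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {KINDS}")
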