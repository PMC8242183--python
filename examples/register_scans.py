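"""Recover inter-scan rigid motion by mutual-information registration.

Applies a known 2 mm / 2 degree motion to a noiseless phantom and checks
that MI-driven Powell optimization recovers it.
"""

import math

import srrmri as s
from srrmri.transforms import RigidTransform
from srrmri.volumes import VoxelGrid, resample_to_grid

grid = VoxelGrid((48, 48, 48), (0.5, 0.5, 0.5))
_, truth, _ = s.make_phantom(s.PhantomSpec(grid=grid, geometry_seed=1, noise_sd=0.0))

t_true = RigidTransform(
    rotation=(math.radians(2.0), math.radians(-1.0), math.radians(1.0)),
    translation=(2.0, -1.0, 1.5),
    center=grid.world_center,
)
moving = resample_to_grid(truth, grid, t_true, order=3)

mi_before = s.mutual_information(moving, truth)
est = s.register_rigid(moving, truth)  # approximates the inverse of t_true
mi_after = s.mutual_information(resample_to_grid(moving, grid, est, order=1), truth)

residual_mm, residual_deg = est.compose(t_true).magnitude()
print(f"MI before {mi_before:.3f} nats -> after {mi_after:.3f} nats")
print(f"residual motion after registration: {residual_mm:.3f} mm, {residual_deg:.3f} deg")
# -> residuals far below the 0.5 mm / 0.5 deg tolerance the pipeline needs
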