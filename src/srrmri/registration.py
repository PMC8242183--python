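"""Inter-scan rigid alignment by mutual-information maximization.

Scans are first interpolated to the common HR grid; scan 1 is the
reference (its pose is the identity) and each further scan is aligned to
it by maximizing the mutual information (MI) of the joint intensity
histogram over the six rigid parameters. MI is estimated from a 32-bin
joint histogram with intensities clipped to each image's 1st-99th
percentiles, reported in nats. Optimization is derivative-free (Powell)
with a two-level coarse-to-fine schedule and is deterministic given the
initialization. These estimator choices are implementation-defined and
are validated by recovery of known simulated motion.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, optimize

from .transforms import RigidTransform
from .volumes import Volume, VoxelGrid, infield_mask, resample_to_grid

__all__ = ["RigidTransform", "mutual_information", "register_rigid"]


def _clipped(arr: np.ndarray) -> np.ndarray:
    lo, hi = np.percentile(arr, [1.0, 99.0])
    if hi <= lo:
        hi = lo + 1.0
    return np.clip(arr, lo, hi)


def mutual_information(
    a: Volume | np.ndarray,
    b: Volume | np.ndarray,
    bins: int = 32,
    mask: np.ndarray | None = None,
) -> float:
    """Mutual information of the joint intensity histogram, in nats.

    Computed over mutually valid voxels (``mask``, if given). For
    identical inputs this equals the marginal entropy of the image under
    the same binning.
    """
    if bins < 8:
        raise ValueError("bins must be >= 8")
    da = a.data if isinstance(a, Volume) else np.asarray(a)
    db = b.data if isinstance(b, Volume) else np.asarray(b)
    if da.shape != db.shape:
        raise ValueError("volumes must live on a common grid")
    va = da.ravel()
    vb = db.ravel()
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        if not m.any():
            raise ValueError("disjoint fields of view: no mutually valid voxels")
        va = va[m]
        vb = vb[m]
    va = _clipped(va)
    vb = _clipped(vb)
    joint, _, _ = np.histogram2d(va, vb, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    outer = px[:, None] * py[None, :]
    return float(np.sum(p[nz] * np.log(p[nz] / outer[nz])))


def _downsample(v: Volume, factor: int) -> Volume:
    if factor == 1:
        return v
    data = ndimage.gaussian_filter(v.data, sigma=factor / 2.0)
    sl = (slice(None, None, factor),) * 3
    data = data[sl]
    g = v.grid
    grid = VoxelGrid(
        data.shape,
        tuple(s * factor for s in g.spacing),
        g.origin,
        g.axis_codes,
    )
    return Volume(grid, data)


def _neg_mi(params: np.ndarray, moving: Volume, fixed: Volume, center, bins: int) -> float:
    tr = RigidTransform(tuple(params[:3]), tuple(params[3:]), center)
    res = resample_to_grid(moving, fixed.grid, tr, order=1)
    valid = infield_mask(moving, fixed.grid, tr)
    if not valid.any():
        return 0.0
    return -mutual_information(res, fixed, bins=bins, mask=valid)


def register_rigid(
    moving: Volume,
    fixed: Volume,
    init: RigidTransform | None = None,
    bins: int = 32,
) -> RigidTransform:
    """Rigid transform maximizing MI(moving composed with T, fixed).

    Both volumes are expected on the common HR grid (interpolate the LR
    stacks first). Runs Powell at half resolution then at full resolution;
    the rotation center is the fixed volume's world center. If the
    optimizer fails to improve on the initialization, the initialization
    is returned with a warning.
    """
    center = fixed.grid.world_center
    if init is None:
        init = RigidTransform(center=center)
    else:
        init = init.recenter(center)
    p = np.array([*init.rotation, *init.translation], dtype=float)

    init_score = _neg_mi(p, moving, fixed, center, bins)
    direc = np.diag([0.02, 0.02, 0.02, 1.0, 1.0, 1.0])  # ~1 degree / 1 mm probes

    for factor in (2, 1):
        mv = _downsample(moving, factor)
        fx = _downsample(fixed, factor)
        res = optimize.minimize(
            _neg_mi,
            p,
            args=(mv, fx, fx.grid.world_center, bins),
            method="Powell",
            options={"direc": direc.copy(), "xtol": 1e-4, "ftol": 1e-6, "maxiter": 20},
        )
        p = res.x
        direc = np.diag([0.005, 0.005, 0.005, 0.25, 0.25, 0.25])

    final_score = _neg_mi(p, moving, fixed, center, bins)
    if final_score > init_score + 1e-12:
        warnings.warn("registration failed to improve on its initialization; returning init")
        return init
    return RigidTransform(tuple(p[:3]), tuple(p[3:]), center)
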