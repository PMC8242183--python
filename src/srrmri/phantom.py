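"""Synthetic three-tissue digital brain phantom.

Generates ground-truth high-resolution volumes for end-to-end testing of
the reconstruction pipeline: a nested geometry of an outer CSF shell, a
convoluted GM ribbon and a WM core, embedded in zero-intensity background
(air). The interfaces are perturbed by smoothed random fields so tissue
boundaries are curved and irregular rather than analytic, which is what
makes through-plane partial voluming emerge naturally once the forward
model is applied.

Label convention: 0 = background, 1 = CSF, 2 = GM, 3 = WM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import RegionMask, Volume, VoxelGrid

__all__ = [
    "TissueModel",
    "PhantomSpec",
    "make_phantom",
    "ground_truth_boundary_fraction",
    "boundary_voxel_mask",
    "T2_TISSUES",
    "T1_TISSUES",
]

LABELS = {"background": 0, "CSF": 1, "GM": 2, "WM": 3}


@dataclass(frozen=True)
class TissueModel:
    """Mean intensities of the three tissue classes for a given contrast.

    Means are ordered as (CSF, GM, WM). A T2-like contrast has
    GM < WM < CSF (fluid bright); a T1-like contrast has CSF < GM < WM.
    """

    means: tuple[float, float, float]
    sds: tuple[float, float, float] = (0.0, 0.0, 0.0)
    contrast: str = "t2"
    class_names: tuple[str, str, str] = ("CSF", "GM", "WM")

    def __post_init__(self):
        csf, gm, wm = self.means
        if len({csf, gm, wm}) != 3:
            raise ValueError("tissue means must be pairwise distinct")
        if any(s < 0 for s in self.sds):
            raise ValueError("tissue sds must be non-negative")
        if self.contrast == "t2":
            if not (gm < wm < csf):
                raise ValueError("T2-like contrast requires mean(GM) < mean(WM) < mean(CSF)")
        elif self.contrast == "t1":
            if not (csf < gm < wm):
                raise ValueError("T1-like contrast requires mean(CSF) < mean(GM) < mean(WM)")
        else:
            raise ValueError(f"contrast must be 't1' or 't2', got {self.contrast!r}")


#: Default T2-weighted intensity model: bright CSF, dark GM, intermediate WM.
T2_TISSUES = TissueModel(means=(300.0, 100.0, 200.0), contrast="t2")
#: Default T1-weighted intensity model: dark CSF, intermediate GM, bright WM.
T1_TISSUES = TissueModel(means=(60.0, 180.0, 280.0), contrast="t1")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom realization.

    Defaults mirror the simulation scale of the study conditions: a 96^3
    lattice at 0.5 mm isotropic with additive Gaussian noise of sd 10 on
    tissue means of 100-300 (SNR well above the additive-Gaussian regime).
    """

    grid: VoxelGrid = field(
        default_factory=lambda: VoxelGrid((96, 96, 96), (0.5, 0.5, 0.5))
    )
    tissue_model: TissueModel = T2_TISSUES
    geometry_seed: int = 0
    noise_sd: float = 10.0
    n_blobs: int = 3

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _label_field(spec: PhantomSpec) -> np.ndarray:
    """Piecewise-constant class map of nested smooth shapes."""
    shape = spec.grid.shape
    rng = np.random.default_rng(spec.geometry_seed)
    idx = np.indices(shape, dtype=float)
    ctr = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    # normalized ellipsoidal radius: ~1 at the head boundary
    semi = 0.46 * np.asarray(shape, dtype=float)
    rho = np.sqrt(sum(((idx[a] - ctr[a]) / semi[a]) ** 2 for a in range(3)))

    # smoothed random perturbation makes the interfaces convoluted
    noise = rng.standard_normal(shape)
    sigma = max(min(shape) / 12.0, 2.0)
    smooth = ndimage.gaussian_filter(noise, sigma)
    smooth /= max(smooth.std(), 1e-12)
    phi = rho + 0.15 * smooth * np.clip(rho, 0.0, 1.0)

    # nested off-center bumps deepen the cortical-looking folds
    for _ in range(max(spec.n_blobs, 0)):
        c = ctr + (rng.uniform(-0.25, 0.25, size=3) * np.asarray(shape))
        width = rng.uniform(0.08, 0.18) * min(shape)
        r2 = sum((idx[a] - c[a]) ** 2 for a in range(3))
        phi += rng.uniform(-0.12, 0.12) * np.exp(-r2 / (2.0 * width**2))

    labels = np.zeros(shape, dtype=np.int16)
    labels[phi < 1.0] = LABELS["CSF"]
    labels[phi < 0.82] = LABELS["GM"]
    labels[phi < 0.58] = LABELS["WM"]
    return labels


def make_phantom(spec: PhantomSpec | None = None) -> tuple[Volume, Volume, RegionMask]:
    """Build (labels, image, boundary_mask) for a phantom specification.

    The image assigns each voxel its class mean intensity plus i.i.d.
    Gaussian noise of sd ``spec.noise_sd`` (background stays at mean 0 so a
    corner region provides a pure-noise sample). Deterministic for a fixed
    ``geometry_seed``. The boundary mask marks foreground voxels with at
    least one of their 6 face-neighbors in a different foreground class.
    """
    spec = spec or PhantomSpec()
    if any(n < 16 for n in spec.grid.shape):
        raise ValueError(
            f"grid too small to host nested shapes: need >= 16 voxels per axis, got {spec.grid.shape}"
        )
    labels = _label_field(spec)
    lut = np.array([0.0, *spec.tissue_model.means])
    image = lut[labels]
    if any(s > 0 for s in spec.tissue_model.sds):
        rng_cls = np.random.default_rng(spec.geometry_seed + 7)
        sd_lut = np.array([0.0, *spec.tissue_model.sds])
        image = image + sd_lut[labels] * rng_cls.standard_normal(labels.shape)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.geometry_seed + 1)
        image = image + rng.normal(0.0, spec.noise_sd, size=labels.shape)
    boundary = boundary_voxel_mask(labels)
    return (
        Volume(spec.grid, labels.astype(float)),
        Volume(spec.grid, image),
        RegionMask(spec.grid, boundary),
    )


def boundary_voxel_mask(labels: np.ndarray) -> np.ndarray:
    """Foreground voxels 6-adjacent to a different nonzero class."""
    lab = np.asarray(labels)
    fg = lab > 0
    mixed = np.zeros(lab.shape, dtype=bool)
    for axis in range(3):
        for shift in (1, -1):
            nb = np.full(lab.shape, -1, dtype=lab.dtype)  # -1: no neighbor (edge)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if shift == 1:
                src[axis] = slice(0, -1)
                dst[axis] = slice(1, None)
            else:
                src[axis] = slice(1, None)
                dst[axis] = slice(0, -1)
            nb[tuple(dst)] = lab[tuple(src)]
            mixed |= fg & (nb > 0) & (nb != lab)
    return mixed


def ground_truth_boundary_fraction(labels: Volume) -> float:
    """Fraction of foreground voxels lying on an inter-tissue boundary."""
    lab = np.rint(labels.data).astype(np.int64)
    fg = int((lab > 0).sum())
    if fg == 0:
        raise ValueError("label volume has no foreground voxels")
    return float(boundary_voxel_mask(lab).sum()) / fg
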