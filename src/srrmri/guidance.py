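"""Interpolate-and-average (IAA) combination and gradient guidance.

The gradient guidance is a fixed family of shift-difference fields
computed once from the IAA image I:

    g_s = I - D_x^a D_y^b D_z^c I

where D_m^n circularly shifts the image by n voxels along axis m. The
default index set takes a in [-2, 2] and b, c in [0, 2], excluding the
all-zero triple and triples with a + b + c < 0 (which duplicate existing
orientations), leaving exactly 40 components spanning several orientations
and scales. The reconstruction's own shift differences are encouraged to
match these fields under an L1 penalty.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .volumes import Volume, VoxelGrid

__all__ = [
    "ShiftTriple",
    "GuidanceSet",
    "enumerate_shifts",
    "shift_difference",
    "shift_difference_adjoint",
    "iaa_combine",
    "build_guidance",
]


@dataclass(frozen=True)
class ShiftTriple:
    """Integer voxel shift (alpha, beta, gamma) along (x, y, z)."""

    alpha: int
    beta: int
    gamma: int

    def __post_init__(self):
        for v in (self.alpha, self.beta, self.gamma):
            if int(v) != v:
                raise ValueError("shifts must be integers")

    @property
    def as_tuple(self) -> tuple[int, int, int]:
        return (self.alpha, self.beta, self.gamma)


def enumerate_shifts(
    alpha_range: tuple[int, int] = (-2, 2),
    beta_range: tuple[int, int] = (0, 2),
    gamma_range: tuple[int, int] = (0, 2),
) -> list[ShiftTriple]:
    """All shift triples in the product of ranges, minus duplicates.

    Excludes the all-zero triple and triples whose coordinate sum is
    negative; with the default ranges this leaves exactly 40 components.
    Triples are returned in lexicographic order.
    """
    out = [
        ShiftTriple(a, b, c)
        for a, b, c in itertools.product(
            range(alpha_range[0], alpha_range[1] + 1),
            range(beta_range[0], beta_range[1] + 1),
            range(gamma_range[0], gamma_range[1] + 1),
        )
        if not (a == b == c == 0) and a + b + c >= 0
    ]
    if not out:
        raise ValueError("shift ranges leave no components after exclusions")
    return out


def shift_difference(v: Volume, s: ShiftTriple) -> Volume:
    """v minus v circularly shifted by (alpha, beta, gamma) voxels.

    Realizes both the guidance component computation and the
    reconstruction-side gradient at the same orientation and scale. The
    lattice sum of the output is exactly zero (circular shifts preserve
    the sum), and a constant image maps to zero.
    """
    shifted = np.roll(v.data, s.as_tuple, axis=(0, 1, 2))
    return Volume(v.grid, v.data - shifted)


def shift_difference_adjoint(v: Volume, s: ShiftTriple) -> Volume:
    """Adjoint of shift_difference: identity minus the inverse circular shift."""
    shifted = np.roll(v.data, tuple(-x for x in s.as_tuple), axis=(0, 1, 2))
    return Volume(v.grid, v.data - shifted)


def iaa_combine(volumes: list[Volume]) -> Volume:
    """Voxelwise mean of n aligned, HR-interpolated scans (the IAA image)."""
    if len(volumes) < 1:
        raise ValueError("iaa_combine requires at least one volume")
    grid = volumes[0].grid
    for v in volumes[1:]:
        if v.grid != grid:
            raise ValueError("iaa_combine requires all volumes on the same grid")
    return Volume(grid, np.mean([v.data for v in volumes], axis=0))


@dataclass
class GuidanceSet:
    """The index set S and its gradient fields g_s on the HR grid."""

    grid: VoxelGrid
    shifts: list[ShiftTriple]
    fields: list[np.ndarray]

    def __post_init__(self):
        if len(self.shifts) != len(self.fields):
            raise ValueError("one field per shift is required")
        if len(set(s.as_tuple for s in self.shifts)) != len(self.shifts):
            raise ValueError("shifts must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.shifts)

    @classmethod
    def zeros(cls, grid: VoxelGrid, shifts: list[ShiftTriple]) -> "GuidanceSet":
        """All-zero fields (the TV prior expressed in the same family)."""
        z = np.zeros(grid.shape)
        return cls(grid, list(shifts), [z] * len(shifts))


def build_guidance(iaa_image: Volume, shifts: list[ShiftTriple] | None = None) -> GuidanceSet:
    """Compute g_s = shift_difference(IAA, s) for every s in the index set."""
    shifts = shifts if shifts is not None else enumerate_shifts()
    fields = [shift_difference(iaa_image, s).data for s in shifts]
    return GuidanceSet(iaa_image.grid, list(shifts), fields)
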