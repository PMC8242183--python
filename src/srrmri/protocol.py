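"""Fast-spin-echo scan-time model and acquisition-planning arithmetic.

The scan time of a 2D multi-slice FSE acquisition is

    T = TR * ceil( FoV_p / (S_p * f_acc * ETL) ) * N_NEX

where ``FoV_p`` and ``S_p`` are the field of view and voxel size along the
phase-encode direction, ``f_acc`` the parallel-imaging acceleration factor,
``ETL`` the echo train length and ``N_NEX`` the number of excitations.

This module also provides the interleaved slice ordering used on the
scanner and the data/time/SNR trade-off between a thick-slice protocol and
a direct isotropic high-resolution acquisition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ProtocolParams",
    "TradeOff",
    "scan_time",
    "max_tr",
    "interleaved_slice_order",
    "encode_budget_ratio",
    "hr_tradeoff",
]


@dataclass(frozen=True)
class ProtocolParams:
    """FSE protocol parameters governing scan time.

    ``TR`` may be None when the repetition time is the unknown being solved
    for (see :func:`max_tr`).
    """

    FoV_p: float  # field of view, phase-encode direction (mm)
    S_p: float  # voxel size, phase-encode direction (mm)
    f_acc: float = 1.0  # parallel-imaging acceleration factor (>= 1)
    ETL: int = 1  # echo train length
    N_NEX: int = 1  # number of excitations (averages)
    TR: float | None = None  # repetition time (s)
    n_slices: int = 1
    slice_thickness: float = 2.0  # mm

    def __post_init__(self):
        for name in ("FoV_p", "S_p", "f_acc", "slice_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("ETL", "N_NEX", "n_slices"):
            val = getattr(self, name)
            if int(val) != val or val < 1:
                raise ValueError(f"{name} must be a positive integer, got {val}")
        if self.f_acc < 1:
            raise ValueError("f_acc must be >= 1")
        if self.TR is not None and self.TR <= 0:
            raise ValueError("TR must be strictly positive")

    @property
    def shots(self) -> float:
        """Continuous phase-encode shot count FoV_p / (S_p * f_acc * ETL)."""
        return self.FoV_p / (self.S_p * self.f_acc * self.ETL)


def scan_time(p: ProtocolParams) -> float:
    """Scan time in seconds: TR * ceil(shots) * N_NEX."""
    if p.TR is None:
        raise ValueError("scan_time requires TR to be set")
    return p.TR * math.ceil(p.shots - 1e-12) * p.N_NEX


def max_tr(T_budget: float, p: ProtocolParams, apply_ceiling: bool = False) -> float:
    """Largest TR (s) keeping the scan within ``T_budget`` seconds.

    With ``apply_ceiling=False`` (default) the shot count is treated as
    continuous, which is how the protocol's published worked value of
    13.1 s arises; with ``apply_ceiling=True`` the integer shot count of
    the scan-time formula is used, giving a slightly smaller TR.
    """
    if T_budget <= 0:
        raise ValueError("T_budget must be strictly positive")
    shots = math.ceil(p.shots - 1e-12) if apply_ceiling else p.shots
    return T_budget / (shots * p.N_NEX)


def interleaved_slice_order(N: int) -> list[int]:
    """Even-first ascending interleave-2 slice order, 1-based.

    For N slices the scanner excites even slice indices ascending, then odd
    ones ascending: N=6 -> [2, 4, 6, 1, 3, 5]. The output is always a
    permutation of 1..N.
    """
    if int(N) != N or N < 1:
        raise ValueError(f"N must be a positive integer, got {N}")
    N = int(N)
    return list(range(2, N + 1, 2)) + list(range(1, N + 1, 2))


def encode_budget_ratio(steps_lr_total: int, steps_hr: int) -> float:
    """Fraction of the direct-HR phase-encode budget spent on the LR stacks."""
    if steps_lr_total <= 0 or steps_hr <= 0:
        raise ValueError("phase-encode step counts must be positive")
    return steps_lr_total / steps_hr


@dataclass(frozen=True)
class TradeOff:
    """Cost of matching a thick-slice protocol by direct HR acquisition."""

    data_factor: float  # k-space samples ratio (voxel_lr/voxel_hr)^3
    time_factor_minutes: float  # scan time scaled by the phase-encode increase
    n_averages: int  # averages needed to match SNR, via the rounded factor
    n_averages_exact: float  # same quantity in exact arithmetic


def hr_tradeoff(voxel_hr: float, voxel_lr: float, base_time: float = 6.0) -> TradeOff:
    """Data, time and SNR-averaging cost of direct HR versus LR acquisition.

    Shrinking the voxel from ``voxel_lr`` to ``voxel_hr`` mm acquires
    ``(voxel_lr/voxel_hr)^3`` times more data, lengthens the ``base_time``
    minute scan by the squared ratio of phase encodes, and costs a squared
    data factor in averages to recover the SNR lost to the smaller voxel.
    ``n_averages`` follows the conventional rounding chain (ratio rounded
    to one decimal, squared, truncated); the exact value is also returned.
    """
    if voxel_hr <= 0 or voxel_lr <= 0:
        raise ValueError("voxel sizes must be strictly positive")
    r = voxel_lr / voxel_hr
    data_factor = r**3
    time_factor = base_time * r**2
    rounded = round(data_factor, 1)
    return TradeOff(
        data_factor=data_factor,
        time_factor_minutes=time_factor,
        n_averages=int(rounded * rounded),
        n_averages_exact=data_factor**2,
    )
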