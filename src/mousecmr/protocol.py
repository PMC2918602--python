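"""Acquisition protocol: sequence parameters, scan-time accounting and the
Cartesian phase-encode undersampling pattern.

The protocol mirrors a self-gated multi-slice gradient-echo (FLASH) cine
sequence: every TR acquires one phase-encode line (preceded by a navigator
echo), slices are swept sequentially, and the whole line set is repeated
``repetitions`` times so that each line is seen at many cardiac phases.
Acceleration ``R`` reduces the acquired phase-encode set to
``floor(N_pe / R)`` lines at (as near as possible) uniform spacing, always
including the DC line.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np


class ProtocolError(ValueError):
    pass


@dataclass
class AcquisitionProtocol:
    """Cartesian multi-slice cine protocol.

    ``matrix`` is (readout, phase-encode); ``fov_mm`` is (readout, phase-encode).
    TE and pulse angle are carried as metadata only (no contrast physics).
    """

    fov_mm: tuple[float, float] = (25.0, 25.0)
    matrix: tuple[int, int] = (154, 154)
    tr_ms: float = 5.2
    te_ms: float = 1.6
    repetitions: int = 200
    n_slices: int = 7
    slice_thickness_mm: float = 1.0
    flip_angle_deg: float = 10.0
    acceleration: float = 1.0
    contrast: str = "black-blood"

    def __post_init__(self):
        if min(self.matrix) < 1 or self.repetitions < 1 or self.n_slices < 1:
            raise ProtocolError("matrix, repetitions and slice count must be >= 1")
        if self.tr_ms <= 0:
            raise ProtocolError("TR must be positive")
        if self.acceleration < 1:
            raise ProtocolError(f"acceleration R must be >= 1, got {self.acceleration}")
        if self.contrast not in ("black-blood", "bright-blood"):
            raise ProtocolError(f"unknown contrast mode {self.contrast!r}")

    @property
    def n_readout(self) -> int:
        return self.matrix[0]

    @property
    def n_pe(self) -> int:
        return self.matrix[1]

    @property
    def voxel_mm(self) -> tuple[float, float, float]:
        """In-plane voxel dimensions plus slice thickness (mm)."""
        return (
            self.fov_mm[0] / self.matrix[0],
            self.fov_mm[1] / self.matrix[1],
            self.slice_thickness_mm,
        )

    @property
    def voxel_volume_ul(self) -> float:
        """Voxel volume in mm^3 (= microlitres * 1e-3 ... 1 mm^3 = 1 ul)."""
        vy, vx, vz = self.voxel_mm
        return vy * vx * vz

    def to_dict(self) -> dict:
        return asdict(self)


def acquired_lines(protocol: AcquisitionProtocol) -> int:
    """Number of phase-encode lines acquired per slice per repetition: floor(N_pe / R)."""
    return int(np.floor(protocol.n_pe / protocol.acceleration + 1e-9))


def _round_half_away(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(abs(x))).quantize(q, rounding=ROUND_HALF_UP)) * (1 if x >= 0 else -1)


def scan_time(protocol: AcquisitionProtocol) -> float:
    """Total acquisition time in minutes, rounded to one decimal.

    lines * TR * NR * slices; one line (plus its navigator echo) per TR.
    """
    ms = acquired_lines(protocol) * protocol.tr_ms * protocol.repetitions * protocol.n_slices
    return _round_half_away(ms / 60000.0, 1)


def phase_encode_pattern(n_pe: int, acceleration: float) -> np.ndarray:
    """Sorted 0-based phase-encode indices acquired at acceleration R.

    Selects floor(N_pe / R) lines at near-uniform spacing, shifted so the
    DC line (index ``n_pe // 2``) is included.
    """
    if acceleration < 1:
        raise ProtocolError("acceleration must be >= 1")
    m = int(np.floor(n_pe / acceleration + 1e-9))
    if m < 1:
        raise ProtocolError("acceleration too large: no lines acquired")
    base = np.floor(np.arange(m) * (n_pe / m)).astype(int)
    dc = n_pe // 2
    shift = dc - base[np.argmin(np.abs(base - dc))]
    pattern = np.sort((base + shift) % n_pe)
    if len(np.unique(pattern)) != m:  # pragma: no cover - guaranteed by construction
        raise ProtocolError("degenerate undersampling pattern")
    return pattern


def uniform_stride(pattern: np.ndarray, n_pe: int) -> int | None:
    """Return integer stride R if the pattern is exactly uniform with R | N_pe.

    Uniform integer-stride patterns admit the classic aliasing-group SENSE
    unfolding; anything else goes through the general per-column solver.
    """
    d = np.diff(pattern)
    if len(pattern) == n_pe:
        return 1
    if len(d) and np.all(d == d[0]) and n_pe % int(d[0]) == 0 and len(pattern) * int(d[0]) == n_pe:
        return int(d[0])
    return None
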