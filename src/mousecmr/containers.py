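"""In-memory containers passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .protocol import AcquisitionProtocol


LINE_TABLE_DTYPE = np.dtype(
    [("slice", np.int32), ("pe", np.int32), ("t_ms", np.float64)]
)


@dataclass
class KSpaceSeries:
    """Time-ordered raw k-space lines from a (simulated) self-gated acquisition.

    data
        complex array (n_coils, n_lines, n_readout); one row per TR, in
        acquisition order.
    line_table
        structured array (n_lines,) with fields ``slice``, ``pe`` (0-based
        phase-encode index) and ``t_ms`` (timestamp).
    navigator
        one complex navigator sample per TR (length n_lines).
    noise_cov
        coil x coil complex noise covariance used for / estimated from the scan.
    """

    data: np.ndarray
    line_table: np.ndarray
    navigator: np.ndarray
    protocol: "AcquisitionProtocol"
    noise_cov: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n_lines = self.data.shape[1]
        if len(self.line_table) != n_lines or len(self.navigator) != n_lines:
            raise ValueError("line_table / navigator length must match k-space lines")

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def n_lines(self) -> int:
        return self.data.shape[1]


@dataclass
class BinnedKSpace:
    """Per-cardiac-frame k-space after retrospective gating.

    data: complex (n_frames, n_slices, n_coils, n_pattern, n_readout)
    hits: int (n_frames, n_slices, n_pattern) acquisition count per bin
    fill_report: pandas DataFrame of borrowed (never-acquired) bins
    """

    data: np.ndarray
    hits: np.ndarray
    pattern: np.ndarray
    fill_report: "object"

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def fill_fraction(self) -> np.ndarray:
        """Fraction of (slice, line) bins that had to be borrowed, per frame."""
        empty = (self.hits == 0).reshape(self.n_frames, -1)
        return empty.mean(axis=1)


@dataclass
class CineStack:
    """Reconstructed magnitude cine: (n_frames, n_slices, n_pe, n_readout).

    ``g_maps`` (n_slices, n_pe, n_readout) holds the SENSE geometry-factor
    map per slice (frame independent for a fixed sampling pattern).
    """

    frames: np.ndarray
    voxel_mm: tuple[float, float, float]
    g_maps: Optional[np.ndarray] = None
    acceleration: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_slices(self) -> int:
        return self.frames.shape[1]
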