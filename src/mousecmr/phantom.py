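"""Dynamic digital mouse-heart phantom and simulated multi-coil acquisition.

The phantom is a short-axis multi-slice left/right-ventricle geometry built
from concentric circles whose radii contract sinusoidally between
end-diastole (ED, cardiac phase 0) and end-systole (ES, phase 0.5).  The
endocardial radius scales by ``sqrt(1 - EF)`` at ES so the stack of
cylindrical slices hits the configured ejection fraction exactly, and the
epicardial radius follows from myocardial incompressibility
(``r_epi^2 - r_endo^2`` constant per slice), so LV mass is conserved over
the cycle.  All ground-truth volumes therefore have closed forms.

Respiration is a rigid in-plane translation with a narrow Gaussian
displacement bump once per cycle, i.e. the heart is still for ~75% of the
respiratory period and moves during the remaining window — the lines
acquired inside that window are the ones a retrospective gater should
divert to the respiratory frame.

Contrast is modeled purely as tissue intensity (black-blood: dark cavity;
bright-blood: bright cavity); no Bloch simulation, TE/TR are metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .containers import KSpaceSeries, LINE_TABLE_DTYPE
from .fourier import cfft2
from .protocol import AcquisitionProtocol, ProtocolError, phase_encode_pattern


class PhantomError(ValueError):
    pass


MYOCARDIAL_DENSITY_MG_PER_MM3 = 1.05  # specific gravity of myocardium


@dataclass
class PhantomConfig:
    """Geometry, dynamics and contrast of one simulated subject.

    Radii are end-diastolic values of the basal slice (mm); apical slices
    are scaled down along an ellipsoidal taper.  Rates are per minute.
    """

    matrix: int = 96
    fov_mm: float = 25.0
    n_slices: int = 5
    slice_thickness_mm: float = 1.0
    endo_radius_ed_mm: float = 1.85
    epi_radius_ed_mm: float = 2.75
    ejection_fraction: float = 0.72
    heart_rate_bpm: float = 498.0
    resp_rate_bpm: float = 85.0
    resp_amplitude_mm: float = 0.8
    resp_axis: tuple[float, float] = (0.94, 0.34)  # unit direction (y, x)
    resp_sigma: float = 0.055  # Gaussian bump width, fraction of the cycle
    hrv_amplitude: float = 0.02    # fractional sinusoidal heart-rate variability
    hrv_period_ms: float = 5000.0
    rrv_amplitude: float = 0.03    # fractional respiratory-rate variability
    rrv_period_ms: float = 11000.0
    contrast: str = "black-blood"
    intensity_myocardium: float = 1.0
    intensity_blood_dark: float = 0.08
    intensity_blood_bright: float = 1.3
    intensity_background: float = 0.25
    lv_center_mm: tuple[float, float] = (-1.2, 0.8)  # (y, x) offset from FOV center
    body_radii_mm: tuple[float, float] = (9.5, 8.5)
    apex_margin: float = 0.75
    include_rv: bool = True
    infarct: bool = False
    infarct_center_deg: float = 135.0
    infarct_extent_deg: float = 90.0
    infarct_thinning: float = 0.5
    infarct_dilation: float = 1.0
    noise_sigma_image: float = 0.05  # image-domain-referred raw-line noise SD
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.endo_radius_ed_mm < self.epi_radius_ed_mm:
            raise PhantomError("need 0 < endocardial radius < epicardial radius")
        if not 0 < self.ejection_fraction < 1:
            raise PhantomError("ejection fraction must be in (0, 1)")
        for r in (self.heart_rate_bpm, self.resp_rate_bpm):
            if not 0 < r < 1200:
                raise PhantomError("rates must lie in (0, 1200) per minute")
        if not 0 < self.infarct_thinning <= 1:
            raise PhantomError("thinning factor must be in (0, 1]")
        for v in (self.intensity_myocardium, self.intensity_blood_dark,
                  self.intensity_blood_bright, self.intensity_background):
            if v < 0:
                raise PhantomError("tissue intensities must be >= 0")
        if self.contrast not in ("black-blood", "bright-blood"):
            raise PhantomError(f"unknown contrast mode {self.contrast!r}")

    @property
    def pixel_mm(self) -> float:
        return self.fov_mm / self.matrix

    @property
    def intensity_blood(self) -> float:
        return (self.intensity_blood_dark if self.contrast == "black-blood"
                else self.intensity_blood_bright)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhantomGroundTruth:
    """Analytic per-phase truth for parameter-recovery tests."""

    phases: np.ndarray                  # cardiac phase of each sample, in [0, 1)
    cavity_volume_ul: np.ndarray        # per phase
    myocardial_volume_ul: np.ndarray    # per phase
    lv_mass_mg: float                   # at end-diastole
    wall_thickness_mm: np.ndarray       # (n_phases, 24) mid-slice profile, 15 deg steps
    ed_index: int
    es_index: int

    @property
    def edv_ul(self) -> float:
        return float(self.cavity_volume_ul[self.ed_index])

    @property
    def esv_ul(self) -> float:
        return float(self.cavity_volume_ul[self.es_index])

    @property
    def sv_ul(self) -> float:
        return self.edv_ul - self.esv_ul

    @property
    def ef_percent(self) -> float:
        return 100.0 * self.sv_ul / self.edv_ul


@dataclass
class CoilModel:
    """Receive array: smooth complex sensitivities on the image grid."""

    maps: np.ndarray                    # (n_coils, N, N) complex
    center_angles_deg: np.ndarray
    ring_radius_mm: float
    falloff_mm: float

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]


# ---------------------------------------------------------------------------
# analytic geometry
# ---------------------------------------------------------------------------

def slice_scale(config: PhantomConfig, slice_index: int) -> float:
    """Ellipsoidal base-to-apex taper of the slice radii."""
    u = slice_index / (config.n_slices + config.apex_margin)
    return float(np.sqrt(max(1.0 - u * u, 1e-6)))


def contraction(config: PhantomConfig, cardiac_phase) -> np.ndarray:
    """Endocardial radius scale over the cycle: 1 at ED, sqrt(1-EF) at ES."""
    alpha = np.sqrt(1.0 - config.ejection_fraction)
    return 1.0 - (1.0 - alpha) * (1.0 - np.cos(2 * np.pi * np.asarray(cardiac_phase))) / 2.0


def lv_radii(config: PhantomConfig, cardiac_phase: float, slice_index: int
             ) -> tuple[float, float]:
    """(endo, epi) radius in mm for one slice at one cardiac phase.

    Wall cross-section area is conserved: epi^2 = endo^2 + ring constant.
    """
    f = slice_scale(config, slice_index)
    endo_ed = config.endo_radius_ed_mm * config.infarct_dilation * f
    ring = (config.epi_radius_ed_mm ** 2 - config.endo_radius_ed_mm ** 2) * f * f
    endo = endo_ed * float(contraction(config, cardiac_phase))
    epi = float(np.sqrt(endo * endo + ring))
    return endo, epi


def _in_infarct_sector(config: PhantomConfig, theta_deg) -> np.ndarray:
    d = np.mod(np.asarray(theta_deg) - config.infarct_center_deg + 180.0, 360.0) - 180.0
    return np.abs(d) <= config.infarct_extent_deg / 2.0


def wall_thickness_at(config: PhantomConfig, cardiac_phase: float,
                      slice_index: int, theta_deg) -> np.ndarray:
    """Analytic wall thickness (mm) at image angle(s) theta."""
    endo, epi = lv_radii(config, cardiac_phase, slice_index)
    w = np.full(np.shape(theta_deg), epi - endo, dtype=float)
    if config.infarct:
        w = np.where(_in_infarct_sector(config, theta_deg),
                     config.infarct_thinning * (epi - endo), w)
    return w


def cardiac_phase_at(config: PhantomConfig, t_ms) -> np.ndarray:
    """Cardiac phase in [0, 1) at scan time t, with slow sinusoidal
    heart-rate variability (a constant-rate heart phase-locks with the
    repeating line sweep for unlucky rate/TR ratios; real hearts do not)."""
    t = np.asarray(t_ms, dtype=float)
    f0 = config.heart_rate_bpm / 60000.0
    a, T = config.hrv_amplitude, config.hrv_period_ms
    phase = f0 * t + f0 * a * T / (2 * np.pi) * np.sin(2 * np.pi * t / T)
    return np.mod(phase, 1.0)


def resp_phase_at(config: PhantomConfig, t_ms) -> np.ndarray:
    """Respiratory phase in [0, 1) with slow rate variability."""
    t = np.asarray(t_ms, dtype=float)
    f0 = config.resp_rate_bpm / 60000.0
    a, T = config.rrv_amplitude, config.rrv_period_ms
    phase = f0 * t + f0 * a * T / (2 * np.pi) * np.sin(2 * np.pi * t / T)
    return np.mod(phase, 1.0)


def resp_displacement(config: PhantomConfig, resp_phase) -> np.ndarray:
    """Rigid displacement magnitude (mm) over the respiratory cycle.

    A narrow Gaussian bump centered at phase 0.5; outside the central ~25%
    window the heart is essentially at rest.
    """
    p = np.asarray(resp_phase, dtype=float)
    return config.resp_amplitude_mm * np.exp(-((p - 0.5) / config.resp_sigma) ** 2)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _soft_mask(signed_dist_px: np.ndarray, width_px: float = 0.8) -> np.ndarray:
    """Anti-aliased indicator: 1 inside (positive distance), 0 outside."""
    return np.clip(signed_dist_px / width_px + 0.5, 0.0, 1.0)


def _paint(img: np.ndarray, alpha: np.ndarray, value: float) -> None:
    img *= (1.0 - alpha)
    img += value * alpha


def make_heart_frame(config: PhantomConfig, cardiac_phase: float,
                     resp_phase: float, slice_index: int) -> np.ndarray:
    """Render one 2D short-axis frame (real-valued tissue intensity).

    The whole scene is rigidly shifted by the respiratory displacement.
    """
    if not (0 <= cardiac_phase < 1) or not (0 <= resp_phase < 1):
        raise PhantomError("cardiac and respiratory phases must lie in [0, 1)")
    if not 0 <= slice_index < config.n_slices:
        raise PhantomError(f"slice index {slice_index} out of range")

    n = config.matrix
    px = config.pixel_mm
    d = resp_displacement(config, resp_phase)
    dy = d * config.resp_axis[0]
    dx = d * config.resp_axis[1]

    coord = (np.arange(n) - n // 2) * px
    yy = coord[:, None] - dy
    xx = coord[None, :] - dx

    img = np.zeros((n, n))
    w = 0.8 * px

    # torso
    by, bx = config.body_radii_mm
    body_d = 1.0 - np.sqrt((yy / by) ** 2 + (xx / bx) ** 2)
    _paint(img, _soft_mask(body_d * min(by, bx) / px * px, w), config.intensity_background)

    cy, cx = config.lv_center_mm
    f = slice_scale(config, slice_index)
    endo, epi = lv_radii(config, cardiac_phase, slice_index)
    if endo >= epi:
        raise PhantomError("degenerate geometry: endocardial >= epicardial radius")

    if config.include_rv:
        scale = float(contraction(config, cardiac_phase))
        rv_cy = cy + 0.3
        rv_cx = cx - (endo + 1.2)
        rv_r = (1.3 * f + 0.2) * (0.75 + 0.25 * scale)
        r_rv = np.sqrt((yy - rv_cy) ** 2 + (xx - rv_cx) ** 2)
        _paint(img, _soft_mask(rv_r + 0.3 - r_rv, w), config.intensity_myocardium)
        _paint(img, _soft_mask(rv_r - r_rv, w), config.intensity_blood)

    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    theta = np.degrees(np.arctan2(yy - cy, xx - cx))
    epi_eff = endo + wall_thickness_at(config, cardiac_phase, slice_index, theta)
    _paint(img, _soft_mask(epi_eff - r, w), config.intensity_myocardium)
    _paint(img, _soft_mask(endo - r, w), config.intensity_blood)
    return img


def time_averaged_frame(config: PhantomConfig, slice_index: int,
                        n_phases: int = 24) -> np.ndarray:
    """Cardiac-cycle-averaged frame at respiratory rest (calibration contrast)."""
    acc = np.zeros((config.matrix, config.matrix))
    for k in range(n_phases):
        acc += make_heart_frame(config, k / n_phases, 0.0, slice_index)
    return acc / n_phases


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def compute_ground_truth(config: PhantomConfig, n_phases: int = 10) -> PhantomGroundTruth:
    """Closed-form cavity/myocardial volumes, mass and wall-thickness profiles.

    Volumes come from the analytic cylinder-stack geometry, not from voxel
    counting; mass applies the 1.05 mg/mm^3 myocardial density at ED.
    """
    if n_phases < 2:
        raise PhantomError("need at least two cardiac phases")
    phases = np.arange(n_phases) / n_phases
    dz = config.slice_thickness_mm
    sector = config.infarct_extent_deg / 360.0 if config.infarct else 0.0
    tf = config.infarct_thinning

    cavity = np.zeros(n_phases)
    myo = np.zeros(n_phases)
    profiles = np.zeros((n_phases, 24))
    angles = np.arange(24) * 15.0
    mid = config.n_slices // 2
    for k, phi in enumerate(phases):
        for s in range(config.n_slices):
            endo, epi = lv_radii(config, phi, s)
            cavity[k] += np.pi * endo * endo * dz
            healthy_ring = np.pi * (epi * epi - endo * endo)
            if sector > 0:
                thin_epi = endo + tf * (epi - endo)
                thin_ring = np.pi * (thin_epi * thin_epi - endo * endo)
                myo[k] += ((1 - sector) * healthy_ring + sector * thin_ring) * dz
            else:
                myo[k] += healthy_ring * dz
        profiles[k] = wall_thickness_at(config, phi, mid, angles)

    ed = int(np.argmax(cavity))
    es = int(np.argmin(cavity))
    return PhantomGroundTruth(
        phases=phases,
        cavity_volume_ul=cavity,
        myocardial_volume_ul=myo,
        lv_mass_mg=float(myo[ed] * MYOCARDIAL_DENSITY_MG_PER_MM3),
        wall_thickness_mm=profiles,
        ed_index=ed,
        es_index=es,
    )


def binned_cavity_volumes(config: PhantomConfig, n_frames: int = 10,
                          trigger_phase: float = 0.5, n_sub: int = 20
                          ) -> np.ndarray:
    """Analytic cavity volume averaged over each retrospective cardiac bin.

    A gated cine frame is the average of the heart over one n-th of the
    cycle starting at the trigger, so the right reference for volumes read
    off a cine is the bin-averaged truth, not the instantaneous one.  The
    navigator of this phantom peaks at end-systole, hence the default
    trigger phase of 0.5.
    """
    dz = config.slice_thickness_mm
    vols = np.zeros(n_frames)
    for f in range(n_frames):
        phis = trigger_phase + (f + (np.arange(n_sub) + 0.5) / n_sub) / n_frames
        acc = 0.0
        for phi in np.mod(phis, 1.0):
            for s in range(config.n_slices):
                endo, _ = lv_radii(config, phi, s)
                acc += np.pi * endo * endo * dz
        vols[f] = acc / n_sub
    return vols


# ---------------------------------------------------------------------------
# coils and noise
# ---------------------------------------------------------------------------

def simulate_coils(n_coils: int, matrix: int, fov_mm: float,
                   ring_radius_mm: float = 12.0, falloff_mm: float = 7.0,
                   start_angle_deg: float = 20.0,
                   phase_cycles: float = 1.0) -> CoilModel:
    """Smooth complex sensitivities of a cylindrical surface array.

    Elements sit on a circle around the FOV center; magnitude decays
    exponentially with distance from each element, phase is a linear ramp
    along the element's look direction plus a per-element offset.  Maps are
    normalized so the maximum sum-of-squares magnitude is 1.
    """
    if n_coils < 1:
        raise PhantomError("need at least one coil element")
    coord = (np.arange(matrix) - (matrix - 1) / 2.0) * (fov_mm / matrix)
    yy, xx = coord[:, None], coord[None, :]
    angles = start_angle_deg + 360.0 * np.arange(n_coils) / n_coils
    maps = np.empty((n_coils, matrix, matrix), dtype=complex)
    for c, a in enumerate(np.deg2rad(angles)):
        py, px_ = ring_radius_mm * np.sin(a), ring_radius_mm * np.cos(a)
        dist = np.sqrt((yy - py) ** 2 + (xx - px_) ** 2)
        mag = np.exp(-dist / falloff_mm) if np.isfinite(falloff_mm) else np.ones_like(dist)
        phase = 2 * np.pi * phase_cycles * (np.cos(a) * xx + np.sin(a) * yy) / fov_mm + a
        maps[c] = mag * np.exp(1j * phase)
    sos = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    maps /= sos.max()
    return CoilModel(maps=maps, center_angles_deg=angles,
                     ring_radius_mm=ring_radius_mm, falloff_mm=falloff_mm)


def default_noise_covariance(n_coils: int, sigma: float = 1.0,
                             rho: float = 0.25, gamma: float = 0.5) -> np.ndarray:
    """Hermitian PSD coil noise covariance with AR(1)-like correlation."""
    j, k = np.meshgrid(np.arange(n_coils), np.arange(n_coils), indexing="ij")
    return sigma ** 2 * (rho ** np.abs(j - k)) * np.exp(1j * gamma * (j - k))


def _check_covariance(psi: np.ndarray) -> np.ndarray:
    psi = np.asarray(psi, dtype=complex)
    if not np.allclose(psi, psi.conj().T, atol=1e-10):
        raise PhantomError("noise covariance must be Hermitian")
    w = np.linalg.eigvalsh(psi)
    if w.min() < -1e-10 * max(w.max(), 1.0):
        raise PhantomError("noise covariance must be positive semi-definite")
    return psi


def correlated_noise(psi: np.ndarray, shape: tuple, rng: np.random.Generator
                     ) -> np.ndarray:
    """Complex Gaussian noise with coil covariance ``psi`` on the first axis."""
    n_coils = psi.shape[0]
    z = (rng.standard_normal((n_coils,) + shape)
         + 1j * rng.standard_normal((n_coils,) + shape)) / np.sqrt(2.0)
    w, v = np.linalg.eigh(psi)
    root = (v * np.sqrt(np.clip(w, 0, None))) @ v.conj().T
    return np.tensordot(root, z, axes=(1, 0))


# ---------------------------------------------------------------------------
# navigator model
# ---------------------------------------------------------------------------

class NavigatorModel:
    """Self-gating navigator: complex sum of a weighted slab image.

    The slab is the mid-ventricular slice seen through an off-center
    Gaussian receive weighting, so cardiac contraction (cavity area) and
    the respiratory shift both modulate the complex sum.  A lookup table
    over (cardiac phase x respiratory phase) keeps per-TR evaluation cheap.
    This waveform is a stand-in for a scanner's navigator echo, not a model
    of any vendor's signal processing.
    """

    def __init__(self, config: PhantomConfig, grid: int = 32,
                 n_cardiac: int = 96, n_resp: int = 25, carrier_rad: float = 0.7):
        self.config = config
        self.n_cardiac = n_cardiac
        self.n_resp = n_resp
        small = PhantomConfig(**{**config.to_dict(), "matrix": grid})
        px = small.pixel_mm
        coord = (np.arange(grid) - grid // 2) * px
        wy = config.lv_center_mm[0] + 3.0
        wx = config.lv_center_mm[1] + 2.0
        weight = np.exp(-(((coord[:, None] - wy) ** 2 + (coord[None, :] - wx) ** 2)
                          / (2 * 5.0 ** 2)))
        table = np.empty((n_cardiac, n_resp))
        mid = config.n_slices // 2
        for qc in range(n_cardiac):
            for qr in range(n_resp):
                frame = make_heart_frame(small, qc / n_cardiac, qr / n_resp, mid)
                table[qc, qr] = float((weight * frame).sum())
        self.table = table * np.exp(1j * carrier_rad)

    def sample(self, cardiac_phase: np.ndarray, resp_phase: np.ndarray) -> np.ndarray:
        qc = np.mod(np.round(np.asarray(cardiac_phase) * self.n_cardiac).astype(int),
                    self.n_cardiac)
        qr = np.mod(np.round(np.asarray(resp_phase) * self.n_resp).astype(int),
                    self.n_resp)
        return self.table[qc, qr]


# ---------------------------------------------------------------------------
# acquisition
# ---------------------------------------------------------------------------

def acquire_kspace(config: PhantomConfig, protocol: AcquisitionProtocol,
                   coils: CoilModel, noise_cov: Optional[np.ndarray] = None,
                   seed: Optional[int] = None, n_cardiac_quant: int = 96,
                   navigator_model: Optional[NavigatorModel] = None,
                   nav_noise_frac: float = 0.005) -> KSpaceSeries:
    """Simulate the continuously-running self-gated multi-slice acquisition.

    Slices are swept sequentially; within a slice, each repetition acquires
    the (possibly reduced) phase-encode line set in linear bottom-to-top
    order, one line per TR, with the timestamp advancing by TR.  Each line
    is a row of the centered 2D DFT of (sensitivity x current heart frame),
    with the respiratory shift applied as a k-space phase ramp and
    correlated complex Gaussian noise added per sample.  One navigator
    sample is recorded per TR.

    The heart frame is quantized to ``n_cardiac_quant`` cardiac phases so
    coil k-spaces can be precomputed per slice.
    """
    n = config.matrix
    if protocol.matrix != (n, n):
        raise ProtocolError(
            f"protocol matrix {protocol.matrix} does not match phantom grid {n}")
    if coils.maps.shape[-1] != n:
        raise PhantomError("coil maps do not match the phantom grid")

    psi = None
    if noise_cov is not None:
        psi = _check_covariance(noise_cov)
        if psi.shape[0] != coils.n_coils:
            raise PhantomError("noise covariance size does not match coil count")
        if np.abs(psi).max() > 0 and seed is None:
            raise PhantomError("a seed is required for a noisy simulation")
    rng = np.random.default_rng(seed)

    pattern = phase_encode_pattern(protocol.n_pe, protocol.acceleration)
    n_per_rep = len(pattern)
    lines_per_slice = n_per_rep * protocol.repetitions
    n_lines = lines_per_slice * protocol.n_slices
    tr = protocol.tr_ms
    px = config.pixel_mm

    nav_model = navigator_model or NavigatorModel(config, n_cardiac=n_cardiac_quant)

    data = np.empty((coils.n_coils, n_lines, protocol.n_readout), dtype=np.complex64)
    table = np.empty(n_lines, dtype=LINE_TABLE_DTYPE)
    navigator = np.empty(n_lines, dtype=np.complex64)

    ramp_f_ro = np.arange(protocol.n_readout) - protocol.n_readout // 2
    q_levels = n_cardiac_quant

    pos = 0
    for s in range(protocol.n_slices):
        # coil k-space cache for this slice over quantized cardiac phases
        cache = np.empty((q_levels, coils.n_coils, n, protocol.n_readout),
                         dtype=np.complex64)
        for q in range(q_levels):
            frame = make_heart_frame(config, q / q_levels, 0.0, s)
            cache[q] = cfft2(coils.maps * frame[None])

        t = (np.arange(lines_per_slice) + s * lines_per_slice) * tr
        cphase = cardiac_phase_at(config, t)
        rphase = resp_phase_at(config, t)
        q_idx = np.mod(np.round(cphase * q_levels).astype(int), q_levels)
        pe_idx = np.tile(pattern, protocol.repetitions)
        d = resp_displacement(config, rphase)
        dy_px = d * config.resp_axis[0] / px
        dx_px = d * config.resp_axis[1] / px

        lines = cache[q_idx, :, pe_idx, :]            # (lines_per_slice, C, n_ro)
        ramp_pe = np.exp(-2j * np.pi * (pe_idx - n // 2) * dy_px / n)
        ramp_ro = np.exp(-2j * np.pi * ramp_f_ro[None, :] * dx_px[:, None]
                         / protocol.n_readout)
        lines = lines * (ramp_pe[:, None, None] * ramp_ro[:, None, :])
        if psi is not None and np.abs(psi).max() > 0:
            sigma_k = config.noise_sigma_image * n
            noise = correlated_noise(psi, (lines_per_slice, protocol.n_readout), rng)
            lines = lines + sigma_k * np.moveaxis(noise, 0, 1)

        sl = slice(pos, pos + lines_per_slice)
        data[:, sl, :] = np.moveaxis(lines, 1, 0)
        table["slice"][sl] = s
        table["pe"][sl] = pe_idx
        table["t_ms"][sl] = t
        nav = nav_model.sample(cphase, rphase)
        nav_scale = np.abs(nav_model.table).mean()
        nav_noise = (rng.standard_normal(lines_per_slice)
                     + 1j * rng.standard_normal(lines_per_slice)) / np.sqrt(2)
        navigator[sl] = nav + nav_noise_frac * nav_scale * nav_noise
        pos += lines_per_slice

    return KSpaceSeries(
        data=data, line_table=table, navigator=navigator, protocol=protocol,
        noise_cov=psi if psi is not None else np.zeros((coils.n_coils, coils.n_coils),
                                                       dtype=complex),
        meta={"pattern": pattern, "heart_rate_bpm": config.heart_rate_bpm,
              "resp_rate_bpm": config.resp_rate_bpm},
    )


def acquire_calibration(config: PhantomConfig, coils: CoilModel,
                        n_pe_lowres: int = 32, noise_sigma: float = 0.002,
                        seed: Optional[int] = None) -> np.ndarray:
    """Low-resolution time-averaged coil images for sensitivity estimation.

    Emulates the separate calibration scan: full readout resolution, a
    reduced central phase-encode window, cardiac-cycle-averaged contrast.
    Returns complex images (n_coils, N, N) zero-fill interpolated to the
    target grid.
    """
    from .fourier import cifft2

    n = config.matrix
    rng = np.random.default_rng(seed)
    avg = np.stack([time_averaged_frame(config, s) for s in range(config.n_slices)])
    mid = config.n_slices // 2
    k = cfft2(coils.maps * avg[mid][None])
    lo = n // 2 - n_pe_lowres // 2
    k_low = np.zeros_like(k)
    k_low[:, lo:lo + n_pe_lowres, :] = k[:, lo:lo + n_pe_lowres, :]
    if noise_sigma > 0:
        k_low[:, lo:lo + n_pe_lowres, :] += noise_sigma * n * (
            rng.standard_normal((coils.n_coils, n_pe_lowres, n))
            + 1j * rng.standard_normal((coils.n_coils, n_pe_lowres, n))
        ) / np.sqrt(2)
    return cifft2(k_low)


def acquire_noise_scan(psi: np.ndarray, n_samples: int,
                       seed: Optional[int] = None) -> np.ndarray:
    """Pure-noise samples (n_coils, n_samples) for covariance estimation."""
    psi = _check_covariance(psi)
    rng = np.random.default_rng(seed)
    return correlated_noise(psi, (n_samples,), rng)


def estimate_noise_covariance(samples: np.ndarray) -> np.ndarray:
    """Sample covariance across coils of a noise-only acquisition."""
    x = samples - samples.mean(axis=1, keepdims=True)
    return (x @ x.conj().T) / x.shape[1]
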