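"""Coil sensitivity estimation and regularized SENSE reconstruction.

Sensitivity maps are estimated by dividing time-averaged single-coil
images by a sum-of-squares reference whose phase is the argument of the
coil sum (so the reference keeps a meaningful phase without a body-coil
scan).  Regions of mere noise are excluded by a noise-level-adapted mask,
tau = MEAN(S_noise) + f * SD(S_noise), and the maps are extrapolated
beyond the object support by iterative region growing.

Unfolding solves, per fully-sampled readout column, the regularized normal
equations (E^H Psi^-1 E + lambda I) x = E^H Psi^-1 y, where E stacks the
sampled phase-encode Fourier rows times the coil sensitivities and Psi is
the coil noise covariance (applied by pre-whitening).  Uniform integer
acceleration reduces to the classic per-pixel-group unfolding (a fast
path); arbitrary patterns, including fractional R, go through the general
per-column solve.  The geometry factor is the unregularized
g = sqrt([(E^H Psi^-1 E)^-1]_pp [E^H Psi^-1 E]_pp).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .containers import BinnedKSpace, CineStack
from .fourier import cifft
from .protocol import AcquisitionProtocol, uniform_stride


class ReconError(RuntimeError):
    pass


@dataclass
class NoiseStats:
    """Moments of a pure-noise region used for the signal mask."""

    mean: float
    sd: float
    factor: float = 2.0

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.factor <= 0:
            raise ValueError("mask factor must be positive")

    @property
    def threshold(self) -> float:
        return self.mean + self.factor * self.sd

    @classmethod
    def from_region(cls, magnitude: np.ndarray, region: np.ndarray,
                    factor: float = 2.0) -> "NoiseStats":
        vals = np.abs(magnitude)[region]
        if vals.size == 0:
            raise ValueError("empty noise region")
        return cls(mean=float(vals.mean()), sd=float(vals.std()), factor=factor)


@dataclass
class SensitivityMaps:
    maps: np.ndarray          # (n_coils, N, N) complex
    mask: np.ndarray          # object support
    reference_magnitude: np.ndarray
    reference_phase: np.ndarray

    def __post_init__(self):
        if not np.any(self.mask):
            raise ReconError("empty support mask")
        if not np.all(np.isfinite(self.maps[:, self.mask])):
            raise ReconError("non-finite sensitivity inside the support mask")


@dataclass
class ReconResult:
    image: np.ndarray                  # complex (n_pe, n_readout)
    g_map: Optional[np.ndarray]
    acceleration: float
    lam: float

    def __post_init__(self):
        if self.g_map is not None:
            finite = np.isfinite(self.g_map)
            if np.any(self.g_map[finite] < 1 - 1e-6):
                raise ReconError("g-factor below 1 - 1e-6: inconsistent encoding")


# ---------------------------------------------------------------------------
# reference and masking
# ---------------------------------------------------------------------------

def sos_reference(coil_images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum-of-squares magnitude and coil-sum phase of single-coil images."""
    imgs = np.asarray(coil_images)
    if imgs.ndim < 3 or imgs.shape[0] < 1:
        raise ValueError("expected a (n_coils, ..., N, N) stack")
    mag = np.sqrt((np.abs(imgs) ** 2).sum(axis=0))
    phase = np.angle(imgs.sum(axis=0))
    return mag, phase


def noise_mask(reference_magnitude: np.ndarray, stats: NoiseStats) -> np.ndarray:
    """Signal mask: pixels above tau = MEAN + f*SD, largest connected
    component, holes closed."""
    raw = np.abs(reference_magnitude) > stats.threshold
    if not np.any(raw):
        return raw
    labels, n = ndimage.label(raw)
    if n > 1:
        sizes = ndimage.sum_labels(raw, labels, index=np.arange(1, n + 1))
        raw = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(raw)


def _region_grow(maps: np.ndarray, mask: np.ndarray,
                 margin: Optional[int] = None) -> np.ndarray:
    """Extrapolate maps outside ``mask`` by iterative nearest-neighbor averaging."""
    out = maps.copy()
    known = mask.copy()
    kernel = np.ones((3, 3))
    steps = 0
    while not known.all():
        counts = ndimage.convolve(known.astype(float), kernel, mode="constant")
        new = (counts > 0) & ~known
        if not np.any(new):
            break
        for c in range(out.shape[0]):
            acc_r = ndimage.convolve(np.where(known, out[c].real, 0.0), kernel,
                                     mode="constant")
            acc_i = ndimage.convolve(np.where(known, out[c].imag, 0.0), kernel,
                                     mode="constant")
            out[c][new] = (acc_r[new] + 1j * acc_i[new]) / counts[new]
        known |= new
        steps += 1
        if margin is not None and steps >= margin:
            break
    return out


def _masked_smooth(maps: np.ndarray, mask: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing normalized by the mask so edges do not bleed."""
    w = ndimage.gaussian_filter(mask.astype(float), sigma)
    out = np.empty_like(maps)
    for c in range(maps.shape[0]):
        r = ndimage.gaussian_filter(np.where(mask, maps[c].real, 0.0), sigma)
        i = ndimage.gaussian_filter(np.where(mask, maps[c].imag, 0.0), sigma)
        out[c] = np.where(w > 1e-6, (r + 1j * i) / np.maximum(w, 1e-6), 0.0)
    return out


def estimate_sensitivities(coil_images: np.ndarray, stats: NoiseStats,
                           smooth_sigma: float = 1.0,
                           grow_margin: Optional[int] = None,
                           min_rel_signal: float = 0.15) -> SensitivityMaps:
    """Relative sensitivity maps from (zero-fill interpolated) coil images.

    map_c = I_c / (SOS magnitude * exp(i * coil-sum phase)) inside the
    noise-adapted mask, lightly smoothed, then extrapolated by region
    growing (``grow_margin`` pixels; None grows until the grid is full).

    The division itself is restricted to pixels whose reference magnitude
    exceeds ``min_rel_signal`` times its 99th percentile: near-zero
    reference pixels (dark blood, truncation-ringing zero crossings of the
    low-resolution scan) make the quotient blow up, and since true coil
    profiles are smooth those pixels are better recovered by the region
    growing that fills the rest of the mask anyway.
    """
    imgs = np.asarray(coil_images, dtype=complex)
    mag, phase = sos_reference(imgs)
    mask = noise_mask(mag, stats)
    if not np.any(mask):
        raise ReconError("empty mask: no object signal above the noise threshold")
    floor = max(stats.threshold, min_rel_signal * float(np.percentile(mag[mask], 99)))
    reliable = mask & (mag > floor)
    if not np.any(reliable):
        raise ReconError("no reliable high-signal pixels for the division")
    ref = mag * np.exp(1j * phase)
    maps = np.zeros_like(imgs)
    maps[:, reliable] = imgs[:, reliable] / ref[reliable]
    if smooth_sigma > 0:
        maps = _masked_smooth(maps, reliable, smooth_sigma)
    maps = _region_grow(maps, reliable, margin=grow_margin)
    return SensitivityMaps(maps=maps, mask=mask, reference_magnitude=mag,
                           reference_phase=phase)


# ---------------------------------------------------------------------------
# SENSE unfolding
# ---------------------------------------------------------------------------

def _whitener(psi: Optional[np.ndarray], n_coils: int) -> np.ndarray:
    if psi is None:
        return np.eye(n_coils, dtype=complex)
    psi = np.asarray(psi, dtype=complex)
    try:
        chol = np.linalg.cholesky(psi)
    except np.linalg.LinAlgError as e:
        raise ReconError("noise covariance is not positive definite") from e
    return np.linalg.inv(chol)


def _alias_groups(n_pe: int, stride: int) -> np.ndarray:
    """Pixel index groups (m, R) that alias onto each other at integer stride."""
    m = n_pe // stride
    u = np.arange(m)
    r0 = (u - m // 2 + n_pe // 2) % m
    return r0[:, None] + m * np.arange(stride)[None, :]


def _solve_batched(A: np.ndarray, b: np.ndarray, lam: float) -> np.ndarray:
    r = A.shape[-1]
    if lam > 0:
        A = A + lam * np.eye(r)
    try:
        if b.ndim == A.ndim - 1:  # batched vector right-hand side
            return np.linalg.solve(A, b[..., None])[..., 0]
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError as e:
        raise ReconError(
            "singular SENSE system (e.g. identical coil maps) with lambda=0; "
            "use a positive regularization weight") from e


def sense_unfold(kspace: np.ndarray, maps: np.ndarray, pattern: np.ndarray,
                 psi: Optional[np.ndarray] = None, lam_rel: float = 1e-3,
                 compute_g: bool = False, acceleration: Optional[float] = None
                 ) -> ReconResult:
    """Reconstruct one 2D frame from undersampled Cartesian k-space.

    kspace: (n_coils, n_sampled, n_readout) rows at phase-encode indices
    ``pattern`` of a centered n_pe x n_readout k-space; maps: (n_coils,
    n_pe, n_readout).  lam_rel scales Tikhonov regularization by the mean
    diagonal of E^H Psi^-1 E (0 disables it).
    """
    kspace = np.asarray(kspace, dtype=complex)
    maps = np.asarray(maps, dtype=complex)
    n_coils, n_samp, n_ro = kspace.shape
    n_pe = maps.shape[1]
    if len(pattern) != n_samp:
        raise ReconError("sampling pattern does not match the k-space line count")
    if acceleration is None:
        acceleration = n_pe / n_samp

    white = _whitener(psi, n_coils)
    y = np.tensordot(white, kspace, axes=(1, 0))
    sw = np.tensordot(white, maps, axes=(1, 0))
    proj = cifft(y, axis=-1)                      # along fully-sampled readout

    stride = uniform_stride(np.asarray(pattern), n_pe)
    if stride is not None:
        image, g = _unfold_uniform(proj, sw, n_pe, stride, lam_rel, compute_g)
    else:
        image, g = _unfold_general(proj, sw, np.asarray(pattern), n_pe, lam_rel,
                                   compute_g)
    lam_val = float(lam_rel)
    return ReconResult(image=image, g_map=g, acceleration=float(acceleration),
                       lam=lam_val)


def _unfold_uniform(proj: np.ndarray, maps_w: np.ndarray, n_pe: int, stride: int,
                    lam_rel: float, compute_g: bool
                    ) -> tuple[np.ndarray, Optional[np.ndarray]]:
    n_coils, m, n_ro = proj.shape
    groups = _alias_groups(n_pe, stride)          # (m, R)
    a = cifft(proj, axis=1)                       # aliased images (C, m, n_ro)

    S = maps_w[:, groups, :]                      # (C, m, R, n_ro)
    S = np.moveaxis(S, (0, 3), (2, 1))            # (m, n_ro, C, R)
    A = np.einsum("mxcr,mxcs->mxrs", S.conj(), S)
    b = np.einsum("mxcr,cmx->mxr", S.conj(), a)
    lam = lam_rel * float(np.einsum("mxrr->", A).real / (A.shape[0] * A.shape[1]
                                                         * A.shape[2]))
    if lam_rel > 0 and lam <= 0:
        lam = lam_rel
    x = _solve_batched(A, b, lam if lam_rel > 0 else 0.0)

    image = np.empty((n_pe, n_ro), dtype=complex)
    image[groups.reshape(-1), :] = x.transpose(0, 2, 1).reshape(-1, n_ro)

    g = None
    if compute_g:
        g = np.empty((n_pe, n_ro))
        diagA = np.einsum("mxrr->mxr", A).real
        try:
            Ainv = np.linalg.inv(A)
            diagAinv = np.einsum("mxrr->mxr", Ainv).real
            gvals = np.sqrt(np.maximum(diagAinv * diagA, 0.0))
        except np.linalg.LinAlgError:
            gvals = np.empty(A.shape[:3])
            for i in range(A.shape[0]):
                for j in range(A.shape[1]):
                    try:
                        gvals[i, j] = np.sqrt(np.maximum(
                            np.diag(np.linalg.inv(A[i, j])).real
                            * np.diag(A[i, j]).real, 0.0))
                    except np.linalg.LinAlgError:
                        gvals[i, j] = np.inf
        g[groups.reshape(-1), :] = gvals.transpose(0, 2, 1).reshape(-1, n_ro)
    return image, g


def _unfold_general(proj: np.ndarray, maps_w: np.ndarray, pattern: np.ndarray,
                    n_pe: int, lam_rel: float, compute_g: bool
                    ) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Per-column solve for arbitrary (e.g. fractional-R) line sets."""
    n_coils, n_samp, n_ro = proj.shape
    f = (pattern - n_pe // 2)[:, None]
    ypix = (np.arange(n_pe) - n_pe // 2)[None, :]
    F = np.exp(-2j * np.pi * f * ypix / n_pe)     # (n_samp, n_pe)
    G = F.conj().T @ F                            # (n_pe, n_pe)

    image = np.empty((n_pe, n_ro), dtype=complex)
    g = np.empty((n_pe, n_ro)) if compute_g else None
    Fh = F.conj().T
    for x in range(n_ro):
        s = maps_w[:, :, x]                       # (C, n_pe)
        C = np.einsum("cy,cz->yz", s.conj(), s)
        A = G * C
        b = np.einsum("cy,cy->y", s.conj(), np.tensordot(proj[:, :, x], Fh,
                                                         axes=(1, 1)))
        lam = lam_rel * float(np.trace(A).real / n_pe)
        image[:, x] = _solve_batched(A, b, lam if lam_rel > 0 else 0.0)
        if compute_g:
            try:
                Ainv = np.linalg.inv(A)
                g[:, x] = np.sqrt(np.maximum(
                    np.diag(Ainv).real * np.diag(A).real, 0.0))
            except np.linalg.LinAlgError:
                g[:, x] = np.inf
    return image, g


def g_factor_map(maps: np.ndarray, pattern: np.ndarray, n_pe: int,
                 psi: Optional[np.ndarray] = None) -> np.ndarray:
    """Unregularized SENSE geometry-factor map for a sampling pattern."""
    maps = np.asarray(maps, dtype=complex)
    white = _whitener(psi, maps.shape[0])
    sw = np.tensordot(white, maps, axes=(1, 0))
    stride = uniform_stride(np.asarray(pattern), n_pe)
    dummy = np.zeros((maps.shape[0], len(pattern), maps.shape[2]), dtype=complex)
    if stride is not None:
        _, g = _unfold_uniform(cifft(dummy, axis=-1), sw, n_pe, stride,
                               lam_rel=1.0, compute_g=True)
    else:
        _, g = _unfold_general(cifft(dummy, axis=-1), sw, np.asarray(pattern),
                               n_pe, lam_rel=1.0, compute_g=True)
    return g


def reconstruct_cine(binned: BinnedKSpace, maps: SensitivityMaps | np.ndarray,
                     psi: Optional[np.ndarray], protocol: AcquisitionProtocol,
                     lam_rel: float = 1e-3, compute_g: bool = True) -> CineStack:
    """Regularized SENSE per frame and slice; magnitude cine plus g maps."""
    m = maps.maps if isinstance(maps, SensitivityMaps) else np.asarray(maps)
    n_frames, n_slices = binned.data.shape[:2]
    n_pe = protocol.n_pe
    frames = np.empty((n_frames, n_slices, n_pe, protocol.n_readout),
                      dtype=np.float32)
    g_maps = None
    if compute_g:
        g_maps = np.empty((n_slices, n_pe, protocol.n_readout), dtype=np.float32)
        g = g_factor_map(m, binned.pattern, n_pe, psi)
        for s in range(n_slices):
            g_maps[s] = g
    for f in range(n_frames):
        for s in range(n_slices):
            res = sense_unfold(binned.data[f, s], m, binned.pattern, psi=psi,
                               lam_rel=lam_rel, compute_g=False,
                               acceleration=protocol.acceleration)
            frames[f, s] = np.abs(res.image)
    return CineStack(frames=frames, voxel_mm=protocol.voxel_mm, g_maps=g_maps,
                     acceleration=protocol.acceleration,
                     meta={"lam_rel": lam_rel,
                           "fill_fraction": binned.fill_fraction().tolist()})
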