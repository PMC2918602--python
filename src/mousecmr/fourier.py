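"""Centered discrete Fourier transforms.

k-space convention used throughout the package: the DC sample sits at
index ``N // 2`` (0-based) along every transformed axis, i.e. arrays are
stored "fftshifted".  ``cfft`` of an image whose object is centered on
pixel ``N // 2`` therefore yields a k-space with a smooth phase.
"""

from __future__ import annotations

import numpy as np


def _axes(axis):
    return axis if isinstance(axis, tuple) else (axis,)


def cfft(a: np.ndarray, axis=-1) -> np.ndarray:
    ax = _axes(axis)
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(a, axes=ax), axes=ax), axes=ax)


def cifft(a: np.ndarray, axis=-1) -> np.ndarray:
    ax = _axes(axis)
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(a, axes=ax), axes=ax), axes=ax)


def cfft2(a: np.ndarray) -> np.ndarray:
    """Centered 2D FFT over the trailing two axes."""
    return cfft(a, axis=(-2, -1))


def cifft2(a: np.ndarray) -> np.ndarray:
    return cifft(a, axis=(-2, -1))


def shift_phase_ramp(n: int, shift_px: float) -> np.ndarray:
    """Phase ramp that translates an image by ``shift_px`` pixels.

    Multiplying the centered k-space along an axis of length ``n`` by this
    ramp shifts the image by ``shift_px`` (circularly, sub-pixel exact for
    band-limited content).
    """
    f = np.arange(n) - n // 2
    return np.exp(-2j * np.pi * f * shift_px / n)


def zero_fill_resample(images: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Resample images onto ``shape`` by centered zero-filling / cropping in k-space.

    Operates on the trailing two axes; preserves image intensity scale.
    """
    src = images.shape[-2:]
    k = cfft2(np.asarray(images, dtype=complex))
    out_shape = images.shape[:-2] + shape
    out = np.zeros(out_shape, dtype=complex)

    def _sl(n_src, n_dst):
        if n_dst >= n_src:
            lo = n_dst // 2 - n_src // 2
            return slice(lo, lo + n_src), slice(0, n_src)
        lo = n_src // 2 - n_dst // 2
        return slice(0, n_dst), slice(lo, lo + n_dst)

    d0, s0 = _sl(src[0], shape[0])
    d1, s1 = _sl(src[1], shape[1])
    out[..., d0, d1] = k[..., s0, s1]
    scale = (shape[0] * shape[1]) / (src[0] * src[1])
    return cifft2(out) * scale
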