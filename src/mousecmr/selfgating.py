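"""Retrospective self-gating: navigator processing and k-space binning.

The navigator (one complex sample per TR) carries both cardiac and
respiratory modulation.  We band-pass the magnitude trace into the two
physiological bands (defaults: 5-12 Hz cardiac for a mouse heart rate of
~400-550 bpm, 0.5-3 Hz respiratory for ~60-150 breaths/min), pick peaks as
triggers, normalize each line's timestamp to a cardiac phase and bin lines
into ``n_frames`` cardiac frames plus one respiratory frame that collects
everything acquired during the motion window of the breathing cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import BinnedKSpace, KSpaceSeries


class GatingError(RuntimeError):
    pass


RESP_FRAME = -1

DEFAULT_CARDIAC_BAND_HZ = (5.0, 12.0)
DEFAULT_RESP_BAND_HZ = (0.5, 3.0)


@dataclass
class GatingAssignment:
    """Per-line cardiac frame assignment plus the timing estimates behind it.

    ``frame`` is 0..n_frames-1 or RESP_FRAME (-1) for lines diverted to the
    respiratory frame (motion window, or outside the trigger span).
    """

    frame: np.ndarray
    cardiac_phase: np.ndarray
    cardiac_triggers_ms: np.ndarray
    resp_triggers_ms: np.ndarray
    heart_rate_bpm: float
    resp_rate_bpm: float
    n_frames: int = 10
    resp_window: float = 0.25

    def __post_init__(self):
        ok = (self.frame == RESP_FRAME) | ((self.frame >= 0) & (self.frame < self.n_frames))
        if not np.all(ok):
            raise GatingError("every line must land in a cardiac bin or the respiratory frame")
        if self.heart_rate_bpm <= 0 or self.resp_rate_bpm <= 0:
            raise GatingError("estimated rates must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": self.frame, "cardiac_phase": self.cardiac_phase})


def extract_waveforms(navigator: np.ndarray, timestamps_ms: np.ndarray,
                      cardiac_band_hz: tuple[float, float] = DEFAULT_CARDIAC_BAND_HZ,
                      resp_band_hz: tuple[float, float] = DEFAULT_RESP_BAND_HZ,
                      order: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Zero-phase band-pass separation of the navigator into cardiac and
    respiratory waveforms (mean removed)."""
    if resp_band_hz[1] > cardiac_band_hz[0]:
        raise GatingError("cardiac and respiratory bands overlap")
    dt = np.median(np.diff(timestamps_ms))
    fs = 1000.0 / dt
    if fs / 2 <= cardiac_band_hz[1]:
        raise GatingError("sampling rate too low for the cardiac band")
    x = np.abs(np.asarray(navigator, dtype=complex)).astype(float)
    x = x - x.mean()
    min_len = 3 * (2 * order + 1)
    if len(x) < min_len:
        raise GatingError(f"navigator trace too short for filtering ({len(x)} samples)")
    out = []
    for band in (cardiac_band_hz, resp_band_hz):
        sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
        out.append(sps.sosfiltfilt(sos, x))
    return out[0], out[1]


def detect_triggers(waveform: np.ndarray, timestamps_ms: np.ndarray,
                    refractory_frac: float = 0.6) -> np.ndarray:
    """Local-maximum trigger picking with a refractory period.

    A first prominence-based pass estimates the median oscillation period;
    the final pass enforces a refractory distance of ``refractory_frac``
    times that period.  Returns strictly increasing trigger times (ms).
    """
    w = np.asarray(waveform, dtype=float)
    sd = w.std()
    if sd == 0 or not np.isfinite(sd):
        raise GatingError("no triggers: flat waveform")
    peaks, _ = sps.find_peaks(w, prominence=0.5 * sd)
    if len(peaks) < 2:
        raise GatingError("no triggers: fewer than two peaks found")
    dt = np.median(np.diff(timestamps_ms))
    period_ms = np.median(np.diff(timestamps_ms[peaks]))
    distance = max(1, int(round(refractory_frac * period_ms / dt)))
    peaks, _ = sps.find_peaks(w, prominence=0.3 * sd, distance=distance)
    if len(peaks) < 2:
        raise GatingError("no triggers: fewer than two peaks after refractory pass")
    t = np.asarray(timestamps_ms, dtype=float)
    # sub-sample refinement: parabola through the peak and its neighbors,
    # otherwise trigger intervals are locked to integer multiples of TR
    times = t[peaks].astype(float)
    inner = (peaks > 0) & (peaks < len(w) - 1)
    p = peaks[inner]
    denom = w[p - 1] - 2 * w[p] + w[p + 1]
    ok = denom != 0
    delta = np.zeros(len(p))
    delta[ok] = 0.5 * (w[p - 1] - w[p + 1])[ok] / denom[ok]
    delta = np.clip(delta, -0.5, 0.5)
    times[inner] = t[p] + delta * dt
    return times


def rate_from_triggers(trigger_ms: np.ndarray) -> float:
    """Mean rate in events per minute from a trigger train."""
    span = trigger_ms[-1] - trigger_ms[0]
    return 60000.0 * (len(trigger_ms) - 1) / span


def _phase_from_triggers(t_ms: np.ndarray, triggers: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Phase in [0, 1) relative to the bracketing trigger pair; validity mask."""
    idx = np.searchsorted(triggers, t_ms, side="right") - 1
    valid = (idx >= 0) & (idx < len(triggers) - 1)
    i = np.clip(idx, 0, len(triggers) - 2)
    t0 = triggers[i]
    t1 = triggers[i + 1]
    phase = np.clip((t_ms - t0) / (t1 - t0), 0.0, 1.0 - 1e-12)
    return phase, valid


def assign_phases(line_t_ms: np.ndarray, cardiac_triggers_ms: np.ndarray,
                  resp_triggers_ms: np.ndarray, n_frames: int = 10,
                  resp_window: float = 0.25) -> GatingAssignment:
    """Assign each acquired line to a cardiac frame or the respiratory frame.

    Cardiac phase is (t - t_prev) / (t_next - t_prev); the frame index is
    floor(phase * n_frames) clipped to n_frames - 1.  Lines whose
    respiratory phase falls inside the motion window (``resp_window`` of
    the cycle, centered on the respiratory trigger, i.e. the displacement
    peak) are diverted to the respiratory frame, as are lines outside the
    first/last trigger interval (conservative discard).
    """
    if len(cardiac_triggers_ms) < 2:
        raise GatingError("empty or degenerate cardiac trigger list")
    t = np.asarray(line_t_ms, dtype=float)
    phase, c_valid = _phase_from_triggers(t, np.asarray(cardiac_triggers_ms, float))
    frame = np.minimum((phase * n_frames).astype(int), n_frames - 1)

    to_resp = ~c_valid
    if len(resp_triggers_ms) >= 2 and resp_window > 0:
        rphase, r_valid = _phase_from_triggers(t, np.asarray(resp_triggers_ms, float))
        half = resp_window / 2.0
        in_window = (rphase < half) | (rphase > 1.0 - half)
        to_resp |= in_window | ~r_valid
    frame = np.where(to_resp, RESP_FRAME, frame)
    phase = np.where(c_valid, phase, np.nan)

    return GatingAssignment(
        frame=frame.astype(np.int32),
        cardiac_phase=phase,
        cardiac_triggers_ms=np.asarray(cardiac_triggers_ms, float),
        resp_triggers_ms=np.asarray(resp_triggers_ms, float),
        heart_rate_bpm=rate_from_triggers(np.asarray(cardiac_triggers_ms, float)),
        resp_rate_bpm=(rate_from_triggers(np.asarray(resp_triggers_ms, float))
                       if len(resp_triggers_ms) >= 2 else np.nan),
        n_frames=n_frames,
        resp_window=resp_window,
    )


def gate_kspace(series: KSpaceSeries,
                cardiac_band_hz: tuple[float, float] = DEFAULT_CARDIAC_BAND_HZ,
                resp_band_hz: tuple[float, float] = DEFAULT_RESP_BAND_HZ,
                n_frames: int = 10, resp_window: float = 0.25) -> GatingAssignment:
    """Navigator -> waveforms -> triggers -> per-line assignment."""
    t = series.line_table["t_ms"]
    cardiac, resp = extract_waveforms(series.navigator, t, cardiac_band_hz, resp_band_hz)
    ctrig = detect_triggers(cardiac, t)
    rtrig = detect_triggers(resp, t)
    return assign_phases(t, ctrig, rtrig, n_frames=n_frames, resp_window=resp_window)


def bin_kspace(series: KSpaceSeries, assignment: GatingAssignment,
               pattern: np.ndarray | None = None) -> BinnedKSpace:
    """Average gated lines into per-frame k-space and borrow missing bins.

    Multiple acquisitions of the same (frame, slice, line) are
    complex-averaged.  A (frame, slice, line) bin never hit is filled from
    the acquisition of that (slice, line) whose cardiac phase is nearest to
    the bin center (f + 0.5) / n_frames, excluding respiratory-frame lines.
    A (slice, line) with no cardiac-frame acquisition at all is a protocol
    bug and raises.
    """
    if pattern is None:
        pattern = series.meta.get("pattern")
        if pattern is None:
            pattern = np.unique(series.line_table["pe"])
    pattern = np.asarray(pattern)
    if len(assignment.frame) != series.n_lines:
        raise GatingError("assignment does not cover all acquired lines")

    n_frames = assignment.n_frames
    n_slices = series.protocol.n_slices
    n_coils = series.n_coils
    n_ro = series.data.shape[2]
    n_pat = len(pattern)

    pos_of_pe = -np.ones(pattern.max() + 1, dtype=int)
    pos_of_pe[pattern] = np.arange(n_pat)
    pe = series.line_table["pe"]
    if np.any(pos_of_pe[pe] < 0):
        raise GatingError("acquired phase-encode index outside the sampling pattern")
    pos = pos_of_pe[pe]
    slc = series.line_table["slice"]

    acc = np.zeros((n_frames, n_slices, n_pat, n_coils, n_ro), dtype=np.complex128)
    hits = np.zeros((n_frames, n_slices, n_pat), dtype=np.int32)

    cardiac = assignment.frame >= 0
    f = assignment.frame[cardiac]
    s = slc[cardiac]
    p = pos[cardiac]
    lines = np.moveaxis(series.data[:, cardiac, :], 0, 1)  # (n_card_lines, C, ro)
    flat = (f * n_slices + s) * n_pat + p
    np.add.at(acc.reshape(n_frames * n_slices * n_pat, n_coils, n_ro),
              flat, lines)
    np.add.at(hits.reshape(-1), flat, 1)

    nz = hits > 0
    filled = acc / np.maximum(hits, 1)[:, :, :, None, None]
    filled = np.ascontiguousarray(np.moveaxis(filled, 3, 2))  # (F, S, C, P, ro)

    # borrow never-acquired bins from the nearest cardiac phase
    fill_rows = []
    if np.any(~nz):
        phases = assignment.cardiac_phase
        line_index = np.arange(series.n_lines)
        for s_i in range(n_slices):
            for p_i in np.unique(np.argwhere(~nz[:, s_i, :])[:, 1]):
                cand = cardiac & (slc == s_i) & (pos == p_i)
                if not np.any(cand):
                    raise GatingError(
                        f"(slice {s_i}, pe {pattern[p_i]}) acquired in no cardiac "
                        "frame at all - protocol bug")
                cand_idx = line_index[cand]
                cand_phase = phases[cand]
                for f_i in np.argwhere(~nz[:, s_i, p_i]).ravel():
                    center = (f_i + 0.5) / n_frames
                    d = np.abs(cand_phase - center)
                    d = np.minimum(d, 1.0 - d)
                    j = cand_idx[np.argmin(d)]
                    filled[f_i, s_i, :, p_i, :] = series.data[:, j, :]
                    fill_rows.append({"frame": int(f_i), "slice": int(s_i),
                                      "pe": int(pattern[p_i]),
                                      "source_line": int(j),
                                      "phase_distance": float(d.min())})

    report = pd.DataFrame(fill_rows,
                          columns=["frame", "slice", "pe", "source_line",
                                   "phase_distance"])
    return BinnedKSpace(data=filled, hits=hits, pattern=pattern, fill_report=report)
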