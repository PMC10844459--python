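"""Phonatory acoustics: fundamental frequency and Bark-band loudness.

Pitch is estimated per frame by a normalized autocorrelation (NCCF)
peak search within a configurable F0 range; frames whose periodicity or
energy fall below threshold are marked unvoiced.  Loudness summarizes,
per frame, the sum of root-mean-squared spectral magnitudes grouped
into the 24 Bark critical bands, mapped to a sone-like scale by a fixed
monotone power law.  Absolute loudness calibration is arbitrary (no SPL
reference is available from a bare waveform); only relative comparisons
between recordings made under the same setup are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AudioSignal
from .timing import Segmentation

__all__ = [
    "PitchTrack",
    "LoudnessSummary",
    "estimate_pitch_track",
    "pitch_stats",
    "loudness_sone",
]

DEFAULT_FRAME_S = 0.040
DEFAULT_HOP_S = 0.010
DEFAULT_FMIN_HZ = 60.0
DEFAULT_FMAX_HZ = 400.0
DEFAULT_VOICING_THRESHOLD = 0.45
# frames whose RMS is below this fraction of full scale are unvoiced
ENERGY_FLOOR_RMS = 1e-4
# reference amplitude for the sone-like power-law map (arbitrary calibration)
LOUDNESS_REF = 2e-5
LOUDNESS_EXPONENT = 0.6


@dataclass(frozen=True)
class PitchTrack:
    """Per-frame F0 estimates; NaN marks unvoiced frames."""

    frame_times: np.ndarray  # frame centers, seconds
    f0: np.ndarray  # Hz, NaN where unvoiced
    fmin: float
    fmax: float

    @property
    def voiced_mask(self) -> np.ndarray:
        return ~np.isnan(self.f0)


@dataclass(frozen=True)
class LoudnessSummary:
    mean_loudness: float  # sone-scale, dimensionless; 0 for silence


def _frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    """Strided view of overlapping frames, shape (n_frames, frame_len)."""
    if len(x) < frame_len:
        raise ValueError(
            f"signal of {len(x)} samples is shorter than one frame ({frame_len})"
        )
    n_frames = 1 + (len(x) - frame_len) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def estimate_pitch_track(
    signal: AudioSignal,
    frame_s: float = DEFAULT_FRAME_S,
    hop_s: float = DEFAULT_HOP_S,
    fmin: float = DEFAULT_FMIN_HZ,
    fmax: float = DEFAULT_FMAX_HZ,
    voicing_threshold: float = DEFAULT_VOICING_THRESHOLD,
) -> PitchTrack:
    """Frame-wise F0 by normalized-autocorrelation peak picking.

    For each frame the normalized cross-correlation
    ``r(tau) = sum x[i] x[i+tau] / sqrt(sum_head x^2 * sum_tail x^2)``
    is evaluated over lags corresponding to [fmin, fmax]; the lag of the
    maximum, refined by parabolic interpolation, gives the frame F0.  A
    frame is voiced when the peak exceeds ``voicing_threshold`` and the
    frame RMS exceeds an absolute energy floor.
    """
    if not fmin < fmax:
        raise ValueError(f"need fmin < fmax, got {fmin} >= {fmax}")
    rate = signal.rate
    frame_len = int(round(frame_s * rate))
    hop = max(1, int(round(hop_s * rate)))
    lag_min = max(1, int(np.floor(rate / fmax)))
    lag_max = int(np.ceil(rate / fmin))
    if lag_max >= frame_len:
        raise ValueError(
            f"frame of {frame_s}s too short for fmin={fmin} Hz at {rate} Hz"
        )

    frames = _frame_signal(signal.samples, frame_len, hop)
    n_frames = frames.shape[0]
    times = (np.arange(n_frames) * hop + frame_len / 2) / rate
    f0 = np.full(n_frames, np.nan)

    rms = np.sqrt(np.mean(frames**2, axis=1))
    lags = np.arange(lag_min, lag_max + 1)

    for k in np.nonzero(rms >= ENERGY_FLOOR_RMS)[0]:
        x = frames[k]
        # numerator for all lags via FFT autocorrelation
        nfft = int(2 ** np.ceil(np.log2(2 * frame_len)))
        spec = np.fft.rfft(x, nfft)
        acorr = np.fft.irfft(spec * np.conj(spec), nfft)[: frame_len]
        # energy normalization terms
        csum = np.concatenate([[0.0], np.cumsum(x**2)])
        e_head = csum[frame_len - lags] - csum[0]
        e_tail = csum[frame_len] - csum[lags]
        denom = np.sqrt(e_head * e_tail)
        with np.errstate(invalid="ignore", divide="ignore"):
            nccf = np.where(denom > 0, acorr[lags] / denom, 0.0)
        best = float(np.max(nccf))
        if best < voicing_threshold:
            continue
        # prefer the smallest-lag local maximum near the global peak:
        # for periodic signals the NCCF is ~equal at the period and its
        # multiples, and argmax alone commits octave-down errors
        is_peak = np.ones(len(nccf), dtype=bool)
        is_peak[1:] &= nccf[1:] >= nccf[:-1]
        is_peak[:-1] &= nccf[:-1] >= nccf[1:]
        candidates = np.nonzero(is_peak & (nccf >= 0.9 * best))[0]
        peak = int(candidates[0]) if len(candidates) else int(np.argmax(nccf))
        lag = float(lags[peak])
        # parabolic refinement for sub-sample lag accuracy
        if 0 < peak < len(nccf) - 1:
            y0, y1, y2 = nccf[peak - 1], nccf[peak], nccf[peak + 1]
            denom2 = y0 - 2 * y1 + y2
            if denom2 < 0:
                lag += 0.5 * (y0 - y2) / denom2
        f0_k = rate / lag
        if fmin <= f0_k <= fmax:
            f0[k] = f0_k
    return PitchTrack(frame_times=times, f0=f0, fmin=fmin, fmax=fmax)


def _in_voiced(times: np.ndarray, seg: Segmentation) -> np.ndarray:
    mask = np.zeros(len(times), dtype=bool)
    for s, e in seg.voiced_intervals:
        mask |= (times >= s) & (times <= e)
    return mask


def pitch_stats(track: PitchTrack, seg: Segmentation) -> tuple[float, float]:
    """Mean and sample SD of F0 over voiced frames inside voiced intervals.

    Returns (NaN, NaN) when fewer than two frames qualify.
    """
    sel = track.voiced_mask & _in_voiced(track.frame_times, seg)
    vals = track.f0[sel]
    if len(vals) < 2:
        return float("nan"), float("nan")
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


def bark_traunmueller(freq_hz: np.ndarray) -> np.ndarray:
    """Critical-band rate (Bark) of a frequency via Traunmüller's formula."""
    return 26.81 * freq_hz / (1960.0 + freq_hz) - 0.53


def frame_loudness(
    frames: np.ndarray, rate: int, n_bands: int = 24
) -> np.ndarray:
    """Per-frame loudness: sum over Bark bands of the RMS spectral magnitude.

    Each Hann-windowed frame's magnitude spectrum is partitioned into
    critical bands (band b covers Bark rate [b-1, b)); per band the RMS
    of bin magnitudes is taken, band values are summed, and the sum is
    mapped to a sone-like scale by ``(p / ref) ** 0.6``.
    """
    frame_len = frames.shape[1]
    window = np.hanning(frame_len)
    # amplitude-normalized spectrum: a unit-amplitude sinusoid gives a
    # peak magnitude near 1 regardless of frame length
    mags = np.abs(np.fft.rfft(frames * window, axis=1)) / (window.sum() / 2)
    freqs = np.fft.rfftfreq(frame_len, 1.0 / rate)
    z = bark_traunmueller(freqs)
    band_idx = np.floor(z).astype(int) + 1  # band 1 covers z in [0, 1)
    out = np.zeros(frames.shape[0])
    for b in range(1, n_bands + 1):
        cols = band_idx == b
        if not cols.any():
            continue
        out += np.sqrt(np.mean(mags[:, cols] ** 2, axis=1))
    return (out / LOUDNESS_REF) ** LOUDNESS_EXPONENT


def loudness_sone(
    signal: AudioSignal,
    seg: Segmentation,
    frame_s: float = DEFAULT_FRAME_S,
    hop_s: float = DEFAULT_HOP_S,
) -> LoudnessSummary:
    """Mean sone-scale loudness over frames inside voiced intervals."""
    if len(signal.samples) == 0:
        raise ValueError("empty signal")
    rate = signal.rate
    frame_len = int(round(frame_s * rate))
    hop = max(1, int(round(hop_s * rate)))
    if len(signal.samples) < frame_len:
        raise ValueError("signal shorter than one analysis frame")
    frames = _frame_signal(signal.samples, frame_len, hop)
    times = (np.arange(frames.shape[0]) * hop + frame_len / 2) / rate
    loud = frame_loudness(frames, rate)
    sel = _in_voiced(times, seg)
    if not sel.any():
        return LoudnessSummary(0.0)
    return LoudnessSummary(float(np.mean(loud[sel])))
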