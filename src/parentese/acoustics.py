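"""Acoustic front-end: segmental and supra-segmental feature streams.

Two complementary descriptions of each utterance feed the detector:

* segmental — a matrix of per-frame Mel-frequency cepstral coefficients
  (25 ms Hamming frames, 10 ms hop, 26 Mel filters, coefficients c1..c13
  plus log-energy, pre-emphasis 0.97), capturing the short-time spectral
  envelope;
* supra-segmental — one fixed-length vector of utterance-level prosodic
  statistics over the fundamental-frequency contour (mean, sd, min, max,
  range, least-squares slope), the frame energy in dB (mean, sd, range),
  the total duration, and the voiced fraction.

F0 is estimated by short-time autocorrelation with parabolic peak
interpolation inside a 75–600 Hz search band; frames are voiced when the
normalised autocorrelation peak and the frame energy both clear their
thresholds.  Sub-harmonic (octave-down) errors are avoided by taking the
shortest candidate lag whose peak is within 15% of the global maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft
from scipy.signal import resample_poly

from .synth.audio import Utterance

TARGET_SR = 16_000
FRAME_S = 0.025
HOP_S = 0.010
F0_FRAME_S = 0.040
F0_MIN_HZ = 75.0
F0_MAX_HZ = 600.0
N_MEL = 26
N_CEPS = 13
PREEMPH = 0.97
VOICING_PEAK_THRESHOLD = 0.45
VOICING_ENERGY_FRACTION = 0.02  # of the loudest frame's RMS

F0_MISSING = np.nan


@dataclass
class SegmentalFeatures:
    features: np.ndarray  # (n_frames, N_CEPS + 1)
    frame_times: np.ndarray  # s, frame centres

    @property
    def n_frames(self) -> int:
        return self.features.shape[0]


SUPRASEG_NAMES = (
    "f0_mean", "f0_std", "f0_min", "f0_max", "f0_range", "f0_slope",
    "energy_mean_db", "energy_std_db", "energy_range_db",
    "duration_s", "voiced_fraction",
)


@dataclass
class SupraSegmentalFeatures:
    vector: np.ndarray  # len(SUPRASEG_NAMES)
    has_voicing: bool

    def as_dict(self) -> dict[str, float]:
        return dict(zip(SUPRASEG_NAMES, self.vector.tolist()))


def _as_waveform(utterance) -> np.ndarray:
    """Accept an Utterance or a bare (waveform, sr); resample to 16 kHz."""
    if isinstance(utterance, Utterance):
        x, sr = utterance.waveform, utterance.sample_rate
    else:
        x, sr = utterance
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("waveform must be a non-empty 1-d array")
    if sr < 8000:
        raise ValueError("sample rate must be >= 8 kHz")
    if sr != TARGET_SR:
        g = np.gcd(int(sr), TARGET_SR)
        x = resample_poly(x, TARGET_SR // g, int(sr) // g)
    return x


def _frame(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    if len(x) < frame_len:
        raise ValueError(f"waveform shorter than one frame ({frame_len} samples)")
    n_frames = (len(x) - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def _mel(f: np.ndarray) -> np.ndarray:
    return 2595.0 * np.log10(1.0 + f / 700.0)


def _inv_mel(m: np.ndarray) -> np.ndarray:
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def _mel_filterbank(n_fft: int, sr: int, n_mel: int) -> np.ndarray:
    edges = _inv_mel(np.linspace(_mel(np.array(0.0)), _mel(np.array(sr / 2.0)), n_mel + 2))
    bins = np.floor((n_fft + 1) * edges / sr).astype(int)
    fb = np.zeros((n_mel, n_fft // 2 + 1))
    for m in range(1, n_mel + 1):
        lo, ctr, hi = bins[m - 1], bins[m], bins[m + 1]
        for k in range(lo, ctr):
            if ctr > lo:
                fb[m - 1, k] = (k - lo) / (ctr - lo)
        for k in range(ctr, hi):
            if hi > ctr:
                fb[m - 1, k] = (hi - k) / (hi - ctr)
    return fb


def extract_segmental(utterance) -> SegmentalFeatures:
    """MFCC matrix (c1..c13 + log-energy) at 25 ms / 10 ms framing."""
    x = _as_waveform(utterance)
    pre = np.empty_like(x)
    pre[0] = x[0]
    pre[1:] = x[1:] - PREEMPH * x[:-1]

    frame_len = int(FRAME_S * TARGET_SR)
    hop = int(HOP_S * TARGET_SR)
    frames = _frame(pre, frame_len, hop)
    log_energy = np.log(np.sum(frames**2, axis=1) + 1e-12)

    n_fft = 512
    window = np.hamming(frame_len)
    spec = np.abs(rfft(frames * window, n=n_fft, axis=1)) ** 2 / n_fft
    fb = _mel_filterbank(n_fft, TARGET_SR, N_MEL)
    mel_energies = np.log(spec @ fb.T + 1e-12)
    ceps = dct(mel_energies, type=2, axis=1, norm="ortho")[:, 1 : N_CEPS + 1]

    feats = np.column_stack([ceps, log_energy])
    times = (np.arange(len(frames)) * hop + frame_len / 2) / TARGET_SR
    return SegmentalFeatures(features=feats, frame_times=times)


def estimate_f0_contour(
    utterance,
    f0_min: float = F0_MIN_HZ,
    f0_max: float = F0_MAX_HZ,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame (voiced flag, F0 Hz, frame time s) by autocorrelation.

    Unvoiced frames carry F0 = nan.  The search band must satisfy
    ``f0_min < f0_max`` and fit the frame length.
    """
    if not 0 < f0_min < f0_max:
        raise ValueError("F0 search band empty or inverted")
    x = _as_waveform(utterance)
    frame_len = int(F0_FRAME_S * TARGET_SR)
    hop = int(HOP_S * TARGET_SR)
    frames = _frame(x, frame_len, hop)
    frames = frames - frames.mean(axis=1, keepdims=True)

    lag_min = max(2, int(np.floor(TARGET_SR / f0_max)))
    lag_max = int(np.ceil(TARGET_SR / f0_min))
    if lag_max >= frame_len:
        raise ValueError("f0_min too low for the analysis frame length")

    # autocorrelation of every frame via FFT
    n_fft = int(2 ** np.ceil(np.log2(2 * frame_len)))
    spec = rfft(frames, n=n_fft, axis=1)
    ac = np.fft.irfft(np.abs(spec) ** 2, n=n_fft, axis=1)[:, : lag_max + 2]
    r0 = ac[:, 0].copy()
    r0[r0 <= 0] = 1e-12
    acn = ac / r0[:, None]

    rms = np.sqrt(np.mean(frames**2, axis=1))
    rms_threshold = VOICING_ENERGY_FRACTION * max(rms.max(), 1e-12)

    n_frames = len(frames)
    f0 = np.full(n_frames, F0_MISSING)
    voiced = np.zeros(n_frames, dtype=bool)
    band = acn[:, lag_min : lag_max + 1]
    interior = band.shape[1] - 1
    for i in range(n_frames):
        if rms[i] < rms_threshold:
            continue
        seg = band[i]
        # local maxima within the band
        peaks = np.where((seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:]))[0] + 1
        if len(peaks) == 0:
            peaks = np.array([int(np.argmax(seg))])
        best = float(seg[peaks].max())
        if best < VOICING_PEAK_THRESHOLD:
            continue
        # shortest lag within 15% of the best peak -> no octave-down errors
        cand = peaks[seg[peaks] >= 0.85 * best]
        k = int(cand.min())
        lag = lag_min + k
        if 1 <= k <= interior - 1:
            a, b, c = acn[i, lag - 1], acn[i, lag], acn[i, lag + 1]
            denom = a - 2 * b + c
            if abs(denom) > 1e-12:
                lag = lag + 0.5 * (a - c) / denom
        voiced[i] = True
        f0[i] = TARGET_SR / lag
    times = (np.arange(n_frames) * hop + frame_len / 2) / TARGET_SR
    return voiced, f0, times


def extract_suprasegmental(utterance) -> SupraSegmentalFeatures:
    """Utterance-level prosodic statistics (see module docstring).

    F0 statistics are over voiced frames only; with zero voiced frames the
    F0 fields are nan and ``has_voicing`` is False (downstream scoring then
    falls back to the class prior for this stream).
    """
    x = _as_waveform(utterance)
    duration = len(x) / TARGET_SR
    voiced, f0, times = estimate_f0_contour((x, TARGET_SR))

    frame_len = int(FRAME_S * TARGET_SR)
    hop = int(HOP_S * TARGET_SR)
    frames = _frame(x, frame_len, hop)
    energy_db = 20.0 * np.log10(np.sqrt(np.mean(frames**2, axis=1)) + 1e-10)

    has_voicing = bool(voiced.any())
    if has_voicing:
        v = f0[voiced]
        tv = times[voiced]
        slope = 0.0
        if len(v) >= 2 and np.ptp(tv) > 0:
            slope = float(np.polyfit(tv, v, 1)[0])
        f0_stats = [
            float(np.mean(v)), float(np.std(v)), float(np.min(v)),
            float(np.max(v)), float(np.ptp(v)), slope,
        ]
    else:
        f0_stats = [F0_MISSING] * 6

    vec = np.array(
        f0_stats
        + [
            float(np.mean(energy_db)),
            float(np.std(energy_db)),
            float(np.ptp(energy_db)),
            duration,
            float(np.mean(voiced)),
        ]
    )
    return SupraSegmentalFeatures(vector=vec, has_voicing=has_voicing)
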