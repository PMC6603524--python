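"""Signal conditioning, EMG-based tremor-onset labelling and windowing.

The LFP path is: polyphase downsampling to the target rate, then a
single-pass 500th-order Hamming-window FIR band-pass (2-45 Hz) with 2 s of
the recording's own edge data as warm-up padding and group-delay
compensation, so the output stays sample-aligned with the input.

The EMG path is: zero-phase (two-pass) 30 Hz high-pass of the same order,
rectification via the Hilbert-envelope (magnitude of the analytic signal),
then the 2-45 Hz FIR, which leaves the low-frequency burst envelope tremor
analysis needs.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .io import Recording, ValidationError

PADDING_S = 2.0


@dataclass
class WindowSet:
    """Equal-length, constant-hop analysis windows cut from one Recording."""

    windows: np.ndarray          # shape (n_windows, length)
    mid_times: np.ndarray        # seconds, strictly increasing
    hop: int                     # samples between window starts
    length: int                  # samples per window
    rate: float

    @property
    def n(self) -> int:
        return self.windows.shape[0]

    @property
    def hop_s(self) -> float:
        return self.hop / self.rate


def _bandpass_taps(rate: float, band: tuple[float, float], order: int) -> np.ndarray:
    return sps.firwin(order + 1, band, pass_zero=False, fs=rate, window="hamming")


def _highpass_taps(rate: float, cutoff: float, order: int) -> np.ndarray:
    if order % 2:
        order += 1  # a type-I FIR high-pass needs an odd tap count
    return sps.firwin(order + 1, cutoff, pass_zero=False, fs=rate, window="hamming")


def _check_length(n: int, order: int, pad: int) -> None:
    if n <= order + 2 * pad:
        raise ValidationError(
            f"recording of {n} samples is too short for a {order}th-order "
            f"filter with {pad}-sample padding")


def _pad_edges(x: np.ndarray, pad: int) -> np.ndarray:
    # warm the filter up on the recording's own (reflected) first/last 2 s
    return np.pad(x, pad, mode="reflect")


def _fir_single_pass(x: np.ndarray, taps: np.ndarray, rate: float) -> np.ndarray:
    pad = int(round(PADDING_S * rate))
    _check_length(x.size, taps.size - 1, pad)
    y = sps.lfilter(taps, 1.0, _pad_edges(x, pad))
    delay = (taps.size - 1) // 2
    return y[pad + delay: pad + delay + x.size]


def _fir_two_pass(x: np.ndarray, taps: np.ndarray, rate: float) -> np.ndarray:
    pad = int(round(PADDING_S * rate))
    _check_length(x.size, taps.size - 1, pad)
    y = sps.filtfilt(taps, 1.0, _pad_edges(x, pad), padlen=0)
    return y[pad: pad + x.size]


def resample_lfp(rec: Recording, target_rate: float = 125.0) -> Recording:
    """Downsample a recording to ``target_rate`` with polyphase filtering.

    Upsampling is refused: the protocol only ever reduces the rate.
    Non-integer ratios are handled by a rational polyphase approximation.
    """
    if rec.rate == target_rate:
        return rec
    if rec.rate < target_rate:
        raise ValidationError(
            f"cannot upsample from {rec.rate} Hz to {target_rate} Hz")
    frac = Fraction(target_rate / rec.rate).limit_denominator(10_000)
    out = sps.resample_poly(rec.samples, frac.numerator, frac.denominator)
    return Recording(out, rate=target_rate, role=rec.role, start_time=rec.start_time)


def bandpass_lfp(rec: Recording, band: tuple[float, float] = (2.0, 45.0),
                 order: int = 500) -> Recording:
    """Single-pass FIR band-pass with edge-data padding; length-preserving."""
    taps = _bandpass_taps(rec.rate, band, order)
    out = _fir_single_pass(rec.samples, taps, rec.rate)
    return Recording(out, rate=rec.rate, role=rec.role, start_time=rec.start_time)


def preprocess_emg(rec: Recording, hp_cutoff: float = 30.0,
                   band: tuple[float, float] = (2.0, 45.0),
                   order: int = 500) -> Recording:
    """Zero-phase 30 Hz high-pass, Hilbert-envelope rectification, 2-45 Hz FIR."""
    if rec.role != "EMG":
        raise ValidationError("preprocess_emg expects an EMG recording")
    if rec.rate <= 2 * hp_cutoff:
        raise ValidationError(
            f"rate {rec.rate} Hz too low for a {hp_cutoff} Hz high-pass")
    hp = _fir_two_pass(rec.samples, _highpass_taps(rec.rate, hp_cutoff, order), rec.rate)
    # reflect-pad before the analytic signal: the FFT-based Hilbert transform
    # wraps around and would otherwise spike the envelope at both ends
    pad = min(int(round(PADDING_S * rec.rate)), hp.size - 1)
    env = np.abs(sps.hilbert(np.pad(hp, pad, mode="reflect")))[pad: pad + hp.size]
    out = _fir_single_pass(env, _bandpass_taps(rec.rate, band, order), rec.rate)
    return Recording(out, rate=rec.rate, role="EMG", start_time=rec.start_time)


def detect_tremor_onset(emg_env: Recording, baseline_s: float = 5.0,
                        confirm_s: float = 5.0, factor: float = 3.0) -> float | None:
    """Earliest confirmed threshold crossing of the processed EMG envelope.

    The threshold is ``factor`` times the mean amplitude over the first
    ``baseline_s`` seconds (assumed atremorous). A crossing at time t only
    counts if the mean over the following ``confirm_s`` seconds, the
    half-open interval (t, t+confirm_s], also exceeds the threshold -- a
    lone spike is not an onset. Returns the onset time in seconds, or None.
    """
    x = np.abs(emg_env.samples)
    rate = emg_env.rate
    n_base = int(round(baseline_s * rate))
    n_conf = int(round(confirm_s * rate))
    if x.size <= n_base + n_conf:
        raise ValidationError("recording must be longer than baseline + confirmation")
    base_mean = float(np.mean(x[:n_base]))
    if base_mean == 0:
        raise ValidationError("baseline mean is zero; onset threshold undefined")
    thr = factor * base_mean
    # a crossing needs the full confirmation window after it; later
    # crossings cannot be confirmed and are ignored
    crossings = np.flatnonzero(x[n_base: x.size - n_conf] > thr) + n_base
    cum = np.concatenate(([0.0], np.cumsum(x)))
    for i in crossings:
        if (cum[i + 1 + n_conf] - cum[i + 1]) / n_conf > thr:
            return emg_env.start_time + i / rate
    return None


def segment_windows(rec: Recording, window_s: float = 2.0,
                    overlap_frac: float = 0.90) -> WindowSet:
    """Cut a recording into equal-length overlapping analysis windows."""
    if not 0 <= overlap_frac < 1:
        raise ValidationError("overlap_frac must be in [0, 1)")
    length = int(round(window_s * rec.rate))
    if rec.n < length:
        raise ValidationError(
            f"recording of {rec.n} samples shorter than one {length}-sample window")
    hop = int(round(length * (1 - overlap_frac)))
    if hop == 0:
        raise ValidationError("overlap too high: hop computes to zero samples")
    count = (rec.n - length) // hop + 1
    idx = np.arange(length)[None, :] + hop * np.arange(count)[:, None]
    mids = rec.start_time + (hop * np.arange(count) + length / 2) / rec.rate
    return WindowSet(windows=rec.samples[idx], mid_times=mids, hop=hop,
                     length=length, rate=rec.rate)
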