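"""ECG conditioning ahead of feature extraction.

Four stages, applied in order: cubic-spline baseline detrending, powerline
(and harmonic) notch filtering, low-pass filtering of muscle artifact, and a
time-local-variance filter that clips patient-electrode motion artifacts.

All filters are zero-phase (forward-backward IIR), so QRS fiducial points do
not shift — a hard requirement when detections are compared at a 10 ms
tolerance across sampling rates from 128 to 360 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline
from scipy.ndimage import maximum_filter1d, uniform_filter1d

from .io import MultileadSignal

__all__ = [
    "PreprocessConfig",
    "detrend_baseline",
    "notch_powerline",
    "lowpass",
    "suppress_motion_artifacts",
    "preprocess_record",
]


@dataclass
class PreprocessConfig:
    """Tunable knobs of the conditioning chain.

    powerline_hz : mains frequency (50 in Europe, 60 in the US).
    n_harmonics  : notches applied at f0, 2*f0, ... up to this count
                   (harmonics at or above Nyquist are skipped).
    lowpass_hz   : muscle-artifact low-pass cut-off; 25 Hz keeps the QRS
                   energy band (5-15 Hz) intact while removing EMG.
    spline_knot_s: spacing of baseline spline knots; 1 s tracks respiratory
                   wander without eating the ST segment.
    var_win_s    : window of the local-variance motion-artifact detector.
    var_k        : a window is flagged when its variance exceeds var_k times
                   the lead's median local variance.
    """

    powerline_hz: float = 50.0
    n_harmonics: int = 2
    lowpass_hz: float = 25.0
    spline_knot_s: float = 1.0
    var_win_s: float = 0.2
    var_k: float = 8.0

    def validate(self, fs: float) -> None:
        if self.lowpass_hz <= 0 or self.lowpass_hz >= fs / 2:
            raise ValueError(f"lowpass_hz must lie in (0, fs/2); got {self.lowpass_hz}")
        for name in ("powerline_hz", "n_harmonics", "spline_knot_s",
                     "var_win_s", "var_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _per_lead(signal: MultileadSignal, fn) -> MultileadSignal:
    out = np.column_stack([fn(signal.samples[:, i])
                           for i in range(signal.n_leads)])
    return MultileadSignal(out, signal.fs, list(signal.lead_names), signal.t0)


def detrend_baseline(signal: MultileadSignal, knot_s: float = 1.0) -> MultileadSignal:
    """Subtract a cubic-spline baseline fitted through per-window medians.

    Knots are placed every ``knot_s`` seconds; the knot value is the median
    of the samples in that window, which is insensitive to the QRS spikes.
    Records too short for a spline (< 3 knots) fall back to mean subtraction.
    """
    fs, n = signal.fs, signal.n_samples
    w = max(1, int(round(knot_s * fs)))
    n_knots = n // w
    if n_knots < 3:
        warnings.warn("record too short for spline detrending; subtracting mean")
        return _per_lead(signal, lambda x: x - x.mean())

    edges = np.arange(n_knots + 1) * w
    edges[-1] = n
    centers = (edges[:-1] + edges[1:] - 1) / 2.0

    def fn(x: np.ndarray) -> np.ndarray:
        knots = np.array([np.median(x[a:b]) for a, b in zip(edges[:-1], edges[1:])])
        baseline = CubicSpline(centers, knots)(np.arange(n))
        return x - baseline

    return _per_lead(signal, fn)


def notch_powerline(signal: MultileadSignal, f0: float = 50.0,
                    n_harmonics: int = 2, bandwidth_hz: float = 1.0) -> MultileadSignal:
    """Zero-phase notches at the mains frequency and its harmonics.

    Harmonics at or above Nyquist are skipped silently; a fundamental at or
    above Nyquist is an error.
    """
    fs = signal.fs
    if f0 >= fs / 2:
        raise ValueError(f"powerline frequency {f0} Hz >= Nyquist ({fs / 2} Hz)")
    sos_list = []
    for h in range(1, n_harmonics + 1):
        fh = h * f0
        if fh >= fs / 2:
            break
        b, a = sps.iirnotch(fh, Q=fh / bandwidth_hz, fs=fs)
        sos_list.append(sps.tf2sos(b, a))
    if not sos_list:
        return signal
    sos = np.vstack(sos_list)
    return _per_lead(signal, lambda x: sps.sosfiltfilt(sos, x))


def lowpass(signal: MultileadSignal, cutoff: float = 25.0, order: int = 4) -> MultileadSignal:
    """Zero-phase Butterworth low-pass; unit DC gain."""
    if cutoff <= 0 or cutoff >= signal.fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, fs/2)")
    sos = sps.butter(order, cutoff, btype="low", fs=signal.fs, output="sos")
    return _per_lead(signal, lambda x: sps.sosfiltfilt(sos, x))


def suppress_motion_artifacts(signal: MultileadSignal, win_s: float = 0.2,
                              k: float = 8.0, clip_k: float = 2.0) -> MultileadSignal:
    """Clip high-variance transients caused by patient-electrode motion.

    A sliding-window variance is compared against a beat-scale reference:
    the median over the lead of the rolling 1 s maximum of that variance.
    On clean ECG the reference sits at QRS level (every second contains a
    QRS), so normal beats are never flagged; motion artifacts an order of
    magnitude above the QRS exceed ``k`` times the reference.  Flagged
    samples are amplitude-clipped at ``clip_k`` times the RMS of the
    unaffected samples.  Clean regions pass through bit-identically —
    clipping, rather than blanking, avoids punching holes into the
    downstream threshold statistics.
    """
    fs = signal.fs
    w = max(3, int(round(win_s * fs)))
    beat_w = max(w, int(round(1.0 * fs)))

    def fn(x: np.ndarray) -> np.ndarray:
        m = uniform_filter1d(x, w, mode="nearest")
        m2 = uniform_filter1d(x * x, w, mode="nearest")
        var = np.maximum(m2 - m * m, 0.0)
        med = np.median(maximum_filter1d(var, beat_w, mode="nearest"))
        if med <= 0 or not np.any(var > k * med):
            return x
        flag = var > k * med
        # widen flags to the full window extent so burst edges are covered
        flag = uniform_filter1d(flag.astype(np.float64), w, mode="nearest") > 0
        clean = x[~flag]
        if clean.size == 0:
            return x
        clip = clip_k * np.sqrt(np.mean(clean ** 2))
        out = x.copy()
        out[flag] = np.clip(out[flag], -clip, clip)
        return out

    return _per_lead(signal, fn)


def preprocess_record(signal: MultileadSignal,
                      cfg: PreprocessConfig | None = None) -> MultileadSignal:
    """Full conditioning chain: detrend -> notch -> low-pass -> motion clip."""
    cfg = cfg or PreprocessConfig()
    cfg.validate(signal.fs)
    out = detrend_baseline(signal, cfg.spline_knot_s)
    out = notch_powerline(out, cfg.powerline_hz, cfg.n_harmonics)
    out = lowpass(out, cfg.lowpass_hz)
    out = suppress_motion_artifacts(out, cfg.var_win_s, cfg.var_k)
    return out
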