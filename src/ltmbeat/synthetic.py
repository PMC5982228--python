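"""Synthetic multilead ECG with known beat times and controllable noise.

The beat template is a sum of Gaussian bumps — P, Q, R, S and T waves at
fixed physiologic offsets from the R apex — so the true R-peak sample of
every beat is known analytically.  RR intervals are drawn around the mean
heart rate with configurable relative jitter.  Additive noise generators
cover the failure modes of ambulatory recordings: baseline wander,
powerline interference, muscle (EMG) noise, sparse electrode-motion
transients, and per-lead electrode disconnects.

A long-term-monitoring surrogate (``synth_ltm``) modulates noise severity
per simulated "day" (compressible to seconds for testing) to emulate the
mid-recording care degradation seen in week-long Holter studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import AnnotationSet, MultileadSignal

__all__ = ["SynthConfig", "synth_ecg", "add_noise", "synth_ltm", "NOISE_TYPES"]

NOISE_TYPES = ("baseline_wander", "powerline", "muscle", "electrode_motion",
               "disconnect")

# Gaussian wave parameters: (amplitude mV, center offset s, width sigma s)
_WAVES = {
    "P": (0.15, -0.20, 0.025),
    "Q": (-0.15, -0.045, 0.010),
    "R": (1.00, 0.0, 0.018),
    "S": (-0.25, 0.045, 0.010),
    "T": (0.35, 0.28, 0.060),
}


@dataclass
class SynthConfig:
    fs: float = 200.0
    duration_s: float = 300.0
    n_leads: int = 2
    mean_hr_bpm: float = 60.0
    hr_jitter: float = 0.05        # relative RR standard deviation
    lead_gains: list[float] | None = None
    obs_noise_mv: float = 0.005   # per-lead sensor noise floor (RMS, mV)
    noise: list[tuple] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 100:
            raise ValueError("fs must be at least 100 Hz")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 20 <= self.mean_hr_bpm <= 240:
            raise ValueError("mean_hr_bpm must lie in [20, 240]")
        if self.lead_gains is None:
            # slightly different projections per lead, as electrodes see
            # the cardiac vector from different angles
            self.lead_gains = [1.0 - 0.15 * i for i in range(self.n_leads)]
        if len(self.lead_gains) != self.n_leads:
            raise ValueError("lead_gains length must equal n_leads")


def _beat_times(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    mean_rr = 60.0 / cfg.mean_hr_bpm
    times = []
    t = 0.5 * mean_rr
    while t < cfg.duration_s - 0.25 * mean_rr:
        times.append(t)
        rr = mean_rr * (1.0 + cfg.hr_jitter * rng.standard_normal())
        t += max(0.3, rr)
    return np.asarray(times)


def synth_ecg(cfg: SynthConfig) -> tuple[MultileadSignal, AnnotationSet]:
    """Generate a clean multilead ECG and its beat annotations.

    R centers are snapped to the sample grid before the template is
    rendered, so each annotated index is exactly the per-beat maximum of
    lead 1 (all per-lead gains are positive scalings of one template).
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t_axis = np.arange(n) / cfg.fs
    beat_samples = np.round(_beat_times(cfg, rng) * cfg.fs).astype(np.int64)
    beat_samples = beat_samples[(beat_samples >= 0) & (beat_samples < n)]
    beat_samples = np.unique(beat_samples)

    base = np.zeros(n)
    for bs in beat_samples:
        t0 = bs / cfg.fs
        for amp, off, sig in _WAVES.values():
            lo = max(0, int((t0 + off - 5 * sig) * cfg.fs))
            hi = min(n, int((t0 + off + 5 * sig) * cfg.fs) + 1)
            tt = t_axis[lo:hi]
            base[lo:hi] += amp * np.exp(-0.5 * ((tt - t0 - off) / sig) ** 2)

    samples = np.column_stack([g * base for g in cfg.lead_gains])
    if cfg.obs_noise_mv > 0:
        # independent white sensor noise per electrode; keeps the lead
        # mixture full-rank, which matrix methods (PCA/ICA) rely on
        samples = samples + cfg.obs_noise_mv * rng.standard_normal(samples.shape)
    signal = MultileadSignal(samples, cfg.fs)
    ann = AnnotationSet(beat_samples, ["N"] * beat_samples.size, fs=cfg.fs)
    return signal, ann


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------

def _scale_to_snr(clean: np.ndarray, noise: np.ndarray, snr_db: float) -> np.ndarray:
    p_sig = float(np.mean(clean ** 2))
    p_noise = float(np.mean(noise ** 2))
    if p_noise == 0:
        return noise
    target = p_sig / (10.0 ** (snr_db / 10.0))
    return noise * np.sqrt(target / p_noise)


def _gen_noise(kind: str, n: int, fs: float, rng: np.random.Generator,
               params: dict) -> np.ndarray:
    if kind == "baseline_wander":
        # band-limited (< 0.5 Hz) random drift
        raw = rng.standard_normal(n)
        sos = sps.butter(2, min(0.5, 0.4 * fs / 2), btype="low", fs=fs, output="sos")
        return sps.sosfiltfilt(sos, raw)
    if kind == "powerline":
        f0 = params.get("f0", 50.0)
        n_harm = params.get("n_harmonics", 1)
        t = np.arange(n) / fs
        phase = rng.uniform(0, 2 * np.pi)
        out = np.zeros(n)
        for h in range(1, n_harm + 1):
            if h * f0 < fs / 2:
                out += np.sin(2 * np.pi * h * f0 * t + phase * h) / h
        return out
    if kind == "muscle":
        raw = rng.standard_normal(n)
        high = 0.95 * fs / 2
        if high > 21:
            sos = sps.butter(2, [20.0, high], btype="band", fs=fs, output="sos")
            raw = sps.sosfiltfilt(sos, raw)
        return raw
    if kind == "electrode_motion":
        # sparse smooth high-amplitude transients, ~0.2 events/s
        out = np.zeros(n)
        n_events = max(1, rng.poisson(0.2 * n / fs))
        width = int(0.15 * fs)
        bump = sps.windows.hann(2 * width + 1)
        for _ in range(n_events):
            c = rng.integers(0, n)
            a = rng.uniform(0.5, 2.0) * rng.choice([-1.0, 1.0])
            lo, hi = max(0, c - width), min(n, c + width + 1)
            out[lo:hi] += a * bump[(lo - c + width):(hi - c + width)]
        return out
    raise ValueError(f"unknown noise type {kind!r}; choose from {NOISE_TYPES}")


def add_noise(signal: MultileadSignal, noise_spec, seed: int = 0) -> MultileadSignal:
    """Add noise per a spec list; annotations are unaffected (additive noise).

    Each item is ``(type, params)`` where params is a dict with ``snr_db``
    (stationary noise, per-lead power-matched so the achieved SNR equals the
    request) and optionally ``leads`` (list of lead indices; default all).
    ``disconnect`` items instead carry ``bursts``: a list of
    ``(lead, start_s, duration_s)`` during which the lead is railed flat.
    An empty spec returns the signal unchanged.
    """
    if not noise_spec:
        return signal
    rng = np.random.default_rng(seed)
    out = signal.samples.copy()
    n, L = out.shape
    for item in noise_spec:
        kind, params = (item if isinstance(item, tuple) else (item, {}))
        params = dict(params or {})
        if kind == "disconnect":
            for lead, start_s, dur_s in params.get("bursts", []):
                a = int(start_s * signal.fs)
                b = min(n, a + int(dur_s * signal.fs))
                rail = params.get("rail", 0.0)
                out[a:b, lead] = rail
            continue
        leads = params.get("leads", range(L))
        snr_db = params.get("snr_db", 12.0)
        for lead in leads:
            noise = _gen_noise(kind, n, signal.fs, rng, params)
            out[:, lead] += _scale_to_snr(signal.samples[:, lead], noise, snr_db)
    return MultileadSignal(out, signal.fs, list(signal.lead_names), signal.t0)


def synth_ltm(cfg: SynthConfig, day_noise_profile,
              day_s: float = 86400.0) -> tuple[MultileadSignal, AnnotationSet]:
    """Multi-day record whose noise severity varies per simulated day.

    ``day_noise_profile`` is a sequence of per-day muscle-noise SNRs in dB
    (``None`` = clean day); ``day_s`` may be compressed (e.g. 60 s) so that
    week-long scenarios run in test time.  The record duration is
    ``len(profile) * day_s`` regardless of ``cfg.duration_s``.
    """
    n_days = len(day_noise_profile)
    cfg = SynthConfig(fs=cfg.fs, duration_s=n_days * day_s, n_leads=cfg.n_leads,
                      mean_hr_bpm=cfg.mean_hr_bpm, hr_jitter=cfg.hr_jitter,
                      lead_gains=cfg.lead_gains, obs_noise_mv=cfg.obs_noise_mv,
                      seed=cfg.seed)
    signal, ann = synth_ecg(cfg)
    out = signal.samples.copy()
    nd = int(round(day_s * cfg.fs))
    rng_seed = cfg.seed + 1
    for d, snr in enumerate(day_noise_profile):
        if snr is None:
            continue
        a, b = d * nd, min(out.shape[0], (d + 1) * nd)
        day_sig = MultileadSignal(signal.samples[a:b], cfg.fs)
        noisy = add_noise(day_sig, [("muscle", {"snr_db": snr})],
                          seed=rng_seed + d)
        out[a:b] = noisy.samples
    return MultileadSignal(out, cfg.fs, list(signal.lead_names)), ann
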