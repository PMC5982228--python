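"""R-peak localization from feature signals.

The detection stage thresholds the feature signal adaptively
(``alpha * mean(y) + beta * std(y)`` per update window, defaults alpha=3,
beta=0.5, refreshed every 3 s), widens each supra-threshold run by 75 ms,
then locates peaks in two passes: a coarse argmax of the derivative-filtered
lead inside each region and a fine argmax of a softer (40 Hz low-passed)
version of the preprocessed signal in a window around the coarse peak.  A
refractory period suppresses T-wave double detections.

Multilead operation runs the chain per lead and fuses the per-lead peak
lists: AND requires agreement of all leads, POLL a majority, SC at least two
leads, OR any lead, with a 10 ms coincidence tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .features import FeatureSignal, compute_feature, derivative_filter_leads, pt_filter_lead
from .io import MultileadSignal, SegmentationPlan, plan_segments
from .preprocess import PreprocessConfig, preprocess_record

__all__ = [
    "ThresholdParams",
    "FusionConfig",
    "PeakList",
    "adaptive_threshold",
    "candidate_regions",
    "coarse_peaks",
    "fine_peaks",
    "apply_refractory",
    "fuse_leads",
    "detect_beats",
    "FUSION_METHODS",
]

FUSION_METHODS = ("and", "or", "poll", "sc")


@dataclass
class ThresholdParams:
    """Adaptive threshold: ``alpha * mean + beta * std`` per update window."""

    alpha: float = 3.0
    beta: float = 0.5
    update_s: float = 3.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.update_s <= 0:
            raise ValueError("alpha, beta must be >= 0 and update_s > 0")


@dataclass
class FusionConfig:
    """Lead-fusion rule and its coincidence tolerance."""

    method: str = "poll"
    tolerance_ms: float = 10.0
    refractory_ms: float = 250.0

    def __post_init__(self) -> None:
        if self.method.lower() not in FUSION_METHODS:
            raise ValueError(f"fusion method must be one of {FUSION_METHODS}")
        self.method = self.method.lower()
        if self.tolerance_ms <= 0:
            raise ValueError("tolerance_ms must be positive")

    def tolerance_samples(self, fs: float) -> int:
        # at 128 Hz, 10 ms is sub-sample; never collapse below one sample
        return max(1, int(round(self.tolerance_ms * fs / 1000.0)))


@dataclass
class PeakList:
    """Strictly increasing detected R-peak sample indices."""

    indices: np.ndarray
    lead: int | str = "FUSED"
    amplitudes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        if self.amplitudes is not None:
            self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
            if self.amplitudes.size != self.indices.size:
                raise ValueError("amplitudes must align with indices")

    def __len__(self) -> int:
        return int(self.indices.size)


# ---------------------------------------------------------------------------
# Thresholding and region selection
# ---------------------------------------------------------------------------

def adaptive_threshold(y: FeatureSignal | np.ndarray, params: ThresholdParams,
                       fs: float | None = None) -> np.ndarray:
    """Per-window threshold ``alpha*mean + beta*std`` held constant in-window.

    Windows are disjoint spans of ``update_s`` seconds.  A window whose
    content is degenerate (all zero — e.g. a flat disconnect) inherits the
    previous window's threshold so that detection does not free-run on noise
    re-entry.
    """
    if isinstance(y, FeatureSignal):
        fs = y.fs
        yv = np.abs(y.y) if y.y.ndim == 1 else np.abs(y.y[:, 0])
    else:
        yv = np.abs(np.asarray(y, dtype=np.float64))
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    n = yv.size
    w = max(1, int(round(params.update_s * fs)))
    thr = np.empty(n, dtype=np.float64)
    prev = None
    for start in range(0, n, w):
        win = yv[start:start + w]
        if win.size == 0:
            continue
        if np.all(win == 0.0) and prev is not None:
            t = prev
        else:
            t = params.alpha * float(win.mean()) + params.beta * float(win.std())
            prev = t
        thr[start:start + w] = t
    return thr


def candidate_regions(y: np.ndarray, thr: np.ndarray, fs: float,
                      widen_ms: float = 75.0) -> list[tuple[int, int]]:
    """Maximal supra-threshold runs, widened and merged.

    Each run where ``y > thr`` is extended by ``widen_ms`` on both sides,
    clipped to the record, and overlapping extensions are merged.  Returned
    as sorted, disjoint half-open ranges.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.shape != np.shape(thr):
        raise ValueError("feature and threshold must have equal length")
    above = y > thr
    if not np.any(above):
        return []
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, y.size]
    pad = int(round(widen_ms * fs / 1000.0))
    regions: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        s, e = max(0, s - pad), min(y.size, e + pad)
        if regions and s <= regions[-1][1]:
            regions[-1] = (regions[-1][0], max(regions[-1][1], e))
        else:
            regions.append((s, e))
    return regions


# ---------------------------------------------------------------------------
# Two-stage peak search
# ---------------------------------------------------------------------------

def coarse_peaks(regions: list[tuple[int, int]], xf: np.ndarray,
                 lead: int | str = 0) -> PeakList:
    """One peak per region: argmax of |xf| inside it (ties -> earliest)."""
    xa = np.abs(np.asarray(xf, dtype=np.float64))
    idx, amp = [], []
    for s, e in regions:
        if s >= e:
            continue
        k = s + int(np.argmax(xa[s:e]))
        idx.append(k)
        amp.append(xa[k])
    return PeakList(np.asarray(idx, dtype=np.int64), lead,
                    np.asarray(amp, dtype=np.float64))


def fine_peaks(coarse: PeakList, soft: np.ndarray, fs: float,
               window_ms: float = 100.0) -> PeakList:
    """Snap each coarse peak to the argmax of |soft| within +-window_ms/2.

    ``soft`` is a softer-filtered version of the input signal (see
    ``soft_signal``); searching it recovers the true R apex that the heavy
    feature filtering may have displaced.  Windows are clipped at record
    edges.  Peaks that collide after snapping are collapsed to one.
    """
    soft_a = np.abs(np.asarray(soft, dtype=np.float64))
    half = max(1, int(round(window_ms * fs / 2000.0)))
    idx, amp = [], []
    for k in coarse.indices:
        s, e = max(0, k - half), min(soft_a.size, k + half + 1)
        j = s + int(np.argmax(soft_a[s:e]))
        if idx and j <= idx[-1]:
            if soft_a[j] > amp[-1]:
                idx[-1], amp[-1] = j, soft_a[j]
            continue
        idx.append(int(j))
        amp.append(float(soft_a[j]))
    return PeakList(np.asarray(idx, dtype=np.int64), coarse.lead,
                    np.asarray(amp, dtype=np.float64))


def soft_signal(lead: np.ndarray, fs: float, cutoff: float = 40.0) -> np.ndarray:
    """The 'softer filtered version' used by the fine search: 40 Hz low-pass."""
    cutoff = min(cutoff, 0.45 * fs)
    sos = sps.butter(2, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(lead, dtype=np.float64))


def apply_refractory(peaks: PeakList, refractory_ms: float, fs: float) -> PeakList:
    """Enforce a minimum spacing, keeping the higher-amplitude peak.

    Greedy left-to-right scan: when the next peak falls inside the
    refractory span of the last kept one, the larger of the two survives.
    Suppresses T-wave and artifact double-detections.
    """
    r = int(round(refractory_ms * fs / 1000.0))
    if len(peaks) == 0 or r <= 0:
        return peaks
    amps = peaks.amplitudes
    if amps is None:
        amps = np.ones(len(peaks))
    keep_idx: list[int] = []
    keep_amp: list[float] = []
    for k, a in zip(peaks.indices, amps):
        if keep_idx and k - keep_idx[-1] < r:
            if a > keep_amp[-1]:
                keep_idx[-1], keep_amp[-1] = int(k), float(a)
        else:
            keep_idx.append(int(k))
            keep_amp.append(float(a))
    return PeakList(np.asarray(keep_idx, dtype=np.int64), peaks.lead,
                    np.asarray(keep_amp, dtype=np.float64))


# ---------------------------------------------------------------------------
# Lead fusion
# ---------------------------------------------------------------------------

def _required_support(method: str, L: int) -> int:
    if method == "and":
        return L
    if method == "poll":
        return L // 2 + 1          # strict majority; for L=2 this equals AND
    if method == "sc":
        if L < 2:
            raise ValueError("simple coupling is undefined for a single lead")
        return 2
    if method == "or":
        return 1
    raise ValueError(f"unknown fusion method {method!r}")


def fuse_leads(per_lead: list[PeakList], cfg: FusionConfig, fs: float,
               n_leads: int | None = None) -> PeakList:
    """Fuse per-lead peak lists into one by coincidence voting.

    Peaks from different leads closer than the tolerance are clustered; a
    cluster is emitted when the number of distinct supporting leads meets
    the rule's quota (AND: all, POLL: majority, SC: two, OR: one).  The
    fused index is the median of the cluster members.  With one lead the
    input list is returned unchanged whatever the rule.
    """
    L = n_leads if n_leads is not None else len(per_lead)
    if L == 1:
        return per_lead[0]
    need = _required_support(cfg.method, L)
    tol = cfg.tolerance_samples(fs)

    events = []  # (index, lead_pos, amplitude)
    for pos, pl in enumerate(per_lead):
        amps = pl.amplitudes if pl.amplitudes is not None else np.ones(len(pl))
        events.extend((int(i), pos, float(a)) for i, a in zip(pl.indices, amps))
    events.sort()
    fused_idx: list[int] = []
    fused_amp: list[float] = []
    cluster: list[tuple[int, int, float]] = []

    def flush() -> None:
        if not cluster:
            return
        support = len({lead for _, lead, _ in cluster})
        if support >= need:
            member_idx = sorted(i for i, _, _ in cluster)
            med = int(np.median(member_idx))
            if not fused_idx or med > fused_idx[-1]:
                fused_idx.append(med)
                fused_amp.append(max(a for _, _, a in cluster))
        cluster.clear()

    for ev in events:
        if cluster and ev[0] - cluster[0][0] > tol:
            flush()
        cluster.append(ev)
    flush()
    return PeakList(np.asarray(fused_idx, dtype=np.int64), "FUSED",
                    np.asarray(fused_amp, dtype=np.float64))


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _detect_from_feature(y: np.ndarray, xf: np.ndarray, soft: np.ndarray,
                         fs: float, thr_params: ThresholdParams,
                         refractory_ms: float, lead: int | str,
                         widen_ms: float = 75.0) -> PeakList:
    thr = adaptive_threshold(np.abs(y), thr_params, fs=fs)
    regions = candidate_regions(np.abs(y), thr, fs, widen_ms)
    pk = coarse_peaks(regions, xf, lead)
    pk = fine_peaks(pk, soft, fs)
    return apply_refractory(pk, refractory_ms, fs)


def detect_segment(signal: MultileadSignal, feature_method: str = "poll-input",
                   fusion: FusionConfig | None = None,
                   thr: ThresholdParams | None = None,
                   seed: int = 0) -> PeakList:
    """Detect R-peaks on one (already preprocessed) segment.

    ``feature_method`` selects the feature pipeline: ``"poll-input"`` (alias
    ``"perlead"``) runs the PT chain per lead and fuses the per-lead peak
    lists with the configured rule; ``pt``/``rms``/``prod``/``pca``/``ica``
    detect on a single combined feature signal.
    """
    fusion = fusion or FusionConfig()
    thr = thr or ThresholdParams()
    fs = signal.fs
    softs = [soft_signal(signal.lead(i), fs) for i in range(signal.n_leads)]

    if feature_method in ("poll-input", "perlead") and signal.n_leads > 1:
        flt = derivative_filter_leads(signal)
        per_lead = []
        for i in range(signal.n_leads):
            y = pt_filter_lead(signal.lead(i), fs)
            per_lead.append(_detect_from_feature(
                y, flt.xf[:, i], softs[i], fs, thr, fusion.refractory_ms, i))
        fused = fuse_leads(per_lead, fusion, fs, signal.n_leads)
        return apply_refractory(fused, fusion.refractory_ms, fs)

    if feature_method in ("poll-input", "perlead"):  # single lead degenerates
        feature_method = "pt"

    feat = compute_feature(signal, feature_method, seed=seed)
    y = feat.y[:, 0] if feat.y.ndim == 2 else feat.y
    if feature_method in ("pt", "prod"):
        flt = derivative_filter_leads(signal)
        lead = (feat.meta or {}).get("lead", 0)
        xf = flt.xf[:, lead]
        soft = softs[lead]
    else:
        # combined features have no natural lead; search the feature itself
        # coarsely and refine on the least-variance-ratio lead
        from .features import select_least_noisy_lead
        lead = select_least_noisy_lead(signal) if signal.n_leads > 1 else 0
        xf = y
        soft = softs[lead]
    return _detect_from_feature(y, xf, soft, fs, thr, fusion.refractory_ms,
                                feature_method.upper())


def detect_beats(signal: MultileadSignal, feature_method: str = "poll-input",
                 fusion: FusionConfig | None = None,
                 thr: ThresholdParams | None = None,
                 plan: SegmentationPlan | None = None,
                 preprocess_cfg: PreprocessConfig | None = None,
                 seed: int = 0) -> PeakList:
    """Full pipeline on a (possibly long) record.

    Per segment of the plan (default 300 s with 2 s overlap): preprocess,
    extract features, threshold, coarse+fine search, refractory, fuse.
    Segment-local indices are shifted back to record coordinates and
    duplicates from the overlaps (within the fusion tolerance) removed.
    """
    fusion = fusion or FusionConfig()
    thr = thr or ThresholdParams()
    plan = plan or plan_segments(signal)
    # each interior segment only reports peaks from its core, half an
    # overlap away from either edge: the adjacent segment sees the trimmed
    # band with full filter context, and filtfilt edge transients never
    # produce spurious boundary detections
    margin = int(round(plan.overlap_s * signal.fs / 2.0))
    collected: list[tuple[int, float]] = []
    for start, end in plan.segments:
        seg = signal.slice(start, end)
        pre = preprocess_record(seg, preprocess_cfg)
        pk = detect_segment(pre, feature_method, fusion, thr, seed=seed)
        amps = pk.amplitudes if pk.amplitudes is not None else np.ones(len(pk))
        lo = margin if start > 0 else 0
        hi = (end - start) - margin if end < signal.n_samples else (end - start)
        collected.extend((int(i) + start, float(a))
                         for i, a in zip(pk.indices, amps)
                         if lo <= i < hi)
    collected.sort()
    # overlap regions yield the same beat from two segments; merge peaks
    # closer than the fusion tolerance, keeping the earlier index
    tol = fusion.tolerance_samples(signal.fs)
    all_idx: list[int] = []
    all_amp: list[float] = []
    for i, a in collected:
        if all_idx and i - all_idx[-1] <= tol:
            all_amp[-1] = max(all_amp[-1], a)
            continue
        all_idx.append(i)
        all_amp.append(a)
    return PeakList(np.asarray(all_idx, dtype=np.int64), "FUSED",
                    np.asarray(all_amp, dtype=np.float64))
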