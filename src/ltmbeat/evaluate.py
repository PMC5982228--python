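"""Beat-by-beat detector scoring, per-day error profiles, threshold tuning.

Matching convention: a detection within a short tolerance window of an
annotated beat is a true positive (TP); unmatched detections are false
positives (FP); unmatched annotations false negatives (FN).  A true negative
(TN) is an inter-beat interval between consecutive annotated R-waves that
contains no FP — the natural re-definition of specificity for a detection
problem with no innate negative class.

Merit figures (percentages), with B = TP + FP + FN + TN:

    Sen = TP / (TP + FN)        Spe = TN / (TN + FP)
    PPV = TP / (TP + FP)        Acc = (TP + TN) / B
    Error = (FP + FN) / B

Under this B the identity Acc + Error = 100 holds exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import AnnotationSet
from .detect import PeakList

__all__ = [
    "DetectionCounts",
    "Metrics",
    "TuningConfig",
    "match_beats",
    "count_true_negatives",
    "evaluate_detections",
    "compute_metrics",
    "error_over_time",
    "tune_threshold",
    "compare_detectors",
    "DetectorComparison",
]

DEFAULT_MATCH_TOL_MS = 150.0   # AAMI EC57 beat-matching window


@dataclass
class DetectionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0

    @property
    def B(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def __add__(self, other: "DetectionCounts") -> "DetectionCounts":
        return DetectionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.FN + other.FN, self.TN + other.TN)


@dataclass
class Metrics:
    sen: float
    spe: float
    ppv: float
    acc: float
    error: float


@dataclass
class TuningConfig:
    K: int = 12
    alpha_grid: list[float] = field(default_factory=lambda: [2.0, 3.0, 4.0])
    beta_grid: list[float] = field(default_factory=lambda: [0.25, 0.5, 1.0])

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if not self.alpha_grid or not self.beta_grid:
            raise ValueError("grids must be non-empty")


def _as_indices(x) -> np.ndarray:
    if isinstance(x, PeakList):
        return x.indices
    if isinstance(x, AnnotationSet):
        return x.indices
    return np.asarray(x, dtype=np.int64)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def match_beats(detected, reference, match_tol_ms: float = DEFAULT_MATCH_TOL_MS,
                fs: float = 1000.0):
    """One-to-one matching of detections to annotated beats.

    Sorted two-pointer greedy: walking both lists in time order and pairing
    whenever the gap is within tolerance yields a maximum-cardinality
    matching for points on a line (each unmatched element is advanced past
    when it can no longer pair).  Returns ``(counts, matched_pairs)`` where
    counts carries TP/FP/FN (TN is filled by ``evaluate_detections``).
    """
    det = _as_indices(detected)
    ref = _as_indices(reference)
    tol = match_tol_ms * fs / 1000.0
    i = j = 0
    pairs: list[tuple[int, int]] = []
    while i < det.size and j < ref.size:
        d = det[i] - ref[j]
        if abs(d) <= tol:
            pairs.append((i, j))
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    counts = DetectionCounts(TP=len(pairs), FP=det.size - len(pairs),
                             FN=ref.size - len(pairs))
    return counts, pairs


def count_true_negatives(reference, false_positives) -> int:
    """Number of inter-beat gaps that contain no false positive.

    With R references there are R-1 consecutive gaps; a gap counts as a TN
    when no FP falls strictly inside it.  Fewer than two references -> 0.
    """
    ref = _as_indices(reference)
    fp = _as_indices(false_positives)
    if ref.size < 2:
        return 0
    # for each FP, which gap (r_g, r_{g+1}) does it fall strictly inside?
    gaps_hit = set()
    for x in fp:
        g = int(np.searchsorted(ref, x, side="right")) - 1
        if 0 <= g < ref.size - 1 and ref[g] < x < ref[g + 1]:
            gaps_hit.add(g)
    return int(ref.size - 1 - len(gaps_hit))


def evaluate_detections(detected, reference,
                        match_tol_ms: float = DEFAULT_MATCH_TOL_MS,
                        fs: float = 1000.0) -> DetectionCounts:
    """Full TP/FP/FN/TN bookkeeping for one record."""
    det = _as_indices(detected)
    ref = _as_indices(reference)
    counts, pairs = match_beats(det, ref, match_tol_ms, fs)
    matched_det = {i for i, _ in pairs}
    fp_idx = np.array([det[i] for i in range(det.size) if i not in matched_det],
                      dtype=np.int64)
    counts.TN = count_true_negatives(ref, fp_idx)
    return counts


# ---------------------------------------------------------------------------
# Merit figures
# ---------------------------------------------------------------------------

def _safe_pct(num: float, den: float, name: str) -> float:
    if den <= 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return 100.0 * num / den


def compute_metrics(c: DetectionCounts) -> Metrics:
    """Sen/Spe/PPV/Acc/Error as percentages from the counts."""
    return Metrics(
        sen=_safe_pct(c.TP, c.TP + c.FN, "sensitivity"),
        spe=_safe_pct(c.TN, c.TN + c.FP, "specificity"),
        ppv=_safe_pct(c.TP, c.TP + c.FP, "positive predictive value"),
        acc=_safe_pct(c.TP + c.TN, c.B, "accuracy"),
        error=_safe_pct(c.FP + c.FN, c.B, "error"),
    )


def error_over_time(detected, reference, fs: float, bin_s: float = 86400.0,
                    match_tol_ms: float = DEFAULT_MATCH_TOL_MS,
                    n_bins: int | None = None):
    """Detection error per time bin (default bin: one day).

    Matching is done globally, then TPs and FNs are binned by annotation
    time and FPs by detection time; per bin the error is (FP+FN)/B with
    B = TP+FP+FN+TN computed from that bin's events.  Bins with no beats
    report NaN.  Returns ``(bin_start_s, error_pct, per_bin_counts)``.
    """
    det = _as_indices(detected)
    ref = _as_indices(reference)
    _, pairs = match_beats(det, ref, match_tol_ms, fs)
    matched_det = {i for i, _ in pairs}
    matched_ref = {j for _, j in pairs}
    fp_idx = np.array([det[i] for i in range(det.size) if i not in matched_det],
                      dtype=np.int64)

    last = max(det[-1] if det.size else 0, ref[-1] if ref.size else 0)
    bw = bin_s * fs
    if n_bins is None:
        n_bins = int(last // bw) + 1 if last > 0 else 1
    counts = [DetectionCounts() for _ in range(n_bins)]

    def bin_of(sample: int) -> int:
        return min(int(sample // bw), n_bins - 1)

    for j in range(ref.size):
        b = bin_of(ref[j])
        if j in matched_ref:
            counts[b].TP += 1
        else:
            counts[b].FN += 1
    for x in fp_idx:
        counts[bin_of(x)].FP += 1
    # TNs: attribute each inter-beat gap to the bin of its left edge
    gaps_hit = set()
    for x in fp_idx:
        g = int(np.searchsorted(ref, x, side="right")) - 1
        if 0 <= g < ref.size - 1 and ref[g] < x < ref[g + 1]:
            gaps_hit.add(g)
    for g in range(max(0, ref.size - 1)):
        if g not in gaps_hit:
            counts[bin_of(ref[g])].TN += 1

    starts = np.arange(n_bins) * bin_s
    err = np.full(n_bins, np.nan)
    for b, c in enumerate(counts):
        if c.B > 0:
            err[b] = 100.0 * (c.FP + c.FN) / c.B
    return starts, err, counts


# ---------------------------------------------------------------------------
# Threshold tuning
# ---------------------------------------------------------------------------

def tune_threshold(records, cfg: TuningConfig, detector,
                   match_tol_ms: float = DEFAULT_MATCH_TOL_MS):
    """K-fold grid search over (alpha, beta).

    ``records`` is a list of ``(MultileadSignal, AnnotationSet)``;
    ``detector(signal, alpha, beta) -> PeakList`` runs the detection
    pipeline at a grid point.  Records are split into K folds; for each
    fold the grid point minimizing the pooled training error is selected
    and scored on the held-out fold (the cross-validated error).  The
    returned point is the one with minimal mean held-out error.

    Returns ``(alpha, beta, cv_error_pct)``.
    """
    records = list(records)
    n = len(records)
    if n < cfg.K:
        raise ValueError(f"need at least K={cfg.K} records/segments, got {n}")
    grid = [(a, b) for a in cfg.alpha_grid for b in cfg.beta_grid]

    # error matrix: per grid point, per record (each record scored once)
    err = np.zeros((len(grid), n))
    for gi, (a, b) in enumerate(grid):
        for ri, (sig, ann) in enumerate(records):
            peaks = detector(sig, a, b)
            c = evaluate_detections(peaks, ann, match_tol_ms, sig.fs)
            err[gi, ri] = 100.0 * (c.FP + c.FN) / c.B if c.B else 100.0

    folds = np.array_split(np.arange(n), cfg.K)
    heldout_err = np.zeros(len(grid))
    cv_err_terms = []
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        fit = int(np.argmin(err[:, train].mean(axis=1)))
        cv_err_terms.append(err[fit, fold].mean())
        heldout_err += err[:, fold].mean(axis=1) / cfg.K
    best = int(np.argmin(heldout_err))
    alpha, beta = grid[best]
    return alpha, beta, float(np.mean(cv_err_terms))


# ---------------------------------------------------------------------------
# Detector-vs-detector comparison
# ---------------------------------------------------------------------------

@dataclass
class DetectorComparison:
    """Reference beats and detections classified by which detector got them.

    ``a_only``/``b_only``: reference beats caught by one detector and missed
    by the other; ``shared_misses``: missed by both; ``fp_a``/``fp_b``: each
    detector's false positives.  Beats in ``a_only`` (missed by b) are also
    split into bursts (runs of >= burst_len consecutive reference beats) and
    single beats.
    """

    a_only: np.ndarray
    b_only: np.ndarray
    shared_misses: np.ndarray
    fp_a: np.ndarray
    fp_b: np.ndarray
    burst_beats: int
    single_beats: int
    bursts: list[tuple[int, int]]


def compare_detectors(a, b, reference, tol_ms: float = DEFAULT_MATCH_TOL_MS,
                      fs: float = 1000.0, burst_len: int = 3) -> DetectorComparison:
    """Classify disagreement between two detectors against a reference."""
    ref = _as_indices(reference)
    _, pairs_a = match_beats(a, ref, tol_ms, fs)
    _, pairs_b = match_beats(b, ref, tol_ms, fs)
    det_a, det_b = _as_indices(a), _as_indices(b)
    hit_a = {j for _, j in pairs_a}
    hit_b = {j for _, j in pairs_b}
    a_only = np.array(sorted(hit_a - hit_b), dtype=np.int64)
    b_only = np.array(sorted(hit_b - hit_a), dtype=np.int64)
    shared = np.array(sorted(set(range(ref.size)) - hit_a - hit_b), dtype=np.int64)
    fp_a = np.array([det_a[i] for i in range(det_a.size)
                     if i not in {i for i, _ in pairs_a}], dtype=np.int64)
    fp_b = np.array([det_b[i] for i in range(det_b.size)
                     if i not in {i for i, _ in pairs_b}], dtype=np.int64)

    # run-length classification of b's misses that a caught
    bursts: list[tuple[int, int]] = []
    burst_beats = single_beats = 0
    if a_only.size:
        run_start = a_only[0]
        run_len = 1
        prev = a_only[0]
        for j in np.r_[a_only[1:], -10]:
            if j == prev + 1:
                run_len += 1
            else:
                if run_len >= burst_len:
                    bursts.append((int(run_start), run_len))
                    burst_beats += run_len
                else:
                    single_beats += run_len
                run_start, run_len = j, 1
            prev = j
    return DetectorComparison(
        a_only=ref[a_only] if a_only.size else np.empty(0, dtype=np.int64),
        b_only=ref[b_only] if b_only.size else np.empty(0, dtype=np.int64),
        shared_misses=ref[shared] if shared.size else np.empty(0, dtype=np.int64),
        fp_a=fp_a, fp_b=fp_b,
        burst_beats=burst_beats, single_beats=single_beats, bursts=bursts)
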