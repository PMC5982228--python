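"""Benchmark runners for the public PhysioNet databases.

These drive the full detection pipeline over a local copy of the MIT-BIH
arrhythmia database (``mitdb``) or the noise stress test database
(``nstdb``) and score it beat-by-beat.  The databases are not shipped with
the package; point ``data_dir`` at a directory containing the ``.hea`` /
``.dat`` / ``.atr`` files (e.g. downloaded from PhysioNet with
``wget -r -np https://physionet.org/files/mitdb/1.0.0/``).

Settings follow the transversal optimization: per-lead PT features fused by
polling, alpha=3, beta=0.5, 3 s threshold update, 25 Hz low-pass, 300 s
segments, 150 ms match tolerance.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .detect import FusionConfig, ThresholdParams, detect_beats
from .evaluate import compute_metrics, evaluate_detections
from .io import plan_segments, read_annotations, read_record
from .preprocess import PreprocessConfig

__all__ = ["run_record", "run_mitbih_benchmark", "run_nstdb_benchmark",
           "MITDB_RECORDS", "NSTDB_RECORDS", "transversal_settings"]

MITDB_RECORDS = [
    "100", "101", "102", "103", "104", "105", "106", "107", "108", "109",
    "111", "112", "113", "114", "115", "116", "117", "118", "119", "121",
    "122", "123", "124", "200", "201", "202", "203", "205", "207", "208",
    "209", "210", "212", "213", "214", "215", "217", "219", "220", "221",
    "222", "223", "228", "230", "231", "232", "233", "234",
]

#: NSTDB record names ordered from clean (24 dB) down to -6 dB.
NSTDB_RECORDS = [
    "118e24", "118e18", "118e12", "118e06", "118e00", "118e_6",
    "119e24", "119e18", "119e12", "119e06", "119e00", "119e_6",
]


def transversal_settings():
    """Detector settings from the transversal optimization (K=12 CV)."""
    return dict(
        fusion=FusionConfig(method="poll", tolerance_ms=10.0, refractory_ms=250.0),
        thr=ThresholdParams(alpha=3.0, beta=0.5, update_s=3.0),
        preprocess_cfg=PreprocessConfig(powerline_hz=60.0, lowpass_hz=25.0),
        segment_length_s=300.0,
    )


def run_record(record_path: str | Path, ann_ext: str = "atr",
               match_tol_ms: float = 150.0, **overrides):
    """Detect and score one WFDB record. Returns (counts, metrics, peaks)."""
    settings = transversal_settings()
    settings.update(overrides)
    seg_s = settings.pop("segment_length_s")
    signal = read_record(record_path, format="wfdb")
    ann = read_annotations(Path(record_path).with_suffix(f".{ann_ext}"),
                           beat_only=True, fs=signal.fs)
    plan = plan_segments(signal, segment_length_s=min(seg_s, max(10.0, signal.duration_s)),
                         overlap_s=2.0 if signal.duration_s > 10 else 0.0)
    peaks = detect_beats(signal, "poll-input", plan=plan, **settings)
    counts = evaluate_detections(peaks, ann, match_tol_ms, signal.fs)
    return counts, compute_metrics(counts), peaks


def _run_database(data_dir: str | Path, records: list[str], match_tol_ms: float):
    data_dir = Path(data_dir)
    missing = [r for r in records if not (data_dir / f"{r}.hea").exists()]
    if missing:
        raise FileNotFoundError(
            f"{len(missing)} records missing under {data_dir} "
            f"(first: {missing[0]}.hea); download the database from PhysioNet")
    rows = {}
    for rec in records:
        counts, metrics, _ = run_record(data_dir / rec, match_tol_ms=match_tol_ms)
        rows[rec] = metrics
    mean = {f: float(np.mean([getattr(m, f) for m in rows.values()]))
            for f in ("sen", "spe", "ppv", "acc", "error")}
    return rows, mean


def run_mitbih_benchmark(data_dir: str | Path, records: list[str] | None = None,
                         match_tol_ms: float = 150.0):
    """Score all (or selected) MIT-BIH arrhythmia records.

    Returns ``(per_record_metrics, mean_metrics)`` where the mean is the
    arithmetic mean over records of each merit figure.
    """
    return _run_database(data_dir, records or MITDB_RECORDS, match_tol_ms)


def run_nstdb_benchmark(data_dir: str | Path, records: list[str] | None = None,
                        match_tol_ms: float = 150.0):
    """Score the noise-stress-test records (118/119 at graded SNRs)."""
    return _run_database(data_dir, records or NSTDB_RECORDS, match_tol_ms)
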