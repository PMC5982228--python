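"""Record and annotation I/O plus long-record segmentation.

Two on-disk dialects are supported:

* WFDB (``.hea``/``.dat``/annotation files) — the PhysioNet format used by the
  MIT-BIH family of databases.  A self-contained reader/writer is provided for
  the two signal encodings those databases use (format 16 and the packed
  12-bit format 212) and for the MIT annotation byte stream.
* A minimal CSV dialect — first header line ``fs=<Hz>``, an optional second
  line of lead names, then one comma-separated row per sample.  Intended as a
  human-readable fixture format.

All coordinates are 0-based sample indices; ranges are half-open
``[start, end)``.  No resampling happens anywhere: filters downstream are
designed at the native sampling rate.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "MultileadSignal",
    "AnnotationSet",
    "SegmentationPlan",
    "BEAT_CODES",
    "SYMBOL_TO_CODE",
    "CODE_TO_SYMBOL",
    "read_record",
    "write_record",
    "read_annotations",
    "write_annotations",
    "plan_segments",
    "write_detections",
    "read_detections",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MultileadSignal:
    """A multilead ECG: ``samples[n, l]`` in millivolts at ``fs`` Hz."""

    samples: np.ndarray          # shape (n, L), float64, millivolts
    fs: float                    # sampling rate, Hz
    lead_names: list[str] = field(default_factory=list)
    t0: int = 0                  # start offset in samples (for segments)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (n x L) array")
        n, L = self.samples.shape
        if n < 1 or L < 1:
            raise ValueError("signal must have at least one sample and one lead")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not self.lead_names:
            self.lead_names = [f"lead{i + 1}" for i in range(L)]
        if len(self.lead_names) != L:
            raise ValueError("lead_names length must match number of leads")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_leads(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, i: int) -> np.ndarray:
        return self.samples[:, i]

    def slice(self, start: int, end: int) -> "MultileadSignal":
        """Return the half-open segment [start, end) with t0 bookkeeping."""
        start = max(0, start)
        end = min(self.n_samples, end)
        return MultileadSignal(self.samples[start:end].copy(), self.fs,
                               list(self.lead_names), t0=self.t0 + start)


@dataclass
class AnnotationSet:
    """Reference beat positions (sample indices) with beat-type labels."""

    indices: np.ndarray                      # strictly increasing ints
    labels: list[str] = field(default_factory=list)
    fs: float | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("annotation indices must be strictly increasing")
        if not self.labels:
            self.labels = ["N"] * self.indices.size
        if len(self.labels) != self.indices.size:
            raise ValueError("labels must align with indices")

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class SegmentationPlan:
    """Half-open sample ranges covering a record, with fixed overlap."""

    segment_length_s: float
    overlap_s: float
    segments: list[tuple[int, int]]

    @property
    def n_segments(self) -> int:
        return len(self.segments)


# ---------------------------------------------------------------------------
# WFDB annotation codes (MIT format)
# ---------------------------------------------------------------------------

CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")", 41: "r",
}
SYMBOL_TO_CODE = {v: k for k, v in CODE_TO_SYMBOL.items()}

#: Annotation codes that denote an actual heartbeat (QRS complex).
BEAT_CODES = frozenset(
    {1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 34, 35, 38, 41})

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


# ---------------------------------------------------------------------------
# Record reading / writing
# ---------------------------------------------------------------------------

def read_record(path: str | Path, format: str | None = None) -> MultileadSignal:
    """Read a multilead record from WFDB or CSV.

    Parameters
    ----------
    path
        For CSV, the ``.csv`` file.  For WFDB, the record name — with or
        without the ``.hea`` extension.
    format
        ``"wfdb"`` or ``"csv"``; inferred from the extension when omitted.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix == ".csv" else "wfdb"
    if format == "csv":
        return _read_csv(path)
    if format == "wfdb":
        return _read_wfdb(path)
    raise ValueError(f"unknown record format: {format!r}")


def write_record(signal: MultileadSignal, path: str | Path,
                 format: str | None = None) -> None:
    """Write a record as CSV or WFDB (header + format-16 .dat)."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix == ".csv" else "wfdb"
    if format == "csv":
        _write_csv(signal, path)
    elif format == "wfdb":
        _write_wfdb(signal, path)
    else:
        raise ValueError(f"unknown record format: {format!r}")


def _read_csv(path: Path) -> MultileadSignal:
    if not path.exists():
        raise FileNotFoundError(f"record not found: {path}")
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("fs="):
            raise ValueError(f"{path}: first CSV line must be 'fs=<Hz>', got {header!r}")
        fs = float(header[3:])
        pos = fh.tell()
        second = fh.readline().strip()
        lead_names: list[str] = []
        try:
            [float(v) for v in second.split(",")]
            fh.seek(pos)  # second line is data, not names
        except ValueError:
            lead_names = [s.strip() for s in second.split(",")]
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    if data.size == 0:
        raise ValueError(f"{path}: no samples")
    return MultileadSignal(data, fs, lead_names)


def _write_csv(signal: MultileadSignal, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"fs={signal.fs:g}\n")
        fh.write(",".join(signal.lead_names) + "\n")
        np.savetxt(fh, signal.samples, delimiter=",", fmt="%.17g")


def _parse_hea(hea_path: Path):
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{hea_path}: empty header")
    rec = lines[0].split()
    if len(rec) < 2:
        raise ValueError(f"{hea_path}: unreadable record line {lines[0]!r}")
    name = rec[0]
    n_sig = int(rec[1])
    fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
    n_samples = int(rec[3]) if len(rec) > 3 else 0
    sig_specs = []
    for ln in lines[1:1 + n_sig]:
        tok = ln.split()
        fname = tok[0]
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = 200.0, None, "mV"
        if len(tok) > 2:
            g = tok[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, b = g.rstrip(")").split("(")
                baseline = int(b)
            gain = float(g) if float(g) != 0 else 200.0
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        desc = " ".join(tok[8:]) if len(tok) > 8 else ""
        sig_specs.append(dict(file=fname, fmt=fmt, gain=gain,
                              baseline=baseline, units=units, desc=desc))
    return name, n_sig, fs, n_samples, sig_specs


def _read_wfdb(path: Path) -> MultileadSignal:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    _, n_sig, fs, n_samples, specs = _parse_hea(hea)
    if n_sig < 1:
        raise ValueError(f"{hea}: no signals")

    # group signals by their .dat file (mitdb interleaves both leads in one)
    leads: list[np.ndarray] = [None] * n_sig  # type: ignore[list-item]
    by_file: dict[str, list[int]] = {}
    for i, s in enumerate(specs):
        by_file.setdefault(s["file"], []).append(i)
    for fname, idxs in by_file.items():
        raw = (hea.parent / fname).read_bytes()
        fmt = specs[idxs[0]]["fmt"]
        k = len(idxs)
        if fmt == 16:
            adc = np.frombuffer(raw, dtype="<i2")
            adc = adc[: (adc.size // k) * k].reshape(-1, k)
        elif fmt == 212:
            adc = _decode_212(raw)
            adc = adc[: (adc.size // k) * k].reshape(-1, k)
        else:
            raise ValueError(f"unsupported WFDB signal format {fmt} in {fname}")
        if n_samples:
            adc = adc[:n_samples]
        for col, i in enumerate(idxs):
            s = specs[i]
            leads[i] = (adc[:, col].astype(np.float64) - s["baseline"]) / s["gain"]
    lengths = {v.size for v in leads}
    if len(lengths) != 1:
        raise ValueError(f"{hea}: leads have inconsistent lengths {sorted(lengths)}")
    names = [s["desc"] or f"lead{i + 1}" for i, s in enumerate(specs)]
    return MultileadSignal(np.column_stack(leads), fs, names)


def _decode_212(raw: bytes) -> np.ndarray:
    """Unpack WFDB format 212: two 12-bit two's-complement samples per 3 bytes."""
    b = np.frombuffer(raw, dtype=np.uint8)
    b = b[: (b.size // 3) * 3].reshape(-1, 3).astype(np.int32)
    s1 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s2 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * b.shape[0], dtype=np.int32)
    out[0::2], out[1::2] = s1, s2
    out[out > 2047] -= 4096
    return out


def _encode_212(adc: np.ndarray) -> bytes:
    vals = np.asarray(adc, dtype=np.int32).ravel()
    if vals.size % 2:
        vals = np.append(vals, 0)
    u = np.where(vals < 0, vals + 4096, vals).astype(np.uint32)
    s1, s2 = u[0::2], u[1::2]
    out = np.empty((s1.size, 3), dtype=np.uint8)
    out[:, 0] = s1 & 0xFF
    out[:, 1] = ((s1 >> 8) & 0x0F) | (((s2 >> 8) & 0x0F) << 4)
    out[:, 2] = s2 & 0xFF
    return out.tobytes()


def _write_wfdb(signal: MultileadSignal, path: Path, gain: float = 200.0) -> None:
    """Write header + interleaved format-16 .dat (adc = round(mV * gain))."""
    base = path.with_suffix("") if path.suffix == ".hea" else path
    adc = np.round(signal.samples * gain).astype(np.int64)
    if adc.max(initial=0) > 32767 or adc.min(initial=0) < -32768:
        raise ValueError("signal amplitude exceeds 16-bit range at this gain")
    adc16 = adc.astype("<i2")
    dat_name = base.name + ".dat"
    (base.parent / dat_name).write_bytes(adc16.ravel().tobytes())
    lines = [f"{base.name} {signal.n_leads} {signal.fs:g} {signal.n_samples}"]
    for i in range(signal.n_leads):
        init = int(adc[0, i])
        lines.append(f"{dat_name} 16 {gain:g}(0)/mV 16 0 {init} 0 0 "
                     f"{signal.lead_names[i]}")
    (base.parent / (base.name + ".hea")).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Annotations (MIT format)
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path, beat_only: bool = False,
                     fs: float | None = None) -> AnnotationSet:
    """Read a WFDB annotation file (e.g. ``.atr``).

    With ``beat_only`` true, only annotations whose code denotes a heartbeat
    are retained (rhythm changes, noise markers etc. are dropped).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    raw = path.read_bytes()
    indices: list[int] = []
    labels: list[str] = []
    t = 0
    pos = 0
    n = len(raw)
    while pos + 1 < n:
        word = raw[pos] | (raw[pos + 1] << 8)
        pos += 2
        code = word >> 10
        interval = word & 0x3FF
        if code == 0 and interval == 0:
            break  # EOF marker
        if code == _SKIP:
            if pos + 3 >= n:
                break
            hi = raw[pos] | (raw[pos + 1] << 8)
            lo = raw[pos + 2] | (raw[pos + 3] << 8)
            pos += 4
            delta = (hi << 16) | lo
            if delta >= 1 << 31:
                delta -= 1 << 32
            t += delta
        elif code in (_NUM, _SUB, _CHN):
            continue  # field modifiers; value in `interval`, not needed here
        elif code == _AUX:
            pos += interval + (interval & 1)  # aux string, padded to even
        else:
            t += interval
            if not beat_only or code in BEAT_CODES:
                indices.append(t)
                labels.append(CODE_TO_SYMBOL.get(code, "Q"))
    if not indices:
        warnings.warn(f"no annotations found in {path}")
        return AnnotationSet(np.empty(0, dtype=np.int64), [], fs=fs)
    return AnnotationSet(np.asarray(indices, dtype=np.int64), labels, fs=fs)


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    """Write an MIT-format annotation file readable by standard WFDB tools."""
    path = Path(path)
    out = bytearray()
    t_prev = 0
    for idx, sym in zip(ann.indices, ann.labels):
        code = SYMBOL_TO_CODE.get(sym, 13)  # unknown beat
        delta = int(idx) - t_prev
        if delta >= 1 << 10:
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<H", (delta >> 16) & 0xFFFF)
            out += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (code << 10) | delta)
        t_prev = int(idx)
    out += struct.pack("<H", 0)  # EOF
    path.write_bytes(bytes(out))


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def plan_segments(signal: MultileadSignal, segment_length_s: float = 300.0,
                  overlap_s: float = 2.0) -> SegmentationPlan:
    """Plan half-open segment ranges covering the whole record.

    Consecutive segments overlap by ``overlap_s`` so that beats at segment
    boundaries are seen with full filter context by at least one segment;
    duplicate detections in the overlap are removed downstream.
    """
    if segment_length_s <= 0 or overlap_s < 0:
        raise ValueError("segment_length_s must be positive, overlap_s >= 0")
    if not segment_length_s > 2 * overlap_s:
        raise ValueError("segment_length_s must exceed twice the overlap")
    n = signal.n_samples
    seg = int(round(segment_length_s * signal.fs))
    ov = int(round(overlap_s * signal.fs))
    step = seg - ov
    segments: list[tuple[int, int]] = []
    start = 0
    while True:
        end = min(start + seg, n)
        segments.append((start, end))
        if end >= n:
            break
        start += step
    return SegmentationPlan(segment_length_s, overlap_s, segments)


# ---------------------------------------------------------------------------
# Detection output
# ---------------------------------------------------------------------------

def write_detections(indices: Sequence[int] | np.ndarray, path: str | Path,
                     format: str | None = None) -> None:
    """Write detected R-peak sample indices as CSV (one per line) or WFDB."""
    idx = np.asarray(indices, dtype=np.int64)
    if idx.size and np.any(np.diff(idx) <= 0):
        raise ValueError("detections must be strictly increasing")
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix == ".csv" else "wfdb_ann"
    if format == "csv":
        with open(path, "w") as fh:
            fh.write("sample\n")
            for i in idx:
                fh.write(f"{int(i)}\n")
    elif format == "wfdb_ann":
        write_annotations(AnnotationSet(idx, ["N"] * idx.size), path)
    else:
        raise ValueError(f"unknown detections format: {format!r}")


def read_detections(path: str | Path, format: str | None = None) -> np.ndarray:
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix == ".csv" else "wfdb_ann"
    if format == "csv":
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        if lines and lines[0] == "sample":
            lines = lines[1:]
        return np.asarray([int(v) for v in lines], dtype=np.int64)
    return read_annotations(path).indices
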