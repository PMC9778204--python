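"""ECG record reading, segmentation, and wavelet denoising.

Records come either from plain CSV (header line ``fs=<Hz>``, one sample per
row, amplitudes in mV) or from PhysioNet WFDB .hea/.dat pairs when the
optional ``wfdb`` package is installed. Fixed-duration, non-overlapping
segments are cut from a record, and each segment is denoised by an 8-level
'bior2.6' wavelet decomposition: the coarsest approximation band (baseline
wander) is zeroed and the two finest detail bands (high-frequency noise)
are soft-thresholded with the universal threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pywt

__all__ = [
    "ECGRecord",
    "Segment",
    "read_record",
    "write_csv",
    "segment",
    "minimal_segment_time",
    "denoise",
]

MIN_DENOISE_LENGTH = 256  # 8-level 'bior2.6' decomposition needs > 256 samples


@dataclass(frozen=True)
class ECGRecord:
    """A single-channel ECG trace in mV with its sampling rate and label."""

    samples: np.ndarray
    fs: float
    label: str = "unknown"  # one of {"NSR", "CHF", "unknown"}
    record_id: str = ""
    channel: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be > 0, got {self.fs}")
        if len(self.samples) == 0:
            raise ValueError("record has no samples")


@dataclass(frozen=True)
class Segment:
    """A fixed-duration window of a record; [start, start+len) half-open."""

    samples: np.ndarray
    fs: float
    duration: float
    label: str = "unknown"
    record_id: str = ""
    start: int = 0

    def __post_init__(self):
        expected = int(round(self.duration * self.fs))
        if len(self.samples) != expected:
            raise ValueError(
                f"segment length {len(self.samples)} != duration*fs={expected}")


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as ECG data."""


def read_record(path: str | Path, format: str = "csv", channel: int = 0,
                label: str = "unknown") -> ECGRecord:
    """Read one channel of an ECG record from CSV or WFDB.

    The class label is taken from the ``label`` argument (or, for WFDB,
    left as given) — it is never guessed from the signal content.
    """
    path = Path(path)
    if format == "csv":
        return _read_csv(path, label=label)
    if format == "wfdb":
        try:
            import wfdb  # optional dependency, not needed for CSV workflows
        except ImportError as exc:  # pragma: no cover - env without wfdb
            raise ImportError(
                "reading WFDB records requires the optional 'wfdb' package "
                "(pip install wfdb)") from exc
        rec = wfdb.rdrecord(str(path.with_suffix("")))
        if channel >= rec.n_sig:
            raise ValueError(f"channel {channel} out of range "
                             f"(record has {rec.n_sig} signals)")
        return ECGRecord(samples=np.asarray(rec.p_signal[:, channel], float),
                         fs=float(rec.fs), label=label,
                         record_id=rec.record_name, channel=channel)
    raise FormatError(f"unknown format {format!r} (use 'csv' or 'wfdb')")


def _read_csv(path: Path, label: str) -> ECGRecord:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("fs="):
            raise FormatError(
                f"{path}: first line must be 'fs=<Hz>', got {header!r}")
        try:
            fs = float(header[3:])
        except ValueError as exc:
            raise FormatError(f"{path}: cannot parse sampling rate "
                              f"from {header!r}") from exc
        samples = np.loadtxt(fh, dtype=float, ndmin=1)
    return ECGRecord(samples=samples, fs=fs, label=label, record_id=path.stem)


def write_csv(path: str | Path, samples: np.ndarray, fs: float) -> None:
    """Write samples in the package CSV dialect (``fs=<Hz>`` header)."""
    with open(path, "w") as fh:
        fh.write(f"fs={fs:g}\n")
        np.savetxt(fh, np.asarray(samples), fmt="%.10g")


def minimal_segment_time(n_min: int, fs: float) -> float:
    """Shortest segment duration (s) providing ``n_min`` samples at ``fs``."""
    if fs <= 0:
        raise ValueError(f"sampling rate must be > 0, got {fs}")
    return n_min / fs


def segment(record: ECGRecord, t: float) -> list[Segment]:
    """Cut a record into consecutive non-overlapping ``t``-second segments.

    The trailing remainder shorter than ``t`` seconds is discarded; if the
    whole record is shorter than one segment, an empty list is returned
    with a warning.
    """
    seg_len = int(round(t * record.fs))
    if seg_len < 1:
        raise ValueError(f"t*fs must be >= 1, got {t}*{record.fs}")
    n_seg = len(record.samples) // seg_len
    if n_seg == 0:
        warnings.warn(
            f"record {record.record_id!r} ({len(record.samples)} samples) "
            f"shorter than one {t}-s segment ({seg_len} samples)",
            stacklevel=2)
        return []
    return [
        Segment(samples=record.samples[i * seg_len:(i + 1) * seg_len],
                fs=record.fs, duration=t, label=record.label,
                record_id=record.record_id, start=i * seg_len)
        for i in range(n_seg)
    ]


def _denoise_array(x: np.ndarray, wavelet: str, levels: int) -> np.ndarray:
    with warnings.catch_warnings():
        # an 8-level decomposition of a short (>256) segment is legitimate
        # here even though the coarsest bands are boundary-dominated
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, wavelet, level=levels, mode="symmetric")
    # coeffs = [cA_levels, cD_levels, ..., cD_1]
    coeffs[0] = np.zeros_like(coeffs[0])  # baseline wander lives here
    finest = coeffs[-1]
    sigma_hat = np.median(np.abs(finest)) / 0.6745
    thr = sigma_hat * np.sqrt(2.0 * np.log(len(x)))
    if thr > 0:
        for band in (-1, -2):  # two finest detail levels
            coeffs[band] = pywt.threshold(coeffs[band], thr, mode="soft")
    out = pywt.waverec(coeffs, wavelet, mode="symmetric")
    return out[: len(x)]


def denoise(seg: Segment | np.ndarray, wavelet: str = "bior2.6",
            levels: int = 8) -> Segment | np.ndarray:
    """Remove baseline drift and high-frequency noise from a segment.

    Zeroes the level-``levels`` approximation coefficients and applies
    universal soft thresholding (sigma estimated from the finest-detail
    median absolute deviation) to the two finest detail bands. Requires
    strictly more than 256 samples for the default 8-level decomposition.
    Accepts a :class:`Segment` (returned as a new Segment) or a bare array.
    """
    x = seg.samples if isinstance(seg, Segment) else np.asarray(seg, float)
    if len(x) <= MIN_DENOISE_LENGTH:
        raise ValueError(
            f"denoising needs length > {MIN_DENOISE_LENGTH}, got {len(x)}")
    out = _denoise_array(x, wavelet, levels)
    if isinstance(seg, Segment):
        return replace(seg, samples=out)
    return out
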