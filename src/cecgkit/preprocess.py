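"""Band-pass filtering, overlapped segmentation and per-segment z-scoring.

The preprocessing chain mirrors how unconstrained cECG records are made
usable: a 2nd-order Butterworth band-pass over [0.05, 40] Hz removes DC
offset and out-of-band interference while keeping the physiologically
informative spectrum; the filtered record is cut into fixed-length
windows (2 s or 4 s) with configurable overlap (50% by default, which
doubles the segment count and acts as data augmentation); each window is
z-scored so the classifier sees shape, not absolute amplitude.

Filtering is zero-phase (forward-backward), so R-peak timing is not
shifted; the magnitude response is therefore the squared single-pass
Butterworth response.  Indexing is 0-based with half-open windows
``[start, start + L)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import (
    InvalidBandError,
    InvalidOverlapError,
    InvalidParameterError,
    InvalidSignalError,
    MissingAnnotationError,
    ZeroVarianceError,
)
from .simulate import SyntheticRecord

__all__ = [
    "FilterSpec",
    "Segment",
    "SegmentDataset",
    "bandpass",
    "segment_record",
    "n_segments",
    "normalize_segment",
    "assemble_dataset",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification (order 2, [0.05, 40] Hz default)."""

    family: str = "butterworth"
    order: int = 2
    band: tuple[float, float] = (0.05, 40.0)

    def __post_init__(self) -> None:
        if self.family.lower() != "butterworth":
            raise InvalidParameterError(f"unsupported filter family {self.family!r}")
        low, high = self.band
        if not 0 < low < high:
            raise InvalidBandError(f"need 0 < low < high, got {self.band}")
        if self.order < 1:
            raise InvalidParameterError("order must be >= 1")


@dataclass
class Segment:
    """One fixed-length window with optional quality/position labels."""

    samples: np.ndarray
    start_index: int
    record_id: str = ""
    quality: str | None = None
    position: str | None = None

    @property
    def length(self) -> int:
        return len(self.samples)


def bandpass(signal: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a 1-D signal.

    Output length equals input length.  Because the filter is applied
    forward and backward, the effective magnitude response is the square
    of the single-pass response (band edges sit at 1/2 rather than 1/sqrt(2)).
    """
    spec = spec or FilterSpec()
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidSignalError("signal contains non-finite samples")
    low, high = spec.band
    if high >= fs / 2:
        raise InvalidBandError(f"high edge {high} Hz not below Nyquist {fs / 2} Hz")
    if x.size <= 3 * spec.order:
        raise InvalidSignalError(f"signal too short ({x.size}) for order {spec.order}")
    sos = sps.butter(spec.order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def n_segments(n_samples: int, window: int, step: int) -> int:
    """Number of complete sliding windows: floor((N - L)/step) + 1, or 0."""
    if n_samples < window:
        return 0
    return (n_samples - window) // step + 1


def segment_record(
    signal: np.ndarray,
    fs: float,
    seg_len_s: float,
    overlap_frac: float = 0.5,
    record_id: str = "",
) -> list[Segment]:
    """Cut a record into fixed-length windows with fractional overlap.

    Window length is ``round(fs * seg_len_s)`` samples, the step is
    ``round(L * (1 - overlap_frac))``; trailing samples that do not fill a
    window are dropped.
    """
    if not 0 <= overlap_frac < 1:
        raise InvalidOverlapError(f"overlap_frac must lie in [0, 1), got {overlap_frac}")
    x = np.asarray(signal, dtype=float)
    window = int(round(fs * seg_len_s))
    step = int(round(window * (1.0 - overlap_frac)))
    if step == 0:
        raise InvalidOverlapError("overlap too large: step rounds to 0 samples")
    count = n_segments(x.size, window, step)
    return [
        Segment(samples=x[i * step : i * step + window], start_index=i * step, record_id=record_id)
        for i in range(count)
    ]


def normalize_segment(segment: np.ndarray) -> np.ndarray:
    """z-score with the population standard deviation.

    Raises ZeroVarianceError for (numerically) constant segments instead
    of silently returning zeros; callers decide whether to drop or
    relabel such windows.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 2:
        raise InvalidParameterError("segment must contain at least 2 samples")
    sd = x.std()  # population sd (ddof=0)
    if sd < 1e-12:
        raise ZeroVarianceError("segment variance is numerically zero")
    return (x - x.mean()) / sd


@dataclass
class SegmentDataset:
    """Normalized labeled windows as a design matrix plus label arrays."""

    X: np.ndarray  # (n, L) float32, z-scored
    quality: np.ndarray  # (n,) object, labels or None
    position: np.ndarray  # (n,) object, labels or None
    record_ids: np.ndarray
    start_indices: np.ndarray
    fs: float
    seg_len_s: float
    overlap_frac: float
    class_counts: dict[tuple[str | None, str | None], int] = field(default_factory=dict)
    n_discarded_straddling: int = 0
    n_discarded_zero_variance: int = 0

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, mask: np.ndarray) -> "SegmentDataset":
        counts: dict[tuple[str | None, str | None], int] = {}
        for q, p in zip(self.quality[mask], self.position[mask]):
            counts[(q, p)] = counts.get((q, p), 0) + 1
        return SegmentDataset(
            X=self.X[mask],
            quality=self.quality[mask],
            position=self.position[mask],
            record_ids=self.record_ids[mask],
            start_indices=self.start_indices[mask],
            fs=self.fs,
            seg_len_s=self.seg_len_s,
            overlap_frac=self.overlap_frac,
            class_counts=counts,
        )


def _interval_label(
    start: int, stop: int, intervals_samples: list[tuple[int, int, str, str | None]]
) -> tuple[str, str | None] | None:
    """Label of the single truth interval fully containing [start, stop), if any."""
    for lo, hi, q, p in intervals_samples:
        if lo <= start and stop <= hi:
            return q, p
    return None


def assemble_dataset(
    records: list[SyntheticRecord],
    seg_len_s: float,
    overlap_frac: float = 0.5,
    filter_spec: FilterSpec | None = None,
    allow_unlabeled: bool = False,
) -> SegmentDataset:
    """Filter, segment, label and normalize a batch of annotated records.

    Pipeline order: band-pass filter the whole record, cut into windows,
    inherit the (quality, position) label of the unique truth interval
    fully containing each window, z-score.  Windows that straddle an
    interval boundary are discarded and counted, as are zero-variance
    windows.  N-class windows keep a None position label: noise carries
    no usable position information.
    """
    filter_spec = filter_spec or FilterSpec()
    xs, quals, poss, rids, starts = [], [], [], [], []
    n_straddle = 0
    n_zerovar = 0
    fs = None
    for rec in records:
        if fs is None:
            fs = rec.fs
        elif rec.fs != fs:
            raise InvalidParameterError("all records must share one sampling frequency")
        if not rec.truth_intervals and not allow_unlabeled:
            raise MissingAnnotationError(f"record {rec.record_id!r} has no truth intervals")
        filtered = bandpass(rec.samples, rec.fs, filter_spec)
        window = int(round(rec.fs * seg_len_s))
        intervals = [
            (int(round(s * rec.fs)), int(round(e * rec.fs)), q, (None if q == "N" else p))
            for (s, e, q, p) in rec.truth_intervals
        ]
        for seg in segment_record(filtered, rec.fs, seg_len_s, overlap_frac, rec.record_id):
            label = _interval_label(seg.start_index, seg.start_index + window, intervals)
            if label is None:
                if rec.truth_intervals or not allow_unlabeled:
                    n_straddle += 1
                    continue
                label = (None, None)
            try:
                z = normalize_segment(seg.samples)
            except ZeroVarianceError:
                n_zerovar += 1
                continue
            xs.append(z.astype(np.float32))
            quals.append(label[0])
            poss.append(label[1])
            rids.append(seg.record_id)
            starts.append(seg.start_index)

    if fs is None:
        raise InvalidParameterError("no records supplied")
    X = np.asarray(xs, dtype=np.float32) if xs else np.empty((0, int(round(fs * seg_len_s))), np.float32)
    quality = np.array(quals, dtype=object)
    position = np.array(poss, dtype=object)
    counts: dict[tuple[str | None, str | None], int] = {}
    for q, p in zip(quals, poss):
        counts[(q, p)] = counts.get((q, p), 0) + 1
    return SegmentDataset(
        X=X,
        quality=quality,
        position=position,
        record_ids=np.array(rids, dtype=object),
        start_indices=np.asarray(starts, dtype=int),
        fs=fs,
        seg_len_s=seg_len_s,
        overlap_frac=overlap_frac,
        class_counts=counts,
        n_discarded_straddling=n_straddle,
        n_discarded_zero_variance=n_zerovar,
    )
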