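"""Signal conditioning: bandpass filtering, min-max normalization, sliding
window segmentation and segment labeling.

Defaults follow the pipeline's study conditions: a fourth-order Butterworth
bandpass of 0.5-40 Hz applied zero-phase (forward-backward, preserving
R-peak timing at the cost of doubling the effective order), 10 s windows with
50% overlap, and per-lead per-segment min-max scaling to [0, 1].

A segment's class label is decided over the beats whose R index falls inside
the window, by severity priority V > S > E > N (a window containing any
ventricular beat is ventricular); a majority-vote rule is available as an
alternative.  Windows containing no annotated beat are dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .io import BeatAnnotation, CLASS_SYMBOLS, Recording

logger = logging.getLogger(__name__)

#: severity ordering used by the priority labeling rule (most severe first)
SEVERITY_ORDER = ("V", "S", "E", "N")


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass design parameters."""

    order: int = 4
    f_low: float = 0.5
    f_high: float = 40.0
    fs: float = 250.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValidationError(f"filter order must be >= 1, got {self.order}")
        if not 0 < self.f_low < self.f_high:
            raise ValidationError("need 0 < f_low < f_high")
        if self.f_high >= self.fs / 2:
            raise ValidationError(
                f"f_high={self.f_high} must be below Nyquist ({self.fs / 2})")

    def sos(self) -> np.ndarray:
        return sps.butter(self.order, [self.f_low, self.f_high],
                          btype="bandpass", fs=self.fs, output="sos")


@dataclass(frozen=True)
class SegmentationSpec:
    """Fixed-length sliding windows: duration ``window_s`` with fractional overlap."""

    window_s: float = 10.0
    overlap_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValidationError("window_s must be positive")
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ValidationError("overlap_frac must be in [0, 1)")

    def n_samples(self, fs: float) -> int:
        n = int(round(fs * self.window_s))
        if n < 2:
            raise ValidationError("window too short: fewer than 2 samples")
        return n

    def stride(self, fs: float) -> int:
        s = int(round(self.n_samples(fs) * (1.0 - self.overlap_frac)))
        return max(s, 1)


class LabelMap:
    """Bijective symbol <-> contiguous integer code map (alphabetical order)."""

    def __init__(self, symbols=CLASS_SYMBOLS):
        ordered = sorted(set(symbols))
        self.symbol_to_code = {s: i for i, s in enumerate(ordered)}
        self.code_to_symbol = {i: s for s, i in self.symbol_to_code.items()}

    def encode(self, symbol: str) -> int:
        return self.symbol_to_code[symbol]

    def decode(self, code: int) -> str:
        return self.code_to_symbol[int(code)]

    @property
    def n_classes(self) -> int:
        return len(self.symbol_to_code)

    def __eq__(self, other) -> bool:
        return isinstance(other, LabelMap) and self.symbol_to_code == other.symbol_to_code


@dataclass
class SegmentSet:
    """Stacked fixed-length windows: ``data`` is segments x leads x N."""

    data: np.ndarray
    start_samples: np.ndarray
    fs: float
    labels: np.ndarray | None = None
    label_map: LabelMap | None = None
    source_id: str = ""
    patient_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.start_samples = np.asarray(self.start_samples, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValidationError("segment data must be segments x leads x N")
        if len(self.start_samples) != self.data.shape[0]:
            raise ValidationError("start_samples length must equal segment count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if len(self.labels) != self.data.shape[0]:
                raise ValidationError("labels length must equal segment count")

    @property
    def n_segments(self) -> int:
        return self.data.shape[0]

    @property
    def n_leads(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def bandpass_filter(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Zero-phase Butterworth bandpass per lead; length and metadata preserved."""
    spec = spec or FilterSpec(fs=rec.fs)
    if abs(spec.fs - rec.fs) > 1e-9:
        spec = FilterSpec(order=spec.order, f_low=spec.f_low, f_high=spec.f_high, fs=rec.fs)
    sos = spec.sos()
    settle = 3 * 2 * spec.order  # forward-backward doubles effective order
    if rec.n_samples < 3 * settle:
        warnings.warn("signal shorter than 3x filter settle length; edge effects likely")
    padlen = min(rec.n_samples - 1, 3 * (2 * sos.shape[0] + 1))
    filtered = sps.sosfiltfilt(sos, rec.signal, axis=0, padlen=padlen)
    return Recording(signal=filtered, fs=rec.fs, lead_names=list(rec.lead_names),
                     patient_id=rec.patient_id, units_per_lead=rec.units_per_lead)


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Map a vector affinely onto [0, 1]; a flat vector maps to all zeros."""
    x = np.asarray(x, dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValidationError("minmax_normalize requires finite values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("zero-range segment: min-max normalization returns zeros")
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def segment_signal(rec: Recording, spec: SegmentationSpec | None = None,
                   normalize: bool = True) -> SegmentSet:
    """Cut the recording into overlapping fixed windows (trailing partial dropped).

    Window starts are 0, stride, 2*stride, ...; the segment count is
    ``floor((L - N) / stride) + 1``.  With ``normalize`` each lead of each
    segment is min-max scaled to [0, 1].
    """
    spec = spec or SegmentationSpec()
    N = spec.n_samples(rec.fs)
    stride = spec.stride(rec.fs)
    L = rec.n_samples
    if L < N:
        warnings.warn("signal shorter than one window: empty segment set")
        return SegmentSet(data=np.empty((0, rec.n_leads, N)),
                          start_samples=np.empty(0, dtype=int), fs=rec.fs,
                          source_id=rec.patient_id or "")
    n_segments = (L - N) // stride + 1
    starts = np.arange(n_segments) * stride
    data = np.empty((n_segments, rec.n_leads, N))
    for i, s in enumerate(starts):
        window = rec.signal[s:s + N].T  # leads x N
        if normalize:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                window = np.stack([minmax_normalize(w) for w in window])
        data[i] = window
    return SegmentSet(data=data, start_samples=starts, fs=rec.fs,
                      source_id=rec.patient_id or "")


def _window_label(symbols: list[str], rule: str) -> str:
    if rule == "priority":
        for sym in SEVERITY_ORDER:
            if sym in symbols:
                return sym
        raise AssertionError("unreachable")
    if rule == "majority":
        counts = {s: symbols.count(s) for s in set(symbols)}
        best = max(counts.values())
        # severity breaks ties among equally frequent classes
        for sym in SEVERITY_ORDER:
            if counts.get(sym) == best:
                return sym
    raise ValidationError(f"unknown labeling rule {rule!r}")


def encode_and_label(segments: SegmentSet, anns: list[BeatAnnotation],
                     rule: str = "priority") -> SegmentSet:
    """Assign one class label per window from the beats inside it.

    Windows are half-open ``[start, start + N)``.  Windows containing no beat
    are dropped (with a log line).  Labels are encoded through a
    deterministic alphabetical :class:`LabelMap`.
    """
    if rule not in ("priority", "majority"):
        raise ValidationError(f"unknown labeling rule {rule!r}")
    label_map = LabelMap()
    if not anns:
        warnings.warn("no annotations: all segments dropped")
    ann_idx = np.array([a.sample_index for a in anns], dtype=np.int64)
    ann_sym = np.array([a.symbol for a in anns])
    N = segments.n_samples
    keep, labels = [], []
    for i, start in enumerate(segments.start_samples):
        in_window = (ann_idx >= start) & (ann_idx < start + N)
        if not in_window.any():
            logger.info("dropping segment %d at sample %d: no beats", i, start)
            continue
        keep.append(i)
        labels.append(label_map.encode(_window_label(list(ann_sym[in_window]), rule)))
    keep = np.asarray(keep, dtype=int)
    return SegmentSet(
        data=segments.data[keep],
        start_samples=segments.start_samples[keep],
        fs=segments.fs,
        labels=np.asarray(labels, dtype=np.int64),
        label_map=label_map,
        source_id=segments.source_id,
        patient_ids=(segments.patient_ids[keep] if segments.patient_ids is not None else None),
    )
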