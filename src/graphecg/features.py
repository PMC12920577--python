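"""R-peak detection and time / frequency / non-linear feature extraction.

The per-segment feature pipeline is:

1. detect R peaks on each lead with a derivative-square-integrate detector
   (Pan-Tompkins style) with an adaptive threshold and a 0.2 s refractory
   period;
2. split the segment into ``T`` equal sub-windows and compute, per sub-window
   and lead, a fixed 14-entry feature vector: RR statistics (mean RR, SDNN,
   mean HR, beat count), spectral band powers of the sub-window signal
   (three configurable bands, their LF/HF-style ratio and the dominant
   non-DC frequency), approximate entropy, Poincare SD1/SD2 of the segment's
   RR series, and the sub-window signal mean and standard deviation;
3. impute undefined entries (e.g. SDNN with fewer than 3 beats) to 0 and
   append a boolean missingness mask, giving 28 values per (sub-window,
   lead).

Classical RR-series HRV band powers (VLF/LF/HF on the 4 Hz-resampled
tachogram) are provided separately via :func:`rr_band_powers` for
segment-level analyses; sub-window spectra use wide raw-signal bands since a
1 s window cannot resolve sub-0.4 Hz rhythms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .preprocess import SegmentSet

__all__ = [
    "RPeakList", "TimeFeatures", "PSDCurve", "FreqFeatures", "NonlinearFeatures",
    "FeatureTensor", "detect_r_peaks", "time_features", "power_spectrum",
    "band_powers", "rr_band_powers", "approximate_entropy", "apen_bruteforce",
    "poincare", "extract_feature_tensor", "FEATURE_NAMES", "RAW_SIGNAL_BANDS",
    "RR_HRV_BANDS",
]

REFRACTORY_S = 0.2

#: default spectral bands (Hz) for raw sub-window signal spectra
RAW_SIGNAL_BANDS = {"vlf": (0.5, 4.0), "lf": (4.0, 15.0), "hf": (15.0, 40.0)}
#: classical HRV bands (Hz) for the RR tachogram resampled to 4 Hz
RR_HRV_BANDS = {"vlf": (0.003, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.40)}

FEATURE_NAMES = (
    "mean_rr", "sdnn", "mean_hr", "n_beats",
    "vlf", "lf", "hf", "lf_hf_ratio", "dominant_freq",
    "apen", "sd1", "sd2", "sig_mean", "sig_sd",
)


@dataclass
class RPeakList:
    """Strictly ascending 0-based R-peak sample indices."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size > 1 and not (np.diff(self.indices) > 0).all():
            raise ValidationError("R-peak indices must be strictly ascending")

    @property
    def times(self) -> np.ndarray:
        return self.indices / self.fs

    def rr_intervals(self) -> np.ndarray:
        """RR intervals in seconds (length n_peaks - 1)."""
        return np.diff(self.times)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class TimeFeatures:
    mean_rr: float
    sdnn: float
    mean_hr: float
    n_beats: int


@dataclass
class PSDCurve:
    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        if (np.asarray(self.power) < 0).any():
            raise ValidationError("PSD power must be nonnegative")


@dataclass
class FreqFeatures:
    vlf_power: float
    lf_power: float
    hf_power: float
    total_power: float
    lf_hf_ratio: float
    dominant_freq: float


@dataclass
class NonlinearFeatures:
    apen: float
    sd1: float
    sd2: float


@dataclass
class FeatureTensor:
    """Model input: ``values`` is segments x T x leads x d_feat, plus masks."""

    values: np.ndarray
    mask: np.ndarray  # 1.0 where the matching value was missing and imputed
    labels: np.ndarray | None
    feature_names: tuple[str, ...] = FEATURE_NAMES
    patient_ids: np.ndarray | None = None

    @property
    def model_input(self) -> np.ndarray:
        """Values concatenated with masks along the feature axis."""
        return np.concatenate([self.values, self.mask], axis=-1)

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def detect_r_peaks(signal: np.ndarray, fs: float) -> RPeakList:
    """Pan-Tompkins-style QRS detector on a (bandpass-filtered) single lead.

    Derivative -> squaring -> moving-window integration (150 ms), candidate
    local maxima spaced by the 0.2 s refractory period, and a running
    signal/noise threshold (THR = noise + 0.25 * (signal - noise)).  Accepted
    candidates are relocated to the local signal maximum within +/-50 ms.
    The threshold is proportional to signal scale, so amplitude scaling does
    not change the detected indices.
    """
    x = np.asarray(signal, dtype=np.float64)
    if fs < 100:
        raise ValidationError("detect_r_peaks requires fs >= 100 Hz")
    if x.size < int(0.3 * fs) or np.ptp(x) == 0:
        return RPeakList(indices=np.empty(0, dtype=int), fs=fs)

    deriv = np.gradient(x)
    sq = deriv * deriv
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(integ, distance=max(refractory, 1))
    if cand.size == 0:
        return RPeakList(indices=np.empty(0, dtype=int), fs=fs)

    # initialize running estimates from the strongest early candidates
    spki = float(np.max(integ[cand]))
    npki = float(np.median(integ[cand])) * 0.1
    accepted: list[int] = []
    for c in cand:
        thr = npki + 0.25 * (spki - npki)
        if integ[c] >= thr:
            spki = 0.125 * integ[c] + 0.875 * spki
            accepted.append(c)
        else:
            npki = 0.125 * integ[c] + 0.875 * npki

    # relocate to the signal's local maximum within +/-50 ms
    half = int(round(0.05 * fs))
    peaks: list[int] = []
    for c in accepted:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        p = lo + int(np.argmax(x[lo:hi]))
        if peaks and p - peaks[-1] < refractory:
            # keep the larger of the two colliding peaks
            if x[p] > x[peaks[-1]]:
                peaks[-1] = p
            continue
        if not peaks or p > peaks[-1]:
            peaks.append(p)
    return RPeakList(indices=np.asarray(peaks, dtype=np.int64), fs=fs)


# ---------------------------------------------------------------------------
# time-domain features
# ---------------------------------------------------------------------------

def time_features(peaks: RPeakList) -> TimeFeatures:
    """Mean RR / SDNN / mean HR from consecutive R-peak times.

    With fewer than 2 peaks the RR statistics are NaN (missing); SDNN
    additionally needs at least 2 intervals and is NaN otherwise.
    """
    n = len(peaks)
    if n < 2:
        return TimeFeatures(mean_rr=math.nan, sdnn=math.nan, mean_hr=math.nan, n_beats=n)
    rr = peaks.rr_intervals()
    mean_rr = float(np.mean(rr))
    sdnn = float(np.std(rr, ddof=1)) if rr.size >= 2 else math.nan
    return TimeFeatures(mean_rr=mean_rr, sdnn=sdnn, mean_hr=60.0 / mean_rr, n_beats=n)


# ---------------------------------------------------------------------------
# frequency-domain features
# ---------------------------------------------------------------------------

def power_spectrum(signal: np.ndarray, fs: float) -> PSDCurve:
    """One-sided periodogram (squared FFT magnitude, density scaling).

    Normalized so that ``sum(power) * df`` equals the signal's mean square
    (discrete Parseval identity), DC included.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size == 0:
        raise ValidationError("power_spectrum requires a non-empty signal")
    if x.size < 8:
        raise ValidationError("power_spectrum requires at least 8 samples")
    freqs, power = sps.periodogram(x, fs=fs, detrend=False)
    return PSDCurve(frequencies=freqs, power=power)


def band_powers(psd: PSDCurve, bands: dict[str, tuple[float, float]] | None = None
                ) -> FreqFeatures:
    """Trapezoidal band power integration over named (lo, hi) ranges.

    ``bands`` needs keys ``vlf``, ``lf``, ``hf``; defaults to the wide
    raw-signal bands.  The dominant frequency is the peak of the PSD
    excluding the DC bin; the LF/HF ratio is NaN when HF power is 0.
    """
    bands = bands or RAW_SIGNAL_BANDS
    f, p = psd.frequencies, psd.power
    out = {}
    for name in ("vlf", "lf", "hf"):
        lo, hi = bands[name]
        if lo < f[0] - 1e-12 or hi > f[-1] + 1e-12:
            raise ValidationError(f"band {name}=({lo}, {hi}) outside PSD grid "
                                  f"[{f[0]}, {f[-1]}]")
        grid = np.unique(np.concatenate([[lo], f[(f > lo) & (f < hi)], [hi]]))
        out[name] = float(np.trapezoid(np.interp(grid, f, p), grid))
    total = float(np.trapezoid(p, f))
    hf = out["hf"]
    ratio = out["lf"] / hf if hf > 0 else math.nan
    if p.size > 1 and np.any(p[1:] > 0):
        dominant = float(f[1 + int(np.argmax(p[1:]))])
    else:
        dominant = math.nan
    return FreqFeatures(vlf_power=out["vlf"], lf_power=out["lf"], hf_power=hf,
                        total_power=total, lf_hf_ratio=ratio, dominant_freq=dominant)


def rr_band_powers(rr: np.ndarray, resample_hz: float = 4.0) -> FreqFeatures:
    """Classical VLF/LF/HF powers of the RR tachogram.

    The RR series is placed at its cumulative beat times, linearly resampled
    to ``resample_hz``, mean-removed, and its periodogram integrated over the
    0.003-0.04 / 0.04-0.15 / 0.15-0.40 Hz bands.
    """
    rr = np.asarray(rr, dtype=np.float64)
    if rr.size < 4:
        raise ValidationError("rr_band_powers requires at least 4 RR intervals")
    t_beats = np.cumsum(rr) - rr[0]
    t_grid = np.arange(0.0, t_beats[-1], 1.0 / resample_hz)
    series = np.interp(t_grid, t_beats, rr)
    series = series - series.mean()
    psd = power_spectrum(series, resample_hz)
    return band_powers(psd, RR_HRV_BANDS)


# ---------------------------------------------------------------------------
# non-linear features
# ---------------------------------------------------------------------------

def _phi_from_pairdist(pair: np.ndarray, n: int, m: int, r: float) -> float:
    """Pincus Phi^m(r): mean log fraction of templates within Chebyshev r.

    ``pair[i, j] = |x_i - x_j|``; the Chebyshev distance between length-m
    templates is the running maximum of ``pair`` along the diagonal offsets,
    which avoids materializing an (n, n, m) array.
    """
    n_vec = n - m + 1
    dist = pair[:n_vec, :n_vec].copy()
    for k in range(1, m):
        np.maximum(dist, pair[k:k + n_vec, k:k + n_vec], out=dist)
    counts = np.count_nonzero(dist <= r, axis=1)  # self-match included
    return float(np.mean(np.log(counts / n_vec)))


def approximate_entropy(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Approximate entropy ApEn(m, r) = Phi^m(r) - Phi^(m+1)(r).

    The standard Pincus estimator with Chebyshev distance and self-matches
    included; ``r`` defaults to 0.2 times the series standard deviation (an
    absolute floor of 1e-12 guards zero-variance input, where the result
    is 0: perfect regularity).
    """
    x = np.asarray(series, dtype=np.float64)
    if x.size <= m + 1:
        raise ValidationError(f"series length {x.size} must exceed m+1={m + 1}")
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        r = 1e-12
    pair = np.abs(x[:, None] - x[None, :])
    return _phi_from_pairdist(pair, x.size, m, r) - _phi_from_pairdist(pair, x.size, m + 1, r)


def apen_bruteforce(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """O(N^2) double-loop reference implementation of the same estimator."""
    x = np.asarray(series, dtype=np.float64)
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        r = 1e-12

    def phi(mm: int) -> float:
        n_vec = x.size - mm + 1
        logs = np.empty(n_vec)
        for i in range(n_vec):
            count = 0
            for j in range(n_vec):
                d = 0.0
                for k in range(mm):
                    d = max(d, abs(x[i + k] - x[j + k]))
                if d <= r:
                    count += 1
            logs[i] = np.log(count / n_vec)
        return float(np.mean(logs))

    return phi(m) - phi(m + 1)


def poincare(rr: np.ndarray) -> tuple[float, float]:
    """Poincare plot short/long axis SDs of successive RR pairs.

    ``sd1 = sqrt(Var(diff(rr)) / 2)``, ``sd2 = sqrt(2 Var(rr) - sd1^2)``
    with population variances; a negative sd2 radicand (numeric) clips to 0.
    """
    rr = np.asarray(rr, dtype=np.float64)
    if rr.size < 3:
        raise ValidationError("poincare requires at least 3 RR intervals")
    sd1_sq = np.var(np.diff(rr)) / 2.0
    sd2_sq = 2.0 * np.var(rr) - sd1_sq
    if sd2_sq < 0:
        import warnings
        warnings.warn("negative SD2 radicand clipped to 0")
        sd2_sq = 0.0
    return float(np.sqrt(sd1_sq)), float(np.sqrt(sd2_sq))


# ---------------------------------------------------------------------------
# feature tensor assembly
# ---------------------------------------------------------------------------

def _subwindow_features(seg: np.ndarray, fs: float, T: int, m: int, r_frac: float,
                        bands: dict[str, tuple[float, float]]) -> np.ndarray:
    """Features for one lead of one segment; returns (T, d_feat) with NaN = missing."""
    N = seg.size
    sub_len = N // T
    peaks = detect_r_peaks(seg, fs)
    p_idx = peaks.indices
    p_t = peaks.times
    rr_all = peaks.rr_intervals()
    # Poincare over the whole segment's RR series (too few beats per sub-window)
    if rr_all.size >= 3:
        sd1, sd2 = poincare(rr_all)
    else:
        sd1 = sd2 = math.nan

    out = np.full((T, len(FEATURE_NAMES)), math.nan)
    for t in range(T):
        lo, hi = t * sub_len, (t + 1) * sub_len
        sub = seg[lo:hi]
        in_sub = (p_idx >= lo) & (p_idx < hi)
        n_beats = int(np.count_nonzero(in_sub))
        # RR intervals assigned to the sub-window of their closing peak
        if rr_all.size:
            closing = p_idx[1:]
            rr_sub = rr_all[(closing >= lo) & (closing < hi)]
        else:
            rr_sub = np.empty(0)
        mean_rr = float(np.mean(rr_sub)) if rr_sub.size >= 1 else math.nan
        sdnn = float(np.std(rr_sub, ddof=1)) if rr_sub.size >= 2 else math.nan
        mean_hr = 60.0 / mean_rr if rr_sub.size >= 1 else math.nan

        psd = power_spectrum(sub, fs)
        ff = band_powers(psd, bands)

        sd = float(np.std(sub))
        r = r_frac * sd
        apen = approximate_entropy(sub, m=m, r=r) if sub.size > m + 1 else math.nan

        out[t] = [mean_rr, sdnn, mean_hr, n_beats,
                  ff.vlf_power, ff.lf_power, ff.hf_power, ff.lf_hf_ratio,
                  ff.dominant_freq, apen, sd1, sd2, float(np.mean(sub)), sd]
    return out


def extract_feature_tensor(segments: SegmentSet, T: int = 10, m: int = 2,
                           r_frac: float = 0.2,
                           bands: dict[str, tuple[float, float]] | None = None
                           ) -> FeatureTensor:
    """Per-segment, per-lead, per-sub-window feature tensor for the model.

    Each segment is split into ``T`` equal sub-windows (trailing remainder
    samples are ignored).  Missing values are imputed to 0 with a parallel
    mask tensor set to 1.  Output shape: segments x T x leads x 14.
    """
    if T < 1 or T > segments.n_samples:
        raise ValidationError(f"T={T} must be in [1, samples per segment]")
    if segments.n_samples // T <= m + 1:
        raise ValidationError("sub-windows too short for the ApEn embedding")
    bands = bands or RAW_SIGNAL_BANDS
    n_seg, n_leads = segments.n_segments, segments.n_leads
    values = np.empty((n_seg, T, n_leads, len(FEATURE_NAMES)))
    for i in range(n_seg):
        for lead in range(n_leads):
            values[i, :, lead, :] = _subwindow_features(
                segments.data[i, lead], segments.fs, T, m, r_frac, bands)
    mask = np.isnan(values).astype(np.float64)
    values = np.nan_to_num(values, nan=0.0)
    return FeatureTensor(values=values, mask=mask, labels=segments.labels,
                         patient_ids=segments.patient_ids)
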