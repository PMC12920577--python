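"""Seeded generator of labeled multi-lead Holter-like ECG recordings.

Each beat is a sum of Gaussian bumps — one per P, Q, R, S and T wave — placed
on an RR grid, which gives analytic control over peak amplitudes and widths
(useful for exact tests) while producing a plausible P-QRS-T morphology.
The four rhythm classes differ in timing and shape:

* ``N`` — normal sinus morphology;
* ``S`` — supraventricular: premature (shortened preceding RR) with a reduced
  P wave;
* ``V`` — ventricular: widened QRS (about three times the normal width),
  absent P wave, inverted T, slightly premature;
* ``E`` — ectopic: normal timing but displaced R-wave center and altered
  amplitude.

Per-beat classes follow a sticky first-order Markov chain whose stationary
distribution equals ``class_probs``: when a beat switches class it draws the
new class from ``class_probs``, and it repeats the previous class with
probability ``class_persistence``.  Run-structured rhythms mimic the episodic
nature of real arrhythmias and keep fixed windows close to single-class.

Noise is additive: a baseline-wander sinusoid, a powerline sinusoid and white
Gaussian noise, independently drawn per lead.  Leads are gain-scaled copies
of one underlying source plus their own noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ResolutionError, ValidationError
from .io import BeatAnnotation, CLASS_SYMBOLS, Recording

__all__ = [
    "Wave", "BeatTemplate", "NoiseSpec", "SimConfig",
    "DEFAULT_TEMPLATES", "synth_beat", "synth_recording", "add_noise",
]


@dataclass(frozen=True)
class Wave:
    """One Gaussian bump: center offset (s, relative to R), amplitude (mV), width (s)."""

    center: float
    amplitude: float
    width: float


@dataclass(frozen=True)
class BeatTemplate:
    """Morphology of one beat class as P/Q/R/S/T Gaussian components."""

    class_symbol: str
    waves: tuple[Wave, ...]
    rr_scale: float = 1.0  # multiplicative prematurity on the preceding RR

    def __post_init__(self) -> None:
        if self.class_symbol not in CLASS_SYMBOLS:
            raise ValidationError(f"class_symbol must be one of {CLASS_SYMBOLS}")
        if not 0.3 < self.rr_scale <= 1.5:
            raise ValidationError(f"rr_scale must be in (0.3, 1.5], got {self.rr_scale}")
        r = self.r_wave
        if r.amplitude <= 0:
            raise ValidationError("R amplitude must be positive")
        for w in self.waves:
            if w.width <= 0:
                raise ValidationError("wave widths must be positive")

    @property
    def r_wave(self) -> Wave:
        return max(self.waves, key=lambda w: w.amplitude)

    @property
    def span(self) -> tuple[float, float]:
        """Time extent covering every component out to 4 sigma."""
        lo = min(w.center - 4 * w.width for w in self.waves)
        hi = max(w.center + 4 * w.width for w in self.waves)
        return lo, hi


def _template(symbol: str, p_amp: float, p_center: float, qrs_width: float,
              r_amp: float, r_center: float, t_amp: float,
              rr_scale: float) -> BeatTemplate:
    w = qrs_width
    return BeatTemplate(
        class_symbol=symbol,
        rr_scale=rr_scale,
        waves=(
            Wave(p_center, p_amp, 0.025),              # P
            Wave(r_center - 3.0 * w, -0.15, w),        # Q
            Wave(r_center, r_amp, w),                  # R
            Wave(r_center + 3.0 * w, -0.25, w),        # S
            Wave(r_center + 0.30, t_amp, 0.06),        # T
        ),
    )


#: Default morphologies per class.  The widened-V QRS (x3) and the S/E timing
#: and amplitude changes are the package's own modeling defaults; they are
#: overridable per simulation.
DEFAULT_TEMPLATES: dict[str, BeatTemplate] = {
    "N": _template("N", p_amp=0.15, p_center=-0.22, qrs_width=0.018,
                   r_amp=1.0, r_center=0.0, t_amp=0.30, rr_scale=1.0),
    "S": _template("S", p_amp=0.05, p_center=-0.20, qrs_width=0.018,
                   r_amp=1.0, r_center=0.0, t_amp=0.30, rr_scale=0.7),
    "V": _template("V", p_amp=0.0, p_center=-0.22, qrs_width=0.054,
                   r_amp=1.2, r_center=0.0, t_amp=-0.35, rr_scale=0.85),
    "E": _template("E", p_amp=0.12, p_center=-0.26, qrs_width=0.018,
                   r_amp=0.55, r_center=0.08, t_amp=0.40, rr_scale=1.0),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise: baseline-wander + powerline sinusoids + white noise."""

    baseline_amp: float = 0.0   # mV
    baseline_freq: float = 0.3  # Hz
    white_sd: float = 0.0       # mV
    powerline_amp: float = 0.0  # mV
    powerline_freq: float = 50.0  # Hz

    def __post_init__(self) -> None:
        if self.baseline_amp < 0 or self.white_sd < 0 or self.powerline_amp < 0:
            raise ValidationError("noise amplitudes and sd must be >= 0")

    @property
    def silent(self) -> bool:
        return self.baseline_amp == 0 and self.white_sd == 0 and self.powerline_amp == 0


@dataclass(frozen=True)
class SimConfig:
    """Conditions for one simulated Holter recording."""

    fs: float = 250.0
    duration: float = 60.0
    n_leads: int = 2
    mean_hr: float = 75.0          # bpm
    hr_jitter_sd: float = 0.03     # s, sd of RR jitter
    class_probs: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0)  # over (N, S, V, E)
    class_persistence: float = 0.9
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    lead_gain: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 100:
            raise ValidationError(f"fs must be >= 100 Hz, got {self.fs}")
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.shape != (4,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValidationError("class_probs must be 4 nonnegative values summing to 1")
        if self.duration * self.mean_hr / 60.0 < 1:
            raise ValidationError("duration too short for a single beat at mean_hr")
        if not 0.0 <= self.class_persistence < 1.0:
            raise ValidationError("class_persistence must be in [0, 1)")
        if self.lead_gain is not None and len(self.lead_gain) != self.n_leads:
            raise ValidationError("lead_gain length must equal n_leads")


def synth_beat(template: BeatTemplate, fs: float) -> np.ndarray:
    """Render one beat waveform at ``fs``; returns the sampled span.

    The value at the R center equals the R amplitude to within the overlap of
    the neighboring Gaussians (about 1%).
    """
    narrowest = min(w.width for w in template.waves)
    if narrowest * fs < 2:
        raise ResolutionError(
            f"fs={fs} cannot resolve a wave of width {narrowest}s (need width*fs >= 2)")
    lo, hi = template.span
    n = int(round((hi - lo) * fs))
    t = lo + np.arange(n) / fs
    return _render(template, t)


def _render(template: BeatTemplate, t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t)
    for w in template.waves:
        if w.amplitude != 0.0:
            out += w.amplitude * np.exp(-0.5 * ((t - w.center) / w.width) ** 2)
    return out


def add_noise(signal: np.ndarray, fs: float, noise: NoiseSpec,
              seed: int | np.random.Generator = 0) -> np.ndarray:
    """Add the configured sinusoids and white noise to every lead independently.

    A zero noise spec returns the input unchanged (bitwise).
    """
    if noise.silent:
        return signal
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sig = np.asarray(signal, dtype=np.float64)
    squeeze = sig.ndim == 1
    if squeeze:
        sig = sig[:, None]
    out = sig.copy()
    t = np.arange(sig.shape[0]) / fs
    for lead in range(sig.shape[1]):
        if noise.baseline_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            out[:, lead] += noise.baseline_amp * np.sin(2 * np.pi * noise.baseline_freq * t + phase)
        if noise.powerline_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            out[:, lead] += noise.powerline_amp * np.sin(
                2 * np.pi * noise.powerline_freq * t + phase)
        if noise.white_sd > 0:
            out[:, lead] += rng.normal(0.0, noise.white_sd, size=sig.shape[0])
    return out[:, 0] if squeeze else out


def _draw_classes(n: int, probs: np.ndarray, persistence: float,
                  rng: np.random.Generator) -> list[str]:
    symbols = list(CLASS_SYMBOLS)
    classes = [symbols[rng.choice(4, p=probs)]]
    for _ in range(n - 1):
        if rng.random() < persistence:
            classes.append(classes[-1])
        else:
            classes.append(symbols[rng.choice(4, p=probs)])
    return classes


def synth_recording(config: SimConfig,
                    templates: dict[str, BeatTemplate] | None = None
                    ) -> tuple[Recording, list[BeatAnnotation]]:
    """Simulate one multi-lead recording plus its beat annotations.

    Deterministic for a given ``config`` (including ``config.seed``).  The
    annotation for each beat sits at the R-wave center sample.
    """
    templates = templates or DEFAULT_TEMPLATES
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n_samples = int(round(config.duration * fs))
    base_rr = 60.0 / config.mean_hr

    # generous upper bound on beat count (prematurity shortens RRs)
    max_beats = int(np.ceil(config.duration / (0.3 * base_rr))) + 2
    classes = _draw_classes(max_beats, np.asarray(config.class_probs), config.class_persistence,
                            rng)
    jitter = rng.normal(0.0, config.hr_jitter_sd, size=max_beats) if config.hr_jitter_sd > 0 \
        else np.zeros(max_beats)

    r_times: list[float] = []
    beat_classes: list[str] = []
    t = base_rr  # first beat one nominal RR in
    for i, symbol in enumerate(classes):
        rr = base_rr * templates[symbol].rr_scale + jitter[i]
        rr = max(rr, 0.3 * base_rr)
        if i > 0:
            t = r_times[-1] + rr
        if t >= config.duration - 0.05:
            break
        r_times.append(t)
        beat_classes.append(symbol)

    source = np.zeros(n_samples)
    time = np.arange(n_samples) / fs
    anns: list[BeatAnnotation] = []
    for t_r, symbol in zip(r_times, beat_classes):
        tpl = templates[symbol]
        lo, hi = tpl.span
        i0 = max(0, int(np.floor((t_r + lo) * fs)))
        i1 = min(n_samples, int(np.ceil((t_r + hi) * fs)) + 1)
        source[i0:i1] += _render_shifted(tpl, time[i0:i1] - t_r)
        r_center = tpl.r_wave.center
        idx = int(round((t_r + r_center) * fs))
        if 0 <= idx < n_samples:
            anns.append(BeatAnnotation(sample_index=idx, symbol=symbol))

    gains = np.asarray(config.lead_gain) if config.lead_gain is not None \
        else np.linspace(1.0, 0.7, config.n_leads)
    signal = source[:, None] * gains[None, :]
    signal = add_noise(signal, fs, config.noise, rng)

    lead_names = [f"lead{i}" for i in range(config.n_leads)]
    rec = Recording(signal=signal, fs=fs, lead_names=lead_names,
                    patient_id=f"sim{config.seed}")
    return rec, sorted(anns)


def _render_shifted(template: BeatTemplate, t_rel: np.ndarray) -> np.ndarray:
    return _render(template, t_rel)
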