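"""Heart-rate-variability features of a simulated rhythm.

Computes RR statistics (mean RR, SDNN), Poincare SD1/SD2, approximate
entropy of the RR series, and VLF/LF/HF band powers of the 4 Hz-resampled
tachogram.
"""

import numpy as np

from graphecg import (SimConfig, approximate_entropy, bandpass_filter,
                      detect_r_peaks, poincare, rr_band_powers, synth_recording,
                      time_features)

rec, _ = synth_recording(SimConfig(fs=250.0, duration=300.0, mean_hr=70.0,
                                   hr_jitter_sd=0.04, seed=5))
filtered = bandpass_filter(rec)
peaks = detect_r_peaks(filtered.signal[:, 0], rec.fs)
rr = peaks.rr_intervals()

tf = time_features(peaks)
sd1, sd2 = poincare(rr)
apen = approximate_entropy(rr)
bands = rr_band_powers(rr)

print(f"{tf.n_beats} beats, mean RR {tf.mean_rr * 1000:.0f} ms, "
      f"mean HR {tf.mean_hr:.1f} bpm, SDNN {tf.sdnn * 1000:.1f} ms")
print(f"Poincare SD1 {sd1 * 1000:.1f} ms, SD2 {sd2 * 1000:.1f} ms")
print(f"ApEn(m=2, r=0.2*sd) of the RR series: {apen:.3f}")
print(f"tachogram band powers: VLF {bands.vlf_power:.2e}, "
      f"LF {bands.lf_power:.2e}, HF {bands.hf_power:.2e} s^2/Hz")
# SD1 tracks beat-to-beat (short-term) variability, SD2 long-term spread;
# with pure white RR jitter SD1 and SD2 are similar and the spectrum is flat.
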