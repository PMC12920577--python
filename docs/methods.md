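# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of `graphecg`. Everything quantitative below is
recomputed by the test suite or `scripts/acceptance.py`; nothing is asserted
from memory.

## Pipeline model

**Filtering.** A fourth-order Butterworth bandpass, 0.5–40 Hz, removes
baseline wander and motion drift below 0.5 Hz and muscle/powerline noise
above 40 Hz. The filter is applied forward–backward (`sosfiltfilt`), which
doubles the effective order and gives exactly zero phase; we chose zero-phase
application (the design itself does not dictate one) because R-peak *timing*
feeds the RR features, and a causal filter would shift peaks by a
frequency-dependent lag. Consequence: measured half-power points of the
single-pass design sit at the band edges, while the effective two-pass
attenuation at any frequency is the square of the single-pass response.

**Segmentation.** Fixed windows of Δt = 10 s with 50% overlap (stride 5 s);
window starts at 0, stride, 2·stride, …, and a trailing partial window is
dropped rather than padded so the model input size is constant. The segment
count is floor((L − N)/stride) + 1, property-tested against brute-force
enumeration.

**Normalization.** Min–max to [0, 1] per lead *per segment*, applied after
filtering. The scope (whole record vs. window) is a genuine design choice;
per-segment was picked so slow amplitude drift cannot leak information
across windows. A flat window maps to all zeros with a warning rather than
erroring, because flat stretches legitimately occur in edge-case synthetic
data.

**Labels.** Symbols {E, N, S, V} map to codes 0–3 in alphabetical order. A
window's label is decided over the beats whose R sample falls inside it,
default rule *severity priority* V ≻ S ≻ E ≻ N: a window containing any
ventricular beat counts as ventricular. This biases toward sensitivity for
the dangerous classes, matching the clinical preference for low false
negative rates; a majority-vote rule is selectable. Beat-less windows are
dropped and logged.

## Features

R peaks come from a Pan–Tompkins-style detector: derivative → squaring →
150 ms moving-window integration, candidate maxima spaced by a 0.2 s
refractory period, and a running signal/noise threshold
THR = noise + 0.25·(signal − noise) with exponential updates (coefficient
0.125). Accepted candidates are relocated to the signal maximum within
±50 ms. Every quantity scales with the input, so the detector is invariant
to amplitude scaling (tested). On noise-free synthetic cohorts the detector
measures ≥ 95% recall and precision against generator ground truth.

Each 10 s segment is split into T = 10 sub-windows of 1 s (T is not dictated
by the architecture; 1 s ≈ one beat makes the transformer's sequence a
beat-scale rhythm description). Per sub-window and lead, a fixed 14-entry
vector: mean RR / SDNN / mean HR / beat count (RR intervals are detected on
the whole segment and assigned to the sub-window of their closing peak, so
sub-window boundaries do not lose intervals), three spectral band powers
with their LF/HF-style ratio and the dominant non-DC frequency, approximate
entropy, Poincaré SD1/SD2 of the segment RR series (a 1 s window has too few
beats for its own Poincaré), and the signal mean and SD. Undefined entries
(e.g. SDNN with fewer than two intervals) are imputed to 0 and flagged in a
parallel mask, giving 28 inputs per (sub-window, lead); imputation + mask
keeps the model input dense and fixed-size.

**Spectra.** `power_spectrum` is the one-sided periodogram with density
scaling and no detrending, so Σ PSD·Δf equals the signal mean square
exactly (discrete Parseval, tested at 1e-6 relative) and a constant signal
shows all power at the 0 Hz bin. Sub-window spectra use wide raw-signal
bands (defaults 0.5–4, 4–15, 15–40 Hz) because classical HRV bands are
meaningless on a 1 s raw trace; classical VLF/LF/HF (0.003–0.04, 0.04–0.15,
0.15–0.40 Hz) are computed by `rr_band_powers` on the RR tachogram linearly
resampled to 4 Hz.

**Approximate entropy.** The standard Pincus estimator
ApEn = Φᵐ(r) − Φᵐ⁺¹(r), with Chebyshev distance, self-matches included,
defaults m = 2, r = 0.2·SD (absolute floor 1e-12 for flat series, where
ApEn = 0). The vectorized implementation shares one pairwise-distance
matrix and takes running maxima along diagonal offsets; it is bit-identical
to the O(N²) double-loop reference (tested over random series), because both
compute the same integer match counts before the same log/mean reductions.

**Poincaré.** sd1 = √(Var(Δrr)/2), sd2 = √(2·Var(rr) − sd1²) with population
variances; a negative sd2 radicand (numerically possible) clips to zero with
a warning.

## The classifier

Leads are nodes of a graph (complete graph with self-loops by default;
identity and |Pearson r| ≥ 0.3 correlation strategies available). Each
sub-window's lead features pass through GCN-style graph convolutions

    h'_v = ReLU( Σ_{u∈N(v)} (1 / c_vu) · W h_u + b ),   c_vu = √(deg v · deg u)

with one weight matrix shared across nodes and the self-loop providing the
node's own contribution. Lead features are then mean-pooled, linearly
embedded to d_model, tagged with sinusoidal positional codes (base 10⁴),
and processed by post-norm transformer encoder blocks — multi-head scaled
dot-product self-attention, residual + LayerNorm, a 4·d_model feed-forward,
residual + LayerNorm, dropout 0.3 — an encoder-only stack: classification
needs no autoregressive decoder or causal masking (uniform-attention
replacement is kept as an ablation switch). Mean-pooling over time yields
h_final; a ReLU hidden layer and a softmax output layer produce class
probabilities; training minimizes mean −w_y·ln p_y (probabilities clamped at
1e-12) with Adam.

Defaults follow the tuned full-scale configuration (η = 1e-4, batch 32,
L_GNN = 3, L_Tr = 4, d_model = 128, h = 8, dropout 0.3, ReLU). Spatial
mixing (GNN over leads, per sub-window) runs before temporal mixing
(transformer over sub-windows); the extracted feature tensor is the model
input — a raw-sample embedding path is out of scope.

The network runs on a small reverse-mode autodiff engine written for this
package (`autodiff.py`/`nn.py`): tensors on numpy arrays, broadcast-aware
gradients, batched matmul, softmax/LayerNorm composites. All gradients are
verified against central finite differences in the test suite, including
through a full encoder block. Weight init is fan-scaled uniform from an
explicit seed; argmax ties break to the lowest class index; features are
z-scored with training-set statistics stored in the checkpoint.

## Synthetic Holter generator

Beats are sums of five Gaussian bumps (P, Q, R, S, T) placed on an RR grid —
analytic morphology control without an ODE integrator, so tests can assert
peak amplitudes and widths in closed form. Class morphologies (package
defaults, all overridable): **S** premature (rr_scale 0.7) with reduced P;
**V** QRS width ×3, absent P, inverted T, rr_scale 0.85; **E** normal timing
with the R center displaced +80 ms and R amplitude 0.55 with a larger T —
the E deviations are deliberately strong enough to survive per-segment
min–max normalization, which erases absolute amplitude.

Beat classes follow a sticky first-order Markov chain: repeat the previous
class with probability `class_persistence` (default 0.9), otherwise redraw
from `class_probs`; the stationary distribution equals `class_probs`.
Episodic rhythm runs are both the realistic regime (arrhythmias come in
episodes, not i.i.d. beats) and necessary for window labels to be
meaningful — with i.i.d. beats nearly every 10 s window would contain a V
beat and the priority rule would collapse to all-V.

Lead diversity is per-lead gain (linear taper) plus independent noise —
baseline-wander and powerline sinusoids with random phase and white
Gaussian noise — not a dipole model; this is enough to make the lead graph
non-degenerate. What the generator does **not** emulate: real inter-patient
morphology variability, respiration coupling, atrial-fibrillation RR
dynamics, electrode motion artifacts, or the extreme class imbalance of
clinical Holter data. Passing the synthetic benchmark therefore shows the
pipeline recovers the structure *it generates* across held-out patients; it
is not evidence of clinical performance.

## Evaluation machinery

Metrics come from one-vs-rest confusion counts with the textbook formulas;
zero denominators report 0 with support flagged. Macro, micro and
support-weighted aggregates are always reported side by side, since
headline figures in the literature mix aggregation conventions. ROC-AUC
uses the Mann–Whitney rank statistic with midrank tie handling, tested
against brute-force concordant-pair counting and scikit-learn. The paired
t-test is the closed form t = mean(d)/(sd(d)/√n), df = n − 1, two-sided p
from the t distribution (zero-variance differences: t = 0/p = 1 if the mean
is also zero, else ±∞/p = 0 with a warning).

Cross-validation folds are class-stratified at segment level or grouped by
patient (seeded patient shuffle, round-robin assignment). The default
evaluation split is **patient-level** holdout: segment-level splits leak
patient identity through adjacent overlapping windows. Grid search trains
every lattice combination per fold and picks the lowest mean validation
cross-entropy (ties: higher accuracy, then enumeration order). Early
stopping monitors validation loss with patience 5.

Mitigation utilities: (1) per-class *veto* thresholds — an abnormal argmax
below its threshold falls back to N; raising a class's threshold can only
convert its positives to N, so its FPR is non-increasing in the threshold
(property-tested over the full 0.00–0.99 grid); the optimizer scans that
grid for the highest threshold keeping sensitivity at a target, or the best
F1. (2) Class-weighted cross-entropy. (3) Temporal alert aggregation: an
alert fires at the k-th consecutive abnormal window (majority abnormal
class, severity ties); the counter resets on N and after each alert, so
k = 1 alerts on every abnormal window and long runs re-alert every k.

## Benchmark sizing

The standard synthetic benchmark (`benchmark_config`) simulates 20 patients
× 505 s at 180 Hz with 2 leads — ≈ 2,000 labeled 10 s segments — with class
mix N 40% / S–V–E 20% each, persistence 0.95, and modest noise (0.05 mV
baseline, 0.02 mV white, 0.02 mV powerline). The model is scaled down to
d_model 32, one GNN layer, one transformer layer, 4 heads, learning rate
1e-3, ≤ 15 epochs — sized to train in seconds on one CPU; the higher
learning rate accompanies the smaller model (the full-scale 1e-4 default is
tuned for the 128-dimensional stack). A quarter of the patients are held
out whole.

## Known limitations

- The E class is identifiable only through post-normalization shape ratios;
  with few patients its per-class sensitivity is the weakest (see the worked
  example) — mirroring the general difficulty of subtle-morphology classes.
- The R-peak detector assumes upright R waves after bandpass filtering;
  inverted-QRS leads would need a polarity step.
- WFDB support is single-segment format 16 only.
- The autodiff engine is CPU/numpy and sized for desk-scale models, not for
  training the full 128-dimensional configuration on large corpora.
- Threshold optimization treats classes independently (one veto at a time);
  joint optimization over all thresholds is out of scope.
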