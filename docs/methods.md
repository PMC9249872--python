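# Methods

## Problem and model

The package implements remote assessment of emotional state from
multispectral face video. The physiological premise is that autonomic
nervous system activity redistributes blood flow, hemoglobin concentration
and skin temperature across the face in emotion-dependent spatial patterns,
and that these are measurable without contact: visible and near-infrared
reflectance carries the cardiac blood-volume pulse (remote
photoplethysmography), while long-wave infrared carries temperature.

The optical model is Beer–Lambert attenuation. Light entering the skin is
attenuated as `T_z = exp(-alpha_{c,lambda} z)` along an optical path of
depth `z` through an absorbing medium; the camera sees a constant specular
term plus diffuse reflectance that falls as absorption rises. Arterial
pulsation modulates the effective path length, so each skin pixel's gray
level oscillates at the heart rate, with a wavelength-dependent depth
(hemoglobin absorbs strongly in blue/green, weakly in red).

From each 4-s trial (120 frames at 30 fps) the pipeline extracts the TSTMS
features on a common 50×35 grid, five pulse frames deep:

| feature | definition | carries |
|---|---|---|
| F1 | `TMP^LWIR`: low-passed (0.75 Hz), 1.5 Hz-resampled temperature | slow thermal changes |
| F2–F4, F7 | `I_AC^λ = Imax − Imin` for R, G, B, NIR | pulsatile amplitude |
| F5 | `I_AC^B / I_AC^R` | cross-wavelength amplitude dissimilarity |
| F6 | `|(I_R^R − I_R^B) / (Imax^R − Imax^B)|`, `I_R^λ = ln(Imax/Imin)` | baseline-adjusted absorption difference |
| F8 | `HR^G`: median of the masked green dominant-frequency map | heart rate |

`Imax`/`Imin` are pixel intensities at detected pulse peaks/troughs. Seven
spatiotemporal features × 5 × 50 × 35 = 8 750 values each, plus the F8
scalar: a 61 251-value vector per trial.

## Pipeline stages and numerical choices

**Preprocessing.** Trials are sliced to their initial 120 frames (shorter
trials are excluded, not padded). Faces are localized per channel: an
explicit bounding box when available (always, for simulated data), a
pluggable detector otherwise — the built-in detector Otsu-thresholds the
first frame and keeps the largest bright connected component. The LWIR face
is an Otsu split plus a hard 30 °C floor. Every channel is downsampled in
two stages: non-overlapping block means (10×10 for R/G/B, 5×5 for NIR/LWIR;
frames are sliced to a whole number of blocks), then bicubic interpolation
to 50 rows × 35 columns (rows = face height; origin top-left). Channels are
registered only through this shared grid — no subpixel alignment. Temporal
slicing precedes downsampling (mathematically immaterial; fixed for
reproducibility).

**Heart rate (F8).** Green-channel pixel series are band-passed to
0.75–4 Hz with a zero-phase Butterworth filter (`scipy.signal.butter`
with order 6; for a band-pass this is the conventional 12-pole reading,
applied forward–backward so peak timing is unshifted). Per-pixel FFT argmax
over positive frequencies gives a dominant-frequency map (resolution
fs/T = 0.25 Hz); the skin mask is a 5×5 uniform blur (edge-replicated),
Otsu binarization and 5×5 morphological opening, restricted to in-band
frequencies. The blur/Otsu step operates on the spectral *peak-magnitude*
map: skin pixels carry a strong coherent peak while band-limited sensor
noise does not, whereas binarizing the frequency values themselves would
favor whichever side has numerically higher frequencies. F8 is the median
of the masked nonzero frequencies (even counts: mean of the two central
values).

**Pulse events.** Peaks are detected on each pixel's min-max-normalized
band-passed series with a temporal floor of `ceil(3/4 · fs/hr)` frames
between events and a minimum prominence of 0.4 (G, NIR) or 0.2 (R, B) —
prominence thresholds are only meaningful on the normalized scale. Troughs
are peaks of the negated signal. Feature values are then read from the
band-passed series with the pixel's temporal mean restored: amplitudes
survive, slow drifts and raw noise spikes do not, and `ln(Imax/Imin)`
stays well defined. Each peak is paired with the nearest *following*
trough (one cardiac cycle); the first five pairs fill pulse frames 1–5 and
missing pairs are zero-padded. Pixels whose pulse differs in phase or count
are aligned ordinally — by pulse index, not wall-clock time. F1 takes the
first five 1.5 Hz samples of the low-passed LWIR series; its five samples
are an independent 5-sample axis, not time-locked to the pulse frames.

**Zero coding.** Zero is the single "no signal" value throughout: padded
pulse frames, guarded divisions (`x/0 → 0`) and logarithms, chin-masked
pixels (bottom 6 of 50 rows by default, configurable) and background. The
vector length never changes; masked or padded parameters are constant-zero
columns and therefore receive zero importance.

**Classification.** One-vs-one over the 5 classes: k(k−1)/2 = 10 binary
gradient-boosted-tree classifiers (LightGBM), each trained on its two
classes' trials with per-sample weights
`class_weight[i] = n_samples / (n_classes · n_samples_i)` computed on the
full training distribution. Pairwise probabilities are averaged and
renormalized into a 5-class probability vector (the coupling is a free
choice; averaging is the simplest symmetric one). Evaluation is
leave-one-subject-out: one fold per subject, the held-out subject's trials
undersampled per class to the subject's smallest class count (seeded,
uniform) so chance baselines keep textbook values — subset accuracy 0.2
and ROC AUC 0.5 for five balanced classes. Reported metrics: per-class
one-vs-rest ROC AUC averaged over folds, per-class balanced accuracy
(mean of one-vs-rest sensitivity and specificity of the final decisions),
pooled subset accuracy, and the elementwise median of per-fold confusion
matrices, row-normalized to percent.

Boosting hyperparameters are config-exposed with modest defaults tuned for
a short, very wide matrix on one CPU: 30 rounds, 4 leaves, learning rate
0.15, `min_child_samples` 5, 15 histogram bins, 50% feature subsampling
per tree, a capped histogram pool, and a binned dataset shared across the
ten pairwise fits of a fold. At 61 251 columns the per-fit cost is
dominated by per-feature bookkeeping, not by tree depth.

**Importance.** The loss-function-change contract — how much worse the
loss gets without a parameter's contribution — is implemented natively by
the trees' per-column split gain (total training-loss reduction from splits
on that column), summed over the ten binary models, clipped at zero and
normalized so all spatiotemporal entries plus F8 sum to 100%. A seeded
permutation surrogate (log-loss increase when a column or column-slab is
permuted) provides a model-agnostic cross-check; the two agree in rank on
columns that matter (Spearman ρ ≥ 0.8 in the test suite). Views:
per-feature spatial maps (sum over pulse frames) and their mean summary
map; per-pulse-frame totals; per-feature totals; per-class-pair maps from
independently retrained binary models; rectangular facial ROI statistics
(mean over ROI pixels, SD across folds, two-sided bootstrap over folds with
10⁴ seeded resamples for ROI-vs-rest); and per-gender retraining.

## The simulator: what it emulates, and what it does not

`tstms.simulator` renders trials directly from the forward model the
features are designed to invert: elliptical face on a dark (VIS) or cool
(LWIR, background < 30 °C) background, per-channel Beer–Lambert intensity
`R_s + A e^{-alpha z(t)}` with `z(t) = z0 + dz(x,y)(1 + sin(2π f t +
φ(x,y)))/2`, a smooth phase field (|φ| ≤ 0.3 rad) emulating pulse-transit
variation, LWIR as base temperature plus linear drift (no pulsatile term —
thermal video carries no usable cardiac component), Gaussian sensor noise,
and 8-bit quantization of reflectance channels (off in oracle mode, where
rendering is float64 and features match closed forms to machine
precision). Default absorption ordering `alpha_B ≥ alpha_G > alpha_R`
mirrors hemoglobin. Emotion classes are spatial modulation templates with
disjoint extra-modulation regions (amusement: cheeks; disgust: mouth/nose;
fear: forehead plus a heart-rate offset; sexual arousal: cheeks+forehead
plus thermal drift; neutral: none — smallest total modulation energy).
Template magnitudes are free parameters (no quantitative per-emotion
effect sizes exist to copy); defaults use a base path-length modulation of
0.12 with 0.25 extra in the class region, chosen once as a
clearly-separable regime, and `contrast=0` produces an exact negative
control.

Deliberately not modeled: photorealistic appearance, head motion,
blinking, facial musculature, illumination drift, non-uniformity artifacts.
Consequently, passing tests demonstrate that the pipeline correctly
inverts its own physical model and recovers planted spatial/temporal/
spectral structure — they do not demonstrate robustness to motion or to
real-world optical confounds, and synthetic classification scores say
nothing about accuracy on human data.

## Validation experiments (defaults)

`tstms.validation` fixes the experiment suite; all sizes are arguments.

- **Bookkeeping**: dimensionalities and chance baselines recomputed from
  running code (including the study's retained per-class trial counts
  27/30/26/22/25, which imply 130 trials per subject, 22-per-class
  undersampling and a fear class weight of 130/110).
- **Heart-rate recovery**: 20 subjects, true rates uniform in 0.9–1.9 Hz;
  the estimate must land within one FFT bin (0.25 Hz) in ≥ 95% of trials.
- **Beer–Lambert oracle**: noiseless unquantized trial; `I_R = alpha·dz`
  and the `I_AC` closed form to 1e−6 (measured ~1e−13).
- **Classification benchmark**: 8 subjects × 5 classes × 3 trials with the
  default templates; macro one-vs-rest ROC AUC ≥ 0.90 and subset accuracy
  above 0.2 at binomial p < 0.01. Negative control: 4 × 5 × 2 with null
  templates, accuracy inside the 99% binomial chance band.
- **Importance localization**: 10 seeded two-class cohorts (3 subjects ×
  3 trials per class) differing only in cheek modulation; the spatial
  summary map's inside-vs-outside difference must reach one-sided
  permutation p < 0.05 in ≥ 9 of 10 cohorts. The localization model uses
  many shallow trees with strong per-tree column subsampling so the
  importance map covers enough distinct pixels for a spatial permutation
  test; the ground-truth region is every pixel with planted contrast,
  including the template's smoothed edges, because trees may legitimately
  split there (gain ties resolve to the lowest column index).
- **Filter/peak contracts**: > 20 dB attenuation one octave outside the
  band; detected event trains never violate the temporal floor.

Cohort-scale simulations use 200×140 face crops (the smallest multiple-of-
grid resolution ≥ 4× the grid) to bound memory and runtime; single-trial
oracle checks use the full 500×350 / 250×175 defaults.

## Known limitations

- Ordinal pulse-frame alignment means pulse index p of one pixel need not
  be simultaneous with pulse index p of another; this matches the fixed
  5×50×35 dimensionality but discards absolute timing.
- The paper-defaults band is 0.75–4 Hz; a 0.8 Hz lower edge also appears in
  the source material's figures. The band is configurable; 0.75 is the
  default.
- With 4-s clips, F8 is quantized to 0.25 Hz; heart-rate differences below
  one bin are invisible to F8 (though not to the amplitude features).
- Split-gain importance is computed on training data (as loss-function-
  change scores are); the permutation surrogate can be pointed at held-out
  data when an unbiased view is needed.
- The automatic face detector assumes a bright face on a darker background;
  real-world use should supply a proper detector or explicit boxes through
  the pluggable interface.
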