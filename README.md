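# tstms

Transdermal spatiotemporal multispectral (TSTMS) analysis of face videos:
remote-photoplethysmography feature extraction, heart-rate estimation,
emotional-state classification and facial feature-importance mapping.

## What it does

Emotions modulate autonomic physiology, and some of that physiology is
visible from a distance: the cardiac blood-volume pulse changes skin
reflectance in the visible and near-infrared bands, and skin temperature
shows in long-wave infrared. Given synchronized RGB / NIR / LWIR recordings
of a face (4 s, 30 fps), this package:

1. localizes the face per channel and reduces everything to a common
   50×35 grid (block-mean pooling + bicubic resize);
2. estimates the heart rate `HR^G` from the green channel's per-pixel
   dominant-frequency map (band-pass 0.75–4 Hz → FFT argmax → blur/Otsu/
   opening mask → median);
3. detects per-pixel pulse peaks and troughs and assembles eight TSTMS
   features per trial — the LWIR temperature track `TMP^LWIR`, pulsatile
   amplitudes `I_AC^λ = Imax − Imin` for R/G/B/NIR, the cross-wavelength
   ratio `I_AC^B / I_AC^R`, the baseline-adjusted absorption difference
   `|(I_R^R − I_R^B)/(Imax^R − Imax^B)|` with `I_R^λ = ln(Imax/Imin)`, and
   the heart-rate scalar — 7 × 5 × 50 × 35 + 1 = 61 251 values;
4. classifies five states (amusement, disgust, fear, sexual arousal,
   neutral) with a class-weighted one-vs-one gradient-boosted model under
   leave-one-subject-out cross-validation, undersampling each held-out
   subject's trials to the smallest class;
5. maps where, when and at which wavelength the discriminative information
   lives: spatial importance maps per feature and per class pair, per-pulse-
   frame profiles, facial-ROI statistics and gender-split analyses.

Raw multispectral emotion datasets are not generally available, so the
package ships a physics-grounded simulator (Beer–Lambert reflectance,
thermal drift, class-specific spatial modulation templates, sensor noise,
8-bit quantization) that generates cohorts with known ground truth; all
end-to-end claims are validated against it.

## Worked example

```python
from tstms import (OpticsModel, SubjectProfile, build_cube, compute_features,
                   default_class_templates, estimate_heart_rate,
                   flatten_features, render_recording)

profile = SubjectProfile(
    subject_id="demo", gender="M", heart_rate_hz=1.42,
    skin_base_intensity={"R": 140, "G": 160, "B": 130, "NIR": 150},
    base_temp_c=34.0, phase_map_seed=2)
rec = render_recording(profile, default_class_templates()["N"],
                       OpticsModel(), seed=3)
cube = build_cube(rec)                      # (5, 120, 50, 35)
f8, fmap = estimate_heart_rate(cube.channel("G"), cube.fs)
print(f"true {profile.heart_rate_hz:.3f} Hz, estimated {f8:.3f} Hz,"
      f" masked pixels {int(fmap.mask.sum())}")
vec = flatten_features(compute_features(cube, hr=f8))
print(f"feature vector length {vec.size}")
```

prints

```
true 1.420 Hz, estimated 1.500 Hz, masked pixels 1142
feature vector length 61251
```

The estimate lands on the FFT bin nearest the true rate (resolution
fs/T = 0.25 Hz for a 4-s clip), and the mask covers the elliptical skin
region. The `examples/` directory has one short script per capability:
simulation, heart-rate estimation, feature extraction, cohort
classification, importance mapping. A thin CLI wraps the same calls
(`tstms simulate`, `tstms estimate-hr`, `tstms run --config cfg.yaml`).

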