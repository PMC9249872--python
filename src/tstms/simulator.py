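"""Synthetic multispectral face-video simulator with known ground truth.

The forward model is Beer–Lambert skin optics: light reflected diffusely from
the skin is attenuated exponentially along the optical path through the
absorbing tissue, and the cardiac cycle modulates that path length as arterial
volume rises and falls.  For every reflectance channel (R, G, B, NIR) a face
pixel renders as

    I(x, y, t) = R_s + A * exp(-alpha_lambda * z(x, y, t)) + noise,
    z(x, y, t) = z0 + dz(x, y) * (1 + sin(2 pi f t + phi(x, y))) / 2,

with ``R_s`` a constant specular term, ``A`` the subject's baseline skin
reflectance for the channel, ``alpha_lambda`` the channel's absorption
coefficient (hemoglobin absorbs most strongly in blue and green, weakly in
red), ``z0`` the baseline path depth, ``dz`` a per-pixel pulsatile
path-length amplitude, ``f`` the heart rate in Hz and ``phi`` a smooth
low-amplitude spatial phase field standing in for pulse-transit-time
variation across the face.  The LWIR channel carries no pulse: face pixels
are degrees Celsius with a slow per-pixel linear drift, on a cool (< 30 °C)
background.

Emotion classes differ through :class:`ClassTemplate`: a spatial map of extra
path-length modulation (``dz_map``), a thermal drift map, and an additive
heart-rate offset.  Templates place their modulation in different facial
regions, so classes are separable and the discriminative region is known
exactly — which is what lets downstream classification and importance
mapping be validated against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from tstms.recording import (
    CLASS_LABELS,
    GRID_SHAPE,
    Recording,
    VIS_NIR_CHANNELS,
)

#: heart-rate analysis band (Hz); rendered rates must lie strictly inside it
HR_BAND = (0.75, 4.0)

#: default face-crop sizes (rows, cols) per channel; integer multiples of the
#: 50x35 analysis grid so block pooling maps crops back onto it cleanly
DEFAULT_NATIVE_RESOLUTIONS = {
    "R": (500, 350),
    "G": (500, 350),
    "B": (500, 350),
    "NIR": (250, 175),
    "LWIR": (250, 175),
}


def face_mask(shape: tuple[int, int] = GRID_SHAPE) -> np.ndarray:
    """Elliptical skin region on the analysis grid (True = face).

    The ellipse nearly fills the grid; its bottom rows play the role of the
    chin, so chin-mask handling is exercisable on synthetic data.
    """
    rows, cols = shape
    r = (np.arange(rows) - (rows - 1) / 2) / (rows / 2 - 1.5)
    c = (np.arange(cols) - (cols - 1) / 2) / (cols / 2 - 1.5)
    return (r[:, None] ** 2 + c[None, :] ** 2) <= 1.0


@dataclass
class SubjectProfile:
    """Per-subject physiology and appearance, shared across the subject's trials."""

    subject_id: str
    gender: str
    heart_rate_hz: float
    skin_base_intensity: dict[str, float]
    base_temp_c: float
    phase_map_seed: int

    def __post_init__(self) -> None:
        lo, hi = HR_BAND
        if not (lo < self.heart_rate_hz < hi):
            raise ValueError(
                f"heart rate {self.heart_rate_hz} Hz outside the analysis band {HR_BAND}"
            )
        if self.base_temp_c <= 30.0:
            raise ValueError("base_temp_c must exceed 30 °C for LWIR face segmentation")


@dataclass
class ClassTemplate:
    """Class-specific spatiotemporal modulation on the 50x35 grid."""

    class_label: str
    dz_map: np.ndarray
    temp_drift_map: np.ndarray
    hr_offset_hz: float = 0.0

    def __post_init__(self) -> None:
        mask = face_mask()
        self.dz_map = np.asarray(self.dz_map, dtype=float)
        self.temp_drift_map = np.asarray(self.temp_drift_map, dtype=float)
        if self.dz_map.shape != GRID_SHAPE:
            raise ValueError(f"dz_map must be {GRID_SHAPE}")
        if np.any(self.dz_map < 0):
            raise ValueError("dz_map must be nonnegative")
        if np.any(self.dz_map[~mask] != 0):
            raise ValueError("dz_map must be zero outside the face mask")


@dataclass
class OpticsModel:
    """Beer–Lambert rendering constants shared by all subjects.

    ``alpha`` are per-channel absorption coefficients (per depth unit); the
    hemoglobin ordering alpha_B >= alpha_G > alpha_R is enforced.  ``noise_sd``
    is per-channel sensor noise (gray levels for reflectance channels, °C for
    LWIR).  With ``quantize`` on, reflectance channels are rounded to 8-bit.
    """

    alpha: dict[str, float] = field(
        default_factory=lambda: {"R": 0.25, "G": 0.80, "B": 0.90, "NIR": 0.40}
    )
    z0: float = 1.0
    specular_Rs: float = 10.0
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"R": 1.0, "G": 1.0, "B": 1.0, "NIR": 1.0, "LWIR": 0.05}
    )
    quantize: bool = True

    def __post_init__(self) -> None:
        a = self.alpha
        if not (a["B"] >= a["G"] > a["R"]):
            raise ValueError("absorption must satisfy alpha_B >= alpha_G > alpha_R")


def phase_field(seed: int, amplitude: float = 0.3,
                shape: tuple[int, int] = GRID_SHAPE) -> np.ndarray:
    """Smooth spatial phase offsets (radians) with |phi| <= amplitude."""
    if amplitude == 0:
        return np.zeros(shape)
    rng = np.random.default_rng(seed)
    raw = gaussian_filter(rng.standard_normal(shape), sigma=6.0)
    peak = np.max(np.abs(raw))
    return raw / peak * amplitude if peak > 0 else raw


def _region_bump(center: tuple[float, float], half: tuple[float, float]) -> np.ndarray:
    """Smooth rectangular bump (max 1) on the grid, clipped to the face."""
    rows, cols = GRID_SHAPE
    bump = np.zeros(GRID_SHAPE)
    r0 = max(int(center[0] - half[0]), 0)
    r1 = min(int(center[0] + half[0]) + 1, rows)
    c0 = max(int(center[1] - half[1]), 0)
    c1 = min(int(center[1] + half[1]) + 1, cols)
    bump[r0:r1, c0:c1] = 1.0
    bump = gaussian_filter(bump, sigma=1.5)
    bump /= bump.max()
    bump[~face_mask()] = 0.0
    return bump


#: anatomical anchor regions (row, col centers and half-sizes) for templates
TEMPLATE_REGIONS = {
    "forehead": ((8.0, 17.0), (5.0, 10.0)),
    "left_cheek": ((28.0, 8.0), (6.0, 4.0)),
    "right_cheek": ((28.0, 26.0), (6.0, 4.0)),
    "mouth": ((40.0, 17.0), (4.0, 7.0)),
    "nose": ((26.0, 17.0), (5.0, 3.0)),
}


def default_class_templates(
    contrast: float = 0.25,
    base_dz: float = 0.12,
    drift_c_per_s: float = 0.04,
    hr_offsets: dict[str, float] | None = None,
) -> dict[str, ClassTemplate]:
    """Five emotion-class templates with disjoint discriminative regions.

    Every class shares a uniform base pulsatile amplitude over the face
    (``base_dz``); each non-neutral class adds ``contrast`` worth of extra
    modulation in its own region — amusement in the cheeks, disgust around
    the mouth/nose, fear on the forehead, sexual arousal across cheeks plus
    forehead with a thermal drift.  Neutral adds nothing, so it has the
    smallest total modulation energy.  ``contrast=0`` yields five identical
    templates (a negative control: nothing is learnable).
    """
    if hr_offsets is None:
        hr_offsets = {"A": 0.0, "D": 0.0, "F": 0.25, "S": 0.15, "N": 0.0}
    mask = face_mask().astype(float)
    cheeks = _region_bump(*TEMPLATE_REGIONS["left_cheek"]) + _region_bump(
        *TEMPLATE_REGIONS["right_cheek"]
    )
    forehead = _region_bump(*TEMPLATE_REGIONS["forehead"])
    mouth = _region_bump(*TEMPLATE_REGIONS["mouth"]) + _region_bump(
        *TEMPLATE_REGIONS["nose"]
    )
    zeros = np.zeros(GRID_SHAPE)
    extra = {
        "A": cheeks,
        "D": mouth,
        "F": forehead,
        "S": 0.5 * cheeks + 0.5 * forehead,
        "N": zeros,
    }
    drift = {
        "A": zeros,
        "D": drift_c_per_s * mouth,
        "F": drift_c_per_s * forehead,
        "S": drift_c_per_s * mask,
        "N": zeros,
    }
    return {
        label: ClassTemplate(
            class_label=label,
            dz_map=(base_dz * mask + contrast * extra[label]),
            temp_drift_map=drift[label],
            hr_offset_hz=hr_offsets.get(label, 0.0),
        )
        for label in CLASS_LABELS
    }


def _upsample(frames: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour upsample of (T, 50, 35) frames by integer factors."""
    rows, cols = GRID_SHAPE
    h, w = out_hw
    if h % rows or w % cols:
        raise ValueError(
            f"native face-crop size {out_hw} must be an integer multiple of {GRID_SHAPE}"
        )
    kr, kc = h // rows, w // cols
    return np.repeat(np.repeat(frames, kr, axis=1), kc, axis=2)


def render_recording(
    profile: SubjectProfile,
    template: ClassTemplate,
    optics: OpticsModel | None = None,
    duration_s: float = 4.0,
    fs: float = 30.0,
    native_resolutions: dict[str, tuple[int, int]] | None = None,
    seed: int = 0,
    phase_amplitude: float = 0.3,
    margin: int = 8,
    background_vis: float = 25.0,
    background_temp_c: float = 22.0,
) -> Recording:
    """Render one trial's five channel stacks from the forward model.

    Pixel signals are computed on the 50x35 grid and upsampled to each
    channel's native face-crop resolution (which must be an integer multiple
    of the grid, at least 4x); the crop is embedded in a frame with a
    ``margin``-pixel background border, and the crop box is recorded as the
    ground-truth face bbox.  Deterministic for a fixed ``seed``.
    """
    optics = optics or OpticsModel()
    native = dict(DEFAULT_NATIVE_RESOLUTIONS, **(native_resolutions or {}))
    n_frames = int(round(duration_s * fs))
    if n_frames < 120:
        raise ValueError("duration_s * fs must be at least 120 frames")
    for ch, (h, w) in native.items():
        if h < 4 * GRID_SHAPE[0] or w < 4 * GRID_SHAPE[1]:
            raise ValueError(f"native resolution for {ch} must be >= 4x the analysis grid")

    f_hz = profile.heart_rate_hz + template.hr_offset_hz
    lo, hi = HR_BAND
    if not (lo < f_hz < hi):
        raise ValueError(
            f"effective heart rate {f_hz:.3f} Hz outside the open band {HR_BAND}; "
            "the signal would be removed by the band-pass stage"
        )

    mask = face_mask()
    phi = phase_field(profile.phase_map_seed, phase_amplitude)
    t = np.arange(n_frames) / fs
    # (T, 50, 35) normalized pulsation in [0, 1]
    pulsation = (1.0 + np.sin(2 * np.pi * f_hz * t[:, None, None] + phi[None])) / 2.0
    z = optics.z0 + template.dz_map[None] * pulsation

    rng = np.random.default_rng(seed)
    channels: dict[str, np.ndarray] = {}
    bboxes: dict[str, tuple[int, int, int, int]] = {}
    # float32 keeps cohort-scale memory bounded; the unquantized oracle mode
    # renders in float64 so closed-form feature checks are exact
    dtype = np.float32 if optics.quantize else np.float64
    for ch in VIS_NIR_CHANNELS:
        amp = profile.skin_base_intensity[ch]
        face_sig = optics.specular_Rs + amp * np.exp(-optics.alpha[ch] * z)
        grid = np.where(mask[None], face_sig, background_vis)
        crop = _upsample(grid.astype(dtype), native[ch])
        h, w = native[ch]
        frame = np.full(
            (n_frames, h + 2 * margin, w + 2 * margin), background_vis, dtype=dtype
        )
        frame[:, margin : margin + h, margin : margin + w] = crop
        sd = optics.noise_sd.get(ch, 0.0)
        if sd > 0:
            frame += sd * rng.standard_normal(frame.shape, dtype=np.float32).astype(dtype)
        if optics.quantize:
            frame = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
        channels[ch] = frame
        bboxes[ch] = (margin, margin, margin + h, margin + w)

    # LWIR: slow linear thermal drift on the face, cool static background
    temp = profile.base_temp_c + template.temp_drift_map[None] * t[:, None, None]
    grid = np.where(mask[None], temp, background_temp_c)
    h, w = native["LWIR"]
    crop = _upsample(grid.astype(np.float32), (h, w))
    frame = np.full(
        (n_frames, h + 2 * margin, w + 2 * margin), background_temp_c, dtype=np.float32
    )
    frame[:, margin : margin + h, margin : margin + w] = crop
    sd = optics.noise_sd.get("LWIR", 0.0)
    if sd > 0:
        frame += sd * rng.standard_normal(frame.shape, dtype=np.float32)
    channels["LWIR"] = frame
    bboxes["LWIR"] = (margin, margin, margin + h, margin + w)

    return Recording(
        subject_id=profile.subject_id,
        class_label=template.class_label,
        gender=profile.gender,
        channels=channels,
        fs=fs,
        face_bboxes=bboxes,
        meta={"true_heart_rate_hz": f_hz, "seed": seed},
    )


@dataclass
class Cohort:
    """A simulated study: per-trial manifest plus lazily rendered recordings.

    Recordings are rendered on demand (:meth:`iter_recordings`) so large
    cohorts never hold all native-resolution video in memory at once.
    """

    manifest: pd.DataFrame
    profiles: dict[str, SubjectProfile]
    templates: dict[str, ClassTemplate]
    optics: OpticsModel
    render_kwargs: dict

    def __len__(self) -> int:
        return len(self.manifest)

    def render_trial(self, row) -> Recording:
        return render_recording(
            self.profiles[row.subject_id],
            self.templates[row.class_label],
            self.optics,
            seed=int(row.trial_seed),
            **self.render_kwargs,
        )

    def iter_recordings(self) -> Iterator[Recording]:
        for row in self.manifest.itertuples(index=False):
            yield self.render_trial(row)

    def recordings(self) -> list[Recording]:
        return list(self.iter_recordings())


def make_cohort(
    n_subjects: int,
    classes: Iterable[str] = CLASS_LABELS,
    trials_per_class: int | dict[str, int] = 1,
    seed: int = 0,
    templates: dict[str, ClassTemplate] | None = None,
    optics: OpticsModel | None = None,
    hr_range_hz: tuple[float, float] = (0.9, 1.9),
    **render_kwargs,
) -> Cohort:
    """Draw a cohort of subjects and lay out their per-class trials.

    Subject-level parameters (heart rate, skin reflectance per channel, base
    temperature, gender, phase-field seed) are drawn once per subject and
    shared across that subject's trials; each trial gets its own noise seed.
    Reproducible: the same ``seed`` yields an identical manifest and
    identical recordings.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    classes = list(classes)
    if isinstance(trials_per_class, int):
        trials_per_class = {c: trials_per_class for c in classes}
    if all(trials_per_class.get(c, 0) == 0 for c in classes):
        raise ValueError("at least one class must have trials_per_class > 0")

    templates = templates or default_class_templates()
    optics = optics or OpticsModel()
    rng = np.random.default_rng(seed)

    profiles: dict[str, SubjectProfile] = {}
    rows = []
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        hr = float(rng.uniform(*hr_range_hz))
        base = {ch: float(rng.uniform(110.0, 190.0)) for ch in VIS_NIR_CHANNELS}
        profiles[sid] = SubjectProfile(
            subject_id=sid,
            gender="F" if i % 2 == 0 else "M",
            heart_rate_hz=hr,
            skin_base_intensity=base,
            base_temp_c=float(rng.uniform(33.0, 36.0)),
            phase_map_seed=int(rng.integers(2**31)),
        )
        for label in classes:
            for k in range(trials_per_class.get(label, 0)):
                rows.append(
                    {
                        "trial_id": f"{sid}_{label}_{k:02d}",
                        "subject_id": sid,
                        "class_label": label,
                        "gender": profiles[sid].gender,
                        "heart_rate_hz": hr + templates[label].hr_offset_hz,
                        "trial_seed": int(rng.integers(2**31)),
                    }
                )
    manifest = pd.DataFrame(rows)
    return Cohort(manifest, profiles, templates, optics, render_kwargs)


def write_cohort_manifest(cohort: Cohort, path) -> None:
    cohort.manifest.to_csv(path, index=False)
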