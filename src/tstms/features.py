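"""The eight TSTMS features and their flattened classifier representation.

F1  TMP^LWIR   slow skin-temperature track (°C), 5 samples per pixel
F2  I_AC^R     red pulsatile amplitude Imax - Imin
F3  I_AC^G     green pulsatile amplitude
F4  I_AC^B     blue pulsatile amplitude
F5  I_R,AC^{B,R}    blue/red pulsatile-amplitude ratio
F6  I_R,ACDC^{R,B}  |(I_R^R - I_R^B) / (Imax^R - Imax^B)|, a baseline-adjusted
                    cross-wavelength absorption difference, with
                    I_R^λ = ln(Imax^λ / Imin^λ)
F7  I_AC^NIR   near-infrared pulsatile amplitude
F8  HR^G       estimated heart rate from the green channel (scalar, Hz)

F1–F7 live on a (pulse frame, row, col) = (5, 50, 35) lattice — 8750 values
each; with the single F8 scalar the flattened vector has 61,251 entries.
Zero is the universal "no signal" code: padded pulse frames, zero-guarded
divisions and logarithms, and chin-masked pixels all contribute exact zeros.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from tstms.heart_rate import estimate_heart_rate
from tstms.preprocess import DownsampledCube
from tstms.pulse_events import N_PULSE_FRAMES, build_pulse_stack, lwir_track
from tstms.recording import GRID_SHAPE

SPATIOTEMPORAL_FEATURES = ("F1", "F2", "F3", "F4", "F5", "F6", "F7")
FEATURE_NAMES = SPATIOTEMPORAL_FEATURES + ("F8",)

#: 5 pulse frames x 50 rows x 35 cols
VALUES_PER_FEATURE = N_PULSE_FRAMES * GRID_SHAPE[0] * GRID_SHAPE[1]
#: 7 spatiotemporal features + the scalar heart rate
FEATURE_VECTOR_LENGTH = len(SPATIOTEMPORAL_FEATURES) * VALUES_PER_FEATURE + 1

_ST_SHAPE = (N_PULSE_FRAMES, *GRID_SHAPE)


@dataclass
class TSTMSFeatures:
    """One trial's complete feature set (chin mask already applied or not)."""

    f1: np.ndarray
    f2: np.ndarray
    f3: np.ndarray
    f4: np.ndarray
    f5: np.ndarray
    f6: np.ndarray
    f7: np.ndarray
    f8: float
    chin_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in SPATIOTEMPORAL_FEATURES:
            arr = getattr(self, name.lower())
            if arr.shape != _ST_SHAPE:
                raise ValueError(f"{name} must have shape {_ST_SHAPE}, got {arr.shape}")

    def spatiotemporal(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name.lower()) for name in SPATIOTEMPORAL_FEATURES}


def pulsatile_amplitude(imax: np.ndarray, imin: np.ndarray) -> np.ndarray:
    """I_AC = Imax - Imin; padded (both-zero) entries stay 0."""
    return np.asarray(imax, dtype=float) - np.asarray(imin, dtype=float)


def absorption_ratio(imax: np.ndarray, imin: np.ndarray) -> np.ndarray:
    """I_R = ln(Imax / Imin), an absorption measure independent of baseline
    tissue reflectance; padded or non-positive entries yield 0."""
    imax = np.asarray(imax, dtype=float)
    imin = np.asarray(imin, dtype=float)
    out = np.zeros_like(imax)
    valid = (imin > 0) & (imax > 0)
    out[valid] = np.log(imax[valid] / imin[valid])
    return out


def amplitude_dissimilarity(i_ac_num: np.ndarray, i_ac_den: np.ndarray) -> np.ndarray:
    """Cross-wavelength pulsatile-amplitude ratio; zero denominator → 0.

    The default feature F5 uses blue over red: ``amplitude_dissimilarity(
    I_AC^B, I_AC^R)``.
    """
    num = np.asarray(i_ac_num, dtype=float)
    den = np.asarray(i_ac_den, dtype=float)
    out = np.zeros_like(num)
    valid = den != 0
    out[valid] = num[valid] / den[valid]
    return out


def absorption_difference(
    i_r_1: np.ndarray, i_r_2: np.ndarray, imax_1: np.ndarray, imax_2: np.ndarray
) -> np.ndarray:
    """|(I_R^λ1 - I_R^λ2) / (Imax^λ1 - Imax^λ2)|; zero denominator → 0.

    The default feature F6 uses λ1 = R, λ2 = B.
    """
    num = np.asarray(i_r_1, dtype=float) - np.asarray(i_r_2, dtype=float)
    den = np.asarray(imax_1, dtype=float) - np.asarray(imax_2, dtype=float)
    out = np.zeros_like(num)
    valid = den != 0
    out[valid] = np.abs(num[valid] / den[valid])
    return out


def default_chin_mask(n_rows: int = 6) -> np.ndarray:
    """Bottom ``n_rows`` rows of the grid (the chin-mount region)."""
    mask = np.zeros(GRID_SHAPE, dtype=bool)
    if n_rows > 0:
        mask[-n_rows:, :] = True
    return mask


def apply_chin_mask(features: TSTMSFeatures, mask: np.ndarray) -> TSTMSFeatures:
    """Zero F1–F7 on masked pixels (the chin head-mount is not skin signal).

    The vector length is unchanged — masked pixels carry zeros, preserving
    the fixed 8750-per-feature dimensionality.  A mask covering more than
    30% of the grid is rejected as implausible.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != GRID_SHAPE:
        raise ValueError(f"chin mask must be {GRID_SHAPE}")
    if mask.mean() > 0.30:
        raise ValueError("chin mask covers more than 30% of the grid")
    keep = ~mask
    updated = {
        name.lower(): getattr(features, name.lower()) * keep[None]
        for name in SPATIOTEMPORAL_FEATURES
    }
    return replace(features, **updated, chin_mask=mask)


def compute_features(
    cube: DownsampledCube,
    hr: float | None = None,
    chin_mask: np.ndarray | None = None,
    prominence: dict[str, float] | None = None,
    band: tuple[float, float] = (0.75, 4.0),
    order: int = 6,
    n_pulse_frames: int = N_PULSE_FRAMES,
) -> TSTMSFeatures:
    """Assemble all eight features for one preprocessed trial.

    If ``hr`` is not supplied it is estimated from the green channel first
    (it parameterizes the peak-detection temporal threshold).  ``chin_mask``
    defaults to the bottom six rows.
    """
    if hr is None:
        hr, _ = estimate_heart_rate(cube.channel("G"), cube.fs, order=order,
                                    lo=band[0], hi=band[1])
    stack = build_pulse_stack(cube, hr, n_pulse_frames=n_pulse_frames,
                              prominence=prominence, band=band, order=order)
    f1 = lwir_track(cube.channel("LWIR"), cube.fs, n_samples=n_pulse_frames,
                    order=order)
    f2 = pulsatile_amplitude(stack.imax["R"], stack.imin["R"])
    f3 = pulsatile_amplitude(stack.imax["G"], stack.imin["G"])
    f4 = pulsatile_amplitude(stack.imax["B"], stack.imin["B"])
    f7 = pulsatile_amplitude(stack.imax["NIR"], stack.imin["NIR"])
    f5 = amplitude_dissimilarity(f4, f2)
    i_r_r = absorption_ratio(stack.imax["R"], stack.imin["R"])
    i_r_b = absorption_ratio(stack.imax["B"], stack.imin["B"])
    f6 = absorption_difference(i_r_r, i_r_b, stack.imax["R"], stack.imax["B"])
    feats = TSTMSFeatures(f1=f1, f2=f2, f3=f3, f4=f4, f5=f5, f6=f6, f7=f7,
                          f8=float(hr))
    mask = default_chin_mask() if chin_mask is None else chin_mask
    return apply_chin_mask(feats, mask)


def flatten_features(features: TSTMSFeatures) -> np.ndarray:
    """Deterministic 61,251-vector: F1..F7 in (pulse, row, col) raster order,
    then F8 last."""
    parts = [getattr(features, n.lower()).ravel() for n in SPATIOTEMPORAL_FEATURES]
    parts.append(np.array([features.f8]))
    vec = np.concatenate(parts)
    assert vec.size == FEATURE_VECTOR_LENGTH
    return vec


def unflatten_features(vec: np.ndarray) -> TSTMSFeatures:
    """Inverse of :func:`flatten_features`."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != FEATURE_VECTOR_LENGTH:
        raise ValueError(f"expected length {FEATURE_VECTOR_LENGTH}, got {vec.size}")
    arrs = {}
    for i, name in enumerate(SPATIOTEMPORAL_FEATURES):
        block = vec[i * VALUES_PER_FEATURE : (i + 1) * VALUES_PER_FEATURE]
        arrs[name.lower()] = block.reshape(_ST_SHAPE).copy()
    return TSTMSFeatures(**arrs, f8=float(vec[-1]))


def index_of(feature: str, pulse: int = 0, row: int = 0, col: int = 0) -> int:
    """Flat index of one (feature, pulse, row, col) parameter; F8 is last."""
    if feature == "F8":
        return FEATURE_VECTOR_LENGTH - 1
    fi = SPATIOTEMPORAL_FEATURES.index(feature)
    return fi * VALUES_PER_FEATURE + np.ravel_multi_index(
        (pulse, row, col), _ST_SHAPE
    )


def index_map() -> list[tuple[str, int, int, int]]:
    """Invertible flat-index → (feature, pulse, row, col) table; F8 maps to
    ``("F8", -1, -1, -1)``."""
    entries = []
    for name in SPATIOTEMPORAL_FEATURES:
        for p in range(N_PULSE_FRAMES):
            for r in range(GRID_SHAPE[0]):
                for c in range(GRID_SHAPE[1]):
                    entries.append((name, p, r, c))
    entries.append(("F8", -1, -1, -1))
    return entries


def save_index_map(path) -> None:
    with open(path, "w") as f:
        json.dump([list(e) for e in index_map()], f)
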