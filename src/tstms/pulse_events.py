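"""Per-pixel pulse peak/trough detection and aligned pulse-frame stacks.

For each reflectance channel, every pixel's band-passed series is min-max
normalized and scanned for peaks with two constraints: a minimum temporal
separation of ceil(3/4 * fs / hr) frames (no two beats can be closer than
three quarters of a cardiac period) and a minimum prominence — 0.4 for the
cleaner green and NIR channels, 0.2 for the noisier red and blue.  Troughs
are peaks of the negated signal under the same thresholds.  Intensities at
those events (read from the band-passed series with the pixel's temporal
mean restored, so ratios and logarithms stay well defined) populate per-pulse
Imax/Imin images; pixels with fewer events than the stack depth are
zero-padded.  The LWIR channel instead yields a slow temperature track:
low-passed at 0.75 Hz and resampled at 1.5 Hz, its first five samples form
feature F1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from tstms.heart_rate import bandpass
from tstms.preprocess import DownsampledCube
from tstms.recording import GRID_SHAPE, VIS_NIR_CHANNELS

#: per-channel minimum peak prominence on the min-max-normalized signal
DEFAULT_PROMINENCE = {"G": 0.4, "NIR": 0.4, "R": 0.2, "B": 0.2}

N_PULSE_FRAMES = 5


def min_peak_separation(fs: float, hr: float) -> int:
    """Minimum frames between detected peaks: ceil(3/4 * fs / hr)."""
    if hr <= 0:
        raise ValueError("heart rate must be positive")
    return int(math.ceil(0.75 * fs / hr))


def find_peaks_troughs(
    signal: np.ndarray,
    fs: float,
    hr: float,
    prominence: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Detect pulse peaks and troughs on one band-passed pixel series.

    Detection runs on the min-max-normalized signal (prominence thresholds
    are defined on the [0, 1] scale); reported values are read from the
    *input* signal at the detected times, preserving amplitude information.
    Returns ``(peak_times, peak_values, trough_times, trough_values)``.
    """
    signal = np.asarray(signal, dtype=float)
    dist = min_peak_separation(fs, hr)
    rng_ = signal.max() - signal.min()
    # numerically flat series (e.g. filter residue of a constant pixel) must
    # not be min-max amplified into spurious full-scale events
    if rng_ <= 1e-9 * max(1.0, abs(signal.max()), abs(signal.min())):
        empty = np.array([], dtype=int)
        return empty, np.array([]), empty.copy(), np.array([])
    norm = (signal - signal.min()) / rng_
    pk, _ = find_peaks(norm, distance=dist, prominence=prominence)
    tr, _ = find_peaks(1.0 - norm, distance=dist, prominence=prominence)
    return pk, signal[pk], tr, signal[tr]


@dataclass
class PulseEvents:
    """Zero-padded per-pixel event arrays for one channel.

    ``peak_times``/``trough_times`` are ``(50, 35, L)`` integer frame indices
    and the matching values are intensities, where ``L`` is the maximum event
    count found in the trial; shorter pixels are padded with exact zeros.
    Within a pixel the non-padded times strictly increase.
    """

    peak_times: np.ndarray
    peak_values: np.ndarray
    trough_times: np.ndarray
    trough_values: np.ndarray
    n_peaks: np.ndarray = field(default=None)
    n_troughs: np.ndarray = field(default=None)


def _restore_dc(channel_cube: np.ndarray, fs: float, band: tuple[float, float],
                order: int) -> np.ndarray:
    """Band-passed series with each pixel's temporal mean added back."""
    bp = bandpass(channel_cube, fs, lo=band[0], hi=band[1], order=order, axis=0)
    return bp + channel_cube.mean(axis=0, keepdims=True)


def extract_events(
    cube: DownsampledCube,
    hr: float,
    prominence: dict[str, float] | None = None,
    band: tuple[float, float] = (0.75, 4.0),
    order: int = 6,
) -> dict[str, PulseEvents]:
    """Per-channel, per-pixel pulse events from a downsampled cube."""
    prominence = prominence or DEFAULT_PROMINENCE
    out: dict[str, PulseEvents] = {}
    for ch in VIS_NIR_CHANNELS:
        series = _restore_dc(cube.channel(ch), cube.fs, band, order)
        rows, cols = GRID_SHAPE
        all_pk, all_tr = {}, {}
        max_pk = max_tr = 0
        for r in range(rows):
            for c in range(cols):
                pk, pv, tr, tv = find_peaks_troughs(
                    series[:, r, c], cube.fs, hr, prominence[ch]
                )
                all_pk[(r, c)] = (pk, pv)
                all_tr[(r, c)] = (tr, tv)
                max_pk = max(max_pk, pk.size)
                max_tr = max(max_tr, tr.size)
        pk_t = np.zeros((rows, cols, max_pk), dtype=int)
        pk_v = np.zeros((rows, cols, max_pk))
        tr_t = np.zeros((rows, cols, max_tr), dtype=int)
        tr_v = np.zeros((rows, cols, max_tr))
        n_pk = np.zeros((rows, cols), dtype=int)
        n_tr = np.zeros((rows, cols), dtype=int)
        for (r, c), (pk, pv) in all_pk.items():
            pk_t[r, c, : pk.size], pk_v[r, c, : pk.size] = pk, pv
            n_pk[r, c] = pk.size
        for (r, c), (tr, tv) in all_tr.items():
            tr_t[r, c, : tr.size], tr_v[r, c, : tr.size] = tr, tv
            n_tr[r, c] = tr.size
        out[ch] = PulseEvents(pk_t, pk_v, tr_t, tr_v, n_pk, n_tr)
    return out


@dataclass
class PulseFrameStack:
    """Aligned peak/trough images per channel: Imax, Imin of shape (5, 50, 35)."""

    imax: dict[str, np.ndarray]
    imin: dict[str, np.ndarray]


def pair_peaks_with_troughs(
    peak_times: np.ndarray, trough_times: np.ndarray
) -> list[tuple[int, int]]:
    """Ordinal pairing: each peak takes the nearest *following* trough.

    Peaks and troughs alternate on a clean pulsatile signal; pairing a peak
    with the trough that follows it captures one cardiac cycle.  A trailing
    peak with no following trough is dropped.
    """
    pairs = []
    j = 0
    for pt in peak_times:
        while j < len(trough_times) and trough_times[j] <= pt:
            j += 1
        if j == len(trough_times):
            break
        pairs.append((int(pt), int(trough_times[j])))
        j += 1
    return pairs


def build_pulse_stack(
    cube: DownsampledCube,
    hr: float,
    n_pulse_frames: int = N_PULSE_FRAMES,
    prominence: dict[str, float] | None = None,
    band: tuple[float, float] = (0.75, 4.0),
    order: int = 6,
) -> PulseFrameStack:
    """Build the per-channel (pulse, row, col) Imax/Imin stacks.

    The first ``n_pulse_frames`` peak→trough pairs of each pixel fill pulse
    indices 0..4; missing pairs stay zero-padded (an all-padded pixel is
    legal and contributes zero features downstream).
    """
    if hr <= 0:
        raise ValueError("heart rate must be positive")
    prominence = prominence or DEFAULT_PROMINENCE
    rows, cols = GRID_SHAPE
    imax: dict[str, np.ndarray] = {}
    imin: dict[str, np.ndarray] = {}
    for ch in VIS_NIR_CHANNELS:
        series = _restore_dc(cube.channel(ch), cube.fs, band, order)
        mx = np.zeros((n_pulse_frames, rows, cols))
        mn = np.zeros((n_pulse_frames, rows, cols))
        for r in range(rows):
            for c in range(cols):
                s = series[:, r, c]
                pk, pv, tr, tv = find_peaks_troughs(s, cube.fs, hr, prominence[ch])
                for p, (ipk, itr) in enumerate(
                    pair_peaks_with_troughs(pk, tr)[:n_pulse_frames]
                ):
                    mx[p, r, c] = s[ipk]
                    mn[p, r, c] = s[itr]
        imax[ch], imin[ch] = mx, mn
    return PulseFrameStack(imax=imax, imin=imin)


def lwir_track(
    lwir_cube: np.ndarray,
    fs: float,
    cutoff_hz: float = 0.75,
    resample_hz: float = 1.5,
    n_samples: int = N_PULSE_FRAMES,
    order: int = 6,
) -> np.ndarray:
    """Slow temperature track (feature F1): low-pass, resample, keep 5 samples.

    Each pixel's series is low-pass filtered at ``cutoff_hz`` (zero-phase
    6th-order Butterworth) and sampled every ``fs / resample_hz`` frames;
    the first ``n_samples`` samples form the (5, 50, 35) track.
    """
    lwir_cube = np.asarray(lwir_cube, dtype=float)
    sos = butter(order, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    low = sosfiltfilt(sos, lwir_cube, axis=0)
    step = int(round(fs / resample_hz))
    idx = np.arange(n_samples) * step
    if idx[-1] >= lwir_cube.shape[0]:
        raise ValueError("cube too short for the requested temperature samples")
    return low[idx]
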