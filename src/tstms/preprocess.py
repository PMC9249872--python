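"""Temporal slicing, face localization and two-stage spatial downsampling.

Each trial is cut to its initial 120 frames (4 s at 30 fps), the face is
localized per channel — reflectance channels by a pluggable detector or an
explicit box, the thermal channel by Otsu thresholding plus a hard 30 °C
floor — and every channel is reduced to a common 50x35 grid by
non-overlapping block-mean pooling (10x10 for R/G/B, 5x5 for NIR/LWIR)
followed by bicubic interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.ndimage import zoom as _ndizoom
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label, regionprops
from skimage.transform import resize as _sk_resize

from tstms.recording import CHANNELS, GRID_SHAPE, Recording

#: pooling blocks per channel (rows, cols) — VIS cameras have ~2x the
#: resolution of the NIR/LWIR cameras, hence the larger block
DEFAULT_POOL_BLOCKS = {
    "R": (10, 10),
    "G": (10, 10),
    "B": (10, 10),
    "NIR": (5, 5),
    "LWIR": (5, 5),
}

LWIR_FLOOR_C = 30.0


class TrialExcluded(Exception):
    """A trial fails a preprocessing admissibility rule and is dropped.

    Carries the human-readable reason so exclusions can be logged alongside
    the run, mirroring how short or faceless trials are discarded rather
    than treated as hard errors.
    """


@dataclass
class DownsampledCube:
    """All five channels on the common analysis grid: (5, T, 50, 35)."""

    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[0] != len(CHANNELS):
            raise ValueError(f"cube must be (5, T, 50, 35), got {self.data.shape}")
        if self.data.shape[2:] != GRID_SHAPE:
            raise ValueError(f"cube grid must be {GRID_SHAPE}, got {self.data.shape[2:]}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")

    def channel(self, name: str) -> np.ndarray:
        return self.data[CHANNELS.index(name)]


def slice_to_length(rec: Recording, n_frames: int = 120) -> Recording:
    """Keep each channel's initial ``n_frames`` frames (4 s at 30 fps).

    A channel shorter than ``n_frames`` excludes the whole trial — clips just
    below the target duration carry length-biased information and are
    dropped, not padded.
    """
    for ch, arr in rec.channels.items():
        if arr.shape[0] < n_frames:
            raise TrialExcluded(
                f"channel {ch} has {arr.shape[0]} frames < required {n_frames}"
            )
    return rec.with_channels({ch: arr[:n_frames] for ch, arr in rec.channels.items()})


def detect_face_bright_region(frame: np.ndarray) -> list[tuple[int, int, int, int]]:
    """Default automatic face detector: bright-blob candidates.

    Thresholds the frame with Otsu and returns the bounding boxes of the
    connected foreground components, ``(row0, col0, row1, col1)``.  Suitable
    for controlled recordings where the illuminated face dominates a darker
    background; any detector callable with the same signature can be swapped
    in.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.max() == frame.min():
        return []
    thr = threshold_otsu(frame)
    fg = frame > thr
    if not fg.any():
        return []
    labels = _cc_label(fg)
    return [tuple(int(v) for v in p.bbox) for p in regionprops(labels)]


def face_region_vis(
    frames: np.ndarray,
    bbox: tuple[int, int, int, int] | None = None,
    detector: Callable[[np.ndarray], list[tuple[int, int, int, int]]] | None = None,
) -> np.ndarray:
    """Crop the face from a reflectance stack.

    An explicit ``bbox`` bypasses detection entirely (the path synthetic
    pipelines take, where ground-truth boxes exist).  Otherwise the detector
    runs on the first frame and the largest candidate box is kept.
    """
    if frames.shape[0] == 0:
        raise ValueError("empty frame stack")
    if bbox is None:
        detector = detector or detect_face_bright_region
        candidates = detector(np.asarray(frames[0], dtype=float))
        if not candidates:
            raise TrialExcluded("no face found and no bbox supplied")
        bbox = max(candidates, key=lambda b: (b[2] - b[0]) * (b[3] - b[1]))
    r0, c0, r1, c1 = bbox
    return frames[:, r0:r1, c0:c1]


def face_region_lwir(frames: np.ndarray) -> np.ndarray:
    """Suppress the LWIR background: Otsu split, then a hard 30 °C floor.

    The face-vs-background temperature gap drives an Otsu binarization of
    the first frame; on top of that, every pixel below 30 °C is zeroed.
    Returns the masked stack (background exactly 0 °C).
    """
    first = np.asarray(frames[0], dtype=float)
    if first.max() > first.min():
        thr = threshold_otsu(first)
        fg = first > thr
    else:
        fg = np.zeros(first.shape, dtype=bool)
    fg &= first >= LWIR_FLOOR_C
    if not fg.any():
        raise TrialExcluded("no LWIR foreground above 30 °C")
    return np.where(fg[None], frames, 0.0)


def lwir_mask_bbox(masked: np.ndarray) -> tuple[int, int, int, int]:
    """Bounding box of the nonzero LWIR foreground in the first frame."""
    rows, cols = np.nonzero(masked[0])
    return int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1


def downsample_two_stage(
    frames: np.ndarray,
    pool_block: tuple[int, int],
    out_shape: tuple[int, int] = GRID_SHAPE,
) -> np.ndarray:
    """Block-mean pooling followed by bicubic resize to the analysis grid.

    Stage 1 averages non-overlapping ``pool_block`` windows (trailing rows or
    columns that do not fill a whole block are sliced off).  Stage 2 resizes
    the pooled frames to ``out_shape`` bicubically, frame by frame.
    """
    frames = np.asarray(frames, dtype=float)
    T, H, W = frames.shape
    bh, bw = pool_block
    if H < bh or W < bw:
        raise ValueError(f"frame {H}x{W} smaller than one {bh}x{bw} block")
    Hc, Wc = H - H % bh, W - W % bw
    pooled = (
        frames[:, :Hc, :Wc]
        .reshape(T, Hc // bh, bh, Wc // bw, bw)
        .mean(axis=(2, 4))
    )
    hp, wp = pooled.shape[1:]
    if (hp, wp) == tuple(out_shape):
        return pooled
    zr, zc = out_shape[0] / hp, out_shape[1] / wp
    if (round(hp * zr), round(wp * zc)) == tuple(out_shape):
        # exact zoom factors: one vectorized cubic-spline call over all frames
        out = _ndizoom(pooled, (1.0, zr, zc), order=3, mode="nearest",
                       grid_mode=True)
        assert out.shape[1:] == tuple(out_shape)
        return out
    out = np.empty((T, *out_shape), dtype=float)
    for i in range(T):
        out[i] = _sk_resize(
            pooled[i], out_shape, order=3, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    return out


def build_cube(
    rec: Recording,
    n_frames: int = 120,
    pool_blocks: dict[str, tuple[int, int]] | None = None,
    detector: Callable | None = None,
    use_ground_truth_bboxes: bool = True,
) -> DownsampledCube:
    """Full preprocessing of one trial: slice, localize, downsample, stack.

    Channel crops are registered only through the shared 50x35 resolution
    (each channel's face box maps onto the same grid); there is no subpixel
    alignment.  Raises :class:`TrialExcluded` for short or faceless trials.
    """
    pool_blocks = pool_blocks or DEFAULT_POOL_BLOCKS
    rec = slice_to_length(rec, n_frames)
    planes = []
    for ch in CHANNELS:
        frames = np.asarray(rec.channels[ch], dtype=float)
        if ch == "LWIR":
            masked = face_region_lwir(frames)
            bbox = lwir_mask_bbox(masked)
            crop = masked[:, bbox[0]:bbox[2], bbox[1]:bbox[3]]
        else:
            bbox = None
            if use_ground_truth_bboxes and rec.face_bboxes:
                bbox = rec.face_bboxes.get(ch)
            crop = face_region_vis(frames, bbox=bbox, detector=detector)
        planes.append(downsample_two_stage(crop, pool_blocks[ch]))
    return DownsampledCube(np.stack(planes, axis=0), fs=rec.fs)
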