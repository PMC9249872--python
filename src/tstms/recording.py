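"""Multichannel trial recordings and their on-disk container.

A :class:`Recording` holds one trial's synchronized frame stacks: R, G, B and
NIR channels as gray-level videos, plus a temperature-calibrated LWIR channel
in degrees Celsius.  Recordings round-trip through a single HDF5 file per
trial (one dataset per channel, metadata as attributes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

#: fixed channel order used everywhere (cube axis 0, feature definitions)
CHANNELS = ("R", "G", "B", "NIR", "LWIR")
#: channels that carry a pulsatile (reflectance) signal
VIS_NIR_CHANNELS = ("R", "G", "B", "NIR")
#: common analysis grid: 50 rows (face height) x 35 columns (face width)
GRID_SHAPE = (50, 35)

CLASS_LABELS = ("A", "D", "F", "S", "N")


@dataclass
class Recording:
    """One trial: five synchronized frame stacks plus metadata.

    ``channels`` maps channel name to a ``(T, H, W)`` array — gray levels for
    R/G/B/NIR, degrees Celsius for LWIR.  ``face_bboxes`` optionally carries
    ground-truth face boxes ``(row0, col0, row1, col1)`` per channel (exclusive
    upper bounds); simulated recordings always provide them.
    """

    subject_id: str
    class_label: str
    gender: str
    channels: dict[str, np.ndarray]
    fs: float
    face_bboxes: dict[str, tuple[int, int, int, int]] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        fss = {ch: arr.ndim for ch, arr in self.channels.items()}
        for ch, nd in fss.items():
            if nd != 3:
                raise ValueError(f"channel {ch} must be (T, H, W), got ndim={nd}")

    @property
    def n_frames(self) -> int:
        return min(arr.shape[0] for arr in self.channels.values())

    def with_channels(self, channels: dict[str, np.ndarray]) -> "Recording":
        return replace(self, channels=channels)


def write_recording(rec: Recording, path) -> None:
    """Write one trial to an HDF5 container (one dataset per channel)."""
    with h5py.File(path, "w") as f:
        for ch, arr in rec.channels.items():
            f.create_dataset(ch, data=arr, compression="gzip", compression_opts=1)
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["class_label"] = rec.class_label
        f.attrs["gender"] = rec.gender
        f.attrs["fs"] = rec.fs
        if rec.face_bboxes is not None:
            for ch, bbox in rec.face_bboxes.items():
                f.attrs[f"bbox_{ch}"] = np.asarray(bbox, dtype=np.int64)


def read_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        channels = {ch: f[ch][...] for ch in f.keys()}
        bboxes = {
            k[len("bbox_"):]: tuple(int(v) for v in f.attrs[k])
            for k in f.attrs
            if k.startswith("bbox_")
        }
        return Recording(
            subject_id=str(f.attrs["subject_id"]),
            class_label=str(f.attrs["class_label"]),
            gender=str(f.attrs["gender"]),
            channels=channels,
            fs=float(f.attrs["fs"]),
            face_bboxes=bboxes or None,
        )
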