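"""Core image containers for dynamic amino-acid PET analysis.

All images live on a regular voxel grid in SUV units.  A dynamic acquisition
is a :class:`DynamicSeries` (frame x X x Y x Z) with an attached
:class:`FrameSchedule`; a summed late image is a :class:`StaticImage`; every
region of interest is a boolean :class:`VoiMask` on the image grid.

Conventions
-----------
* Voxel indices are 0-based; world coordinates are voxel-center millimetres
  obtained as ``index * voxel_size``.
* On disk, series and images are NIfTI-1 (spatial axes first, time last);
  frame timing travels in a JSON sidecar with keys ``frame_start_s`` and
  ``frame_duration_s``; masks are uint8 NIfTI-1 on the same grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "FrameSchedule",
    "DynamicSeries",
    "StaticImage",
    "VoiMask",
]

#: frame counts x durations (seconds) of the default 40-min dynamic protocol
DEFAULT_PROTOCOL = ((12, 5.0), (6, 10.0), (6, 30.0), (5, 60.0), (6, 300.0))


@dataclass(frozen=True)
class FrameSchedule:
    """Timing grid of a dynamic acquisition.

    Parameters
    ----------
    frame_start : ndarray
        Start of each frame in seconds post-injection, strictly increasing.
    frame_duration : ndarray
        Duration of each frame in seconds, all positive.  Frames must be
        contiguous: ``frame_start[i+1] == frame_start[i] + frame_duration[i]``.
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        if start.ndim != 1 or start.shape != dur.shape or start.size == 0:
            raise ValueError("frame_start and frame_duration must be equal-length 1-D arrays")
        if np.any(dur <= 0):
            raise ValueError("every frame_duration must be > 0")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame_start must be strictly increasing")
        if not np.allclose(start[1:], start[:-1] + dur[:-1]):
            raise ValueError("frames must be contiguous")
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)

    @classmethod
    def default(cls) -> "FrameSchedule":
        """The 35-frame, 40-min schedule: 12x5 s, 6x10 s, 6x30 s, 5x60 s, 6x300 s."""
        durations = np.concatenate([np.full(n, d) for n, d in DEFAULT_PROTOCOL])
        starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(starts, durations)

    @property
    def n_frames(self) -> int:
        return int(self.frame_start.size)

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def total_duration_s(self) -> float:
        return float(self.frame_end[-1])

    @property
    def mid_times_s(self) -> np.ndarray:
        return self.frame_start + 0.5 * self.frame_duration

    @property
    def mid_times_min(self) -> np.ndarray:
        return self.mid_times_s / 60.0

    def to_sidecar_dict(self) -> dict:
        return {
            "frame_start_s": self.frame_start.tolist(),
            "frame_duration_s": self.frame_duration.tolist(),
        }

    @classmethod
    def from_sidecar_dict(cls, d: dict) -> "FrameSchedule":
        return cls(np.asarray(d["frame_start_s"], float), np.asarray(d["frame_duration_s"], float))

    def save_sidecar(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_sidecar_dict(), indent=2) + "\n")

    @classmethod
    def load_sidecar(cls, path: str | Path) -> "FrameSchedule":
        return cls.from_sidecar_dict(json.loads(Path(path).read_text()))


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


@dataclass
class DynamicSeries:
    """4-D SUV voxel series: axis 0 is the frame axis."""

    voxels: np.ndarray  # (n_frames, nx, ny, nz), SUV
    schedule: FrameSchedule
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ValueError("DynamicSeries.voxels must be 4-D (frame, x, y, z)")
        if self.voxels.shape[0] != self.schedule.n_frames:
            raise ValueError("first axis must match schedule.n_frames")
        if np.any(self.voxels < 0):
            raise ValueError("SUV values must be >= 0")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def save(self, image_path: str | Path, sidecar_path: str | Path) -> None:
        data = np.transpose(self.voxels, (1, 2, 3, 0)).astype(np.float32)
        nib.save(nib.Nifti1Image(data, _affine(self.voxel_size)), str(image_path))
        self.schedule.save_sidecar(sidecar_path)

    @classmethod
    def load(cls, image_path: str | Path, sidecar_path: str | Path) -> "DynamicSeries":
        img = nib.load(str(image_path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"expected a 4-D NIfTI, got shape {data.shape}")
        voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
        schedule = FrameSchedule.load_sidecar(sidecar_path)
        return cls(np.transpose(data, (3, 0, 1, 2)), schedule, voxel_size)


@dataclass
class StaticImage:
    """3-D SUV image summed over an acquisition window (seconds p.i.)."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    window: tuple[float, float] = (1200.0, 2400.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("StaticImage.voxels must be 3-D")
        if np.any(self.voxels < 0):
            raise ValueError("SUV values must be >= 0")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.window = (float(self.window[0]), float(self.window[1]))

    def save(self, path: str | Path) -> None:
        nib.save(
            nib.Nifti1Image(self.voxels.astype(np.float32), _affine(self.voxel_size)), str(path)
        )


@dataclass
class VoiMask:
    """Boolean volume-of-interest on an image grid."""

    voxels: np.ndarray
    kind: str = "generic"  # sphere | crescent | tumor_autocontour | lesion_truth | ...

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("VoiMask.voxels must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def empty(self) -> bool:
        return not self.voxels.any()

    def volume_ml(self, voxel_size: tuple[float, float, float]) -> float:
        return self.n_voxels * float(np.prod(voxel_size)) / 1000.0

    def save(self, path: str | Path, voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)) -> None:
        nib.save(
            nib.Nifti1Image(self.voxels.astype(np.uint8), _affine(voxel_size)), str(path)
        )

    @classmethod
    def load(cls, path: str | Path, kind: str = "generic") -> "VoiMask":
        return cls(np.asarray(nib.load(str(path)).dataobj) > 0, kind=kind)
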