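"""Core containers shared by the simulator and the fitting pipeline.

Conventions used throughout the package (enforced at module boundaries):
0-based voxel indices, voxel-center geometry, times in ms, lengths in mm,
volumes in mm^3 (== ul), iron in mg/g dry weight.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

FRAME_KINDS = ("TE", "TI", "cine", "slice")


@dataclass
class ImageSeries:
    """A stack of 2D frames with an ordered timing axis.

    ``data`` has shape (ny, nx, nframes); ``times`` gives the acquisition
    time of each frame in ms (echo time, inversion time, or cine trigger
    time; for anatomical stacks it is the slice position in mm and
    ``kind`` is ``"slice"``).
    """

    data: np.ndarray
    times: np.ndarray
    kind: str
    voxel_size: tuple[float, float] = (0.3, 0.3)
    slice_thickness: float = 1.5

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"series data must be 3D (ny, nx, nframes), got {self.data.shape}")
        if self.times.shape != (self.data.shape[2],):
            raise ValueError(
                f"{self.data.shape[2]} frames but {self.times.size} times in sidecar"
            )
        if self.kind not in FRAME_KINDS:
            raise ValueError(f"unknown frame kind {self.kind!r}, expected one of {FRAME_KINDS}")
        if self.kind != "slice" and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[2])

    def frame(self, i: int) -> np.ndarray:
        return self.data[:, :, i]

    def copy(self) -> "ImageSeries":
        return replace(self, data=self.data.copy(), times=self.times.copy())


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing description of one acquisition.

    mode: spin_echo_multiTE | gradient_echo_multiTE | look_locker | cine
          | anatomical_stack
    times: TE/TI/frame times in ms, strictly increasing.
    """

    mode: str
    times: tuple[float, ...]
    slice_thickness: float = 1.5
    n_slices: int = 1

    _MODES = (
        "spin_echo_multiTE",
        "gradient_echo_multiTE",
        "look_locker",
        "cine",
        "anatomical_stack",
    )

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        t = np.asarray(self.times, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("protocol times must be strictly increasing")

    @property
    def times_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)


def spin_echo_protocol(n_echoes: int = 8, te_min: float = 2.7, te_max: float = 20.0) -> AcquisitionProtocol:
    """Multi-echo spin-echo protocol: 8 TEs spanning 2.7-20 ms by default."""
    return AcquisitionProtocol("spin_echo_multiTE", tuple(np.linspace(te_min, te_max, n_echoes)))


def gradient_echo_protocol(n_echoes: int = 15, te_min: float = 0.9, dte: float = 1.0) -> AcquisitionProtocol:
    """Multi-gradient-echo protocol: 15 TEs, 0.9-14.9 ms at 1 ms intervals."""
    return AcquisitionProtocol("gradient_echo_multiTE", tuple(te_min + dte * np.arange(n_echoes)))


def look_locker_protocol(heart_rate: float = 600.0, n_ti: int = 30, ti0: float = 10.0) -> AcquisitionProtocol:
    """Look-Locker protocol: ``n_ti`` inversion times spaced by the RR interval."""
    rr = 60000.0 / heart_rate
    return AcquisitionProtocol("look_locker", tuple(ti0 + rr * np.arange(n_ti)))


def cine_protocol(
    heart_rate: float = 600.0, dt: float = 5.0, slice_thickness: float = 1.0
) -> AcquisitionProtocol:
    """Cine protocol covering one cardiac cycle at ``dt`` ms temporal resolution."""
    rr = 60000.0 / heart_rate
    n = max(int(np.floor(rr / dt)), 2)
    return AcquisitionProtocol("cine", tuple(dt * np.arange(n)), slice_thickness=slice_thickness)


@dataclass
class SignalCurve:
    """ROI-mean signal sampled at each echo/inversion time."""

    times: np.ndarray
    values: np.ndarray
    n_voxels: int = 0
    rejected: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("curve times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")
        self.rejected = tuple(sorted(int(i) for i in self.rejected))
        if any(i < 0 or i >= self.times.size for i in self.rejected):
            raise ValueError("rejected indices out of range")

    @property
    def usable(self) -> np.ndarray:
        keep = np.ones(self.times.size, dtype=bool)
        keep[list(self.rejected)] = False
        return keep

    def usable_points(self) -> tuple[np.ndarray, np.ndarray]:
        keep = self.usable
        return self.times[keep], self.values[keep]
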