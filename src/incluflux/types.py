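"""Core data containers shared across the pipeline.

Conventions used throughout the package:

* image axis order is always ``TZCYX`` (time, z, channel, y, x);
* pixel indices are 0-based; physical units are μm, s, and min and are
  spelled out in attribute and column names;
* a :class:`Track` stores positions in μm together with its calibration so
  that downstream motion analysis never needs the source images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImageStack",
    "Track",
    "MSDCurve",
    "MotionEstimate",
    "MotionClass",
    "ObjectClass",
    "SegmentedObject",
    "CellMeasurement",
    "FluxSeries",
    "BleachDecayModel",
]


@dataclass
class ImageStack:
    """Multi-dimensional pixel data with physical calibration.

    ``data`` always carries five axes in ``TZCYX`` order; singleton axes are
    kept so that 2D frames, z-stacks and movies share one container.
    """

    data: np.ndarray  # TZCYX
    pixel_size_um: float
    frame_interval_s: float = 0.0
    z_spacing_um: float = 0.0
    channel_names: Sequence[str] = ("ch0",)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim > 5:
            raise ValueError(f"at most 5 axes (TZCYX) supported, got {arr.ndim}")
        # promote missing leading axes: YX -> ZYX -> CZYX? No: insert T,Z,C
        while arr.ndim < 5:
            arr = arr[np.newaxis]
        self.data = arr
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[3], self.data.shape[4]

    def frame(self, t: int, z: int = 0, c: int = 0) -> np.ndarray:
        """Return one 2D (Y, X) plane."""
        return self.data[t, z, c]

    def max_projection(self, t: int, c: int = 0) -> np.ndarray:
        """Maximum-intensity projection along z for one timepoint/channel."""
        return self.data[t, :, c].max(axis=0)


@dataclass
class Track:
    """Time-ordered particle coordinates with intensities.

    Positions are stored in μm.  ``frames`` must be strictly increasing;
    timestamps ``t_s`` are seconds from the first frame of the movie.
    """

    frames: np.ndarray
    t_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    intensity: np.ndarray
    pixel_size_um: float = 1.0
    frame_interval_s: float = 1.0
    track_id: int = 0
    diagnostic: Optional[str] = None  # set by the tracker when a path broke

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        for name in ("t_s", "x_um", "y_um", "intensity"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.frames)
        if not all(len(getattr(self, a)) == n for a in ("t_s", "x_um", "y_um", "intensity")):
            raise ValueError("all track columns must have equal length")
        if n >= 2 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("track frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def positions_um(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions in μm."""
        return np.column_stack([self.x_um, self.y_um])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "track_id": self.track_id,
                "frame": self.frames,
                "t_seconds": self.t_s,
                "x_um": self.x_um,
                "y_um": self.y_um,
                "intensity": self.intensity,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, pixel_size_um: float = 1.0,
                       frame_interval_s: float = 1.0) -> "Track":
        track_id = int(df["track_id"].iloc[0]) if "track_id" in df else 0
        return cls(
            frames=df["frame"].to_numpy(),
            t_s=df["t_seconds"].to_numpy(),
            x_um=df["x_um"].to_numpy(),
            y_um=df["y_um"].to_numpy(),
            intensity=df["intensity"].to_numpy() if "intensity" in df else np.ones(len(df)),
            pixel_size_um=pixel_size_um,
            frame_interval_s=frame_interval_s,
            track_id=track_id,
        )


@dataclass
class MSDCurve:
    """Mean squared displacement per lag.

    ``lag_frames`` are the integer lags k, ``dt_s`` the corresponding mean
    time intervals, ``msd_um2`` the mean over all overlapping start frames of
    the squared 2D displacement, and ``n_intervals`` the sample count per lag.
    """

    lag_frames: np.ndarray
    dt_s: np.ndarray
    msd_um2: np.ndarray
    n_intervals: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_frames": self.lag_frames,
                "dt_s": self.dt_s,
                "msd_um2": self.msd_um2,
                "n_intervals": self.n_intervals,
            }
        )


@dataclass
class MotionEstimate:
    """Fitted anomalous-diffusion exponent and diffusion coefficient."""

    alpha: float
    D_um2_s: float
    r_squared: float
    n_lags_used: int


class MotionClass(str, Enum):
    DIFFUSIVE = "diffusive"
    SUPERDIFFUSIVE = "superdiffusive"
    SUBDIFFUSIVE = "subdiffusive"


class ObjectClass(str, Enum):
    IB = "IB"
    SMALL_PARTICLE = "small_particle"
    CLI = "CLI"  # cluster-like inclusion


@dataclass
class SegmentedObject:
    """A thresholded fluorescent body measured on its brightest z-slice."""

    label: int
    z_slice: int
    area_um2: float
    perimeter_um: float
    circularity: float
    aspect_ratio: float
    mean_intensity: float
    centroid_yx_px: tuple[float, float] = (0.0, 0.0)
    apparent_volume_um3: Optional[float] = None
    n_visible_planes: int = 1
    object_class: Optional[ObjectClass] = None


@dataclass
class CellMeasurement:
    """Per-cell reference quantities for threshold-based segmentation.

    ``cytoplasm_mean`` is measured in a cytoplasmic region excluding the
    inclusion and the vacuole.
    """

    cytoplasm_mean: float
    cell_area_um2: float = np.nan
    vacuole_area_um2: float = 0.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.cytoplasm_mean <= 0:
            raise ValueError("cytoplasm_mean must be positive")


@dataclass
class FluxSeries:
    """Per-timepoint inclusion and cytoplasm intensities for one experiment.

    ``data`` has one row per (timepoint, channel) with columns
    ``time_min, channel, ib_area_um2, ib_mean, ib_integrated, cyto_mean,
    corrected``.  Integrated intensity is exactly area × mean.
    """

    data: pd.DataFrame
    normalization: Optional[str] = None
    meta: dict = field(default_factory=dict)

    REQUIRED = ("time_min", "channel", "ib_area_um2", "ib_mean",
                "ib_integrated", "cyto_mean", "corrected")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"FluxSeries missing columns: {missing}")

    def channel(self, name: str) -> pd.DataFrame:
        sub = self.data[self.data["channel"] == name]
        if sub.empty:
            raise ValueError(f"no such channel: {name!r}")
        return sub.sort_values("time_min").reset_index(drop=True)

    @property
    def channels(self) -> list[str]:
        return sorted(self.data["channel"].unique().tolist())


@dataclass
class BleachDecayModel:
    """Exponential photobleaching calibration: I(c) = I0 · retention^c."""

    retention_per_cycle: float
    fit_r_squared: float
    channel: str = "ch0"

    def __post_init__(self) -> None:
        if not (0 < self.retention_per_cycle <= 1):
            raise ValueError("retention_per_cycle must be in (0, 1]")

    @property
    def decay_rate(self) -> float:
        """Decay rate per cycle, −ln(retention)."""
        return -float(np.log(self.retention_per_cycle))
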