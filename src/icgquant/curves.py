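"""The sampled time-intensity trace at the center of the pipeline.

A :class:`PerfusionCurve` is what every stage of the package consumes or
produces: the simulator emits one, the video quantifier reduces a frame
stack to one, and the analysis model parameterizes one.  Intensities are in
arbitrary units (AU) -- fluorescence magnitudes depend on camera, light
source and working distance, which is exactly why the downstream analysis
favors time-based parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CurveFormatError

#: Minimum number of samples a curve must carry to be analyzable.
MIN_SAMPLES = 10


@dataclass(frozen=True)
class PerfusionCurve:
    """A sampled fluorescence time-intensity trace.

    Parameters
    ----------
    times : ndarray
        Sample times in seconds, strictly increasing.  The first sample
        defines t = 0 (the absolute origin is irrelevant: all perfusion
        time parameters are measured from the detected onset, not from
        injection).
    intensities : ndarray
        Fluorescence intensities in arbitrary units, same length as `times`.
    frame_rate : float, optional
        Frames per second, recorded when the curve was derived from a video
        frame stack (in which case times are i / frame_rate, 0-based).
    """

    times: np.ndarray
    intensities: np.ndarray
    frame_rate: float | None = None
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.shape != y.shape:
            raise CurveFormatError(
                "times and intensities must be 1-D arrays of equal length"
            )
        if t.size and np.any(np.diff(t) <= 0):
            raise CurveFormatError("times must be strictly increasing")
        if t.size and not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
            raise CurveFormatError("times and intensities must be finite")
        if t.size and t[0] != 0.0:
            t = t - t[0]
        if self.frame_rate is not None and self.frame_rate <= 0:
            raise CurveFormatError("frame_rate must be positive")
        t.setflags(write=False)
        y.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)

    # -- basic geometry -------------------------------------------------

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        """Time span covered by the samples, in seconds."""
        return float(self.times[-1] - self.times[0]) if len(self) else 0.0

    @property
    def dt(self) -> float:
        """Median inter-sample interval in seconds."""
        if len(self) < 2:
            raise CurveFormatError("need at least two samples for an interval")
        return float(np.median(np.diff(self.times)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        """Whether sampling is uniform to relative tolerance `rtol`."""
        if len(self) < 3:
            return True
        d = np.diff(self.times)
        return bool(np.max(np.abs(d - d[0])) <= rtol * d[0])

    # -- I/O ------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "intensity_au": self.intensities}
        )

    def to_csv(self, path) -> None:
        """Write the curve as a two-column CSV (`time_s,intensity_au`)."""
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, frame_rate: float | None = None
    ) -> "PerfusionCurve":
        missing = {"time_s", "intensity_au"} - set(frame.columns)
        if missing:
            raise CurveFormatError(f"curve table missing columns: {sorted(missing)}")
        return cls(
            times=frame["time_s"].to_numpy(dtype=float),
            intensities=frame["intensity_au"].to_numpy(dtype=float),
            frame_rate=frame_rate,
        )

    @classmethod
    def from_csv(cls, path, frame_rate: float | None = None) -> "PerfusionCurve":
        """Read a curve from a `time_s,intensity_au` CSV file."""
        return cls.from_dataframe(pd.read_csv(path), frame_rate=frame_rate)

    # -- transforms -----------------------------------------------------

    def with_intensities(self, intensities: np.ndarray) -> "PerfusionCurve":
        """Copy of the curve with intensities replaced (times preserved)."""
        return PerfusionCurve(
            times=self.times.copy(),
            intensities=np.asarray(intensities, dtype=float),
            frame_rate=self.frame_rate,
            label=self.label,
        )
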