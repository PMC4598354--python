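"""The central data container: plug length L(t) along the phantom axis.

Lengths are measured in mm from the injection end (x = 0) to the plug's
leading edge; times in seconds from the start of the recording. A series may
come from the tracker (``source="tracked"``) or from the simulator
(``source="simulated"``, in which case the noise-free ground truth is kept
alongside for validation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .geometry import TubeGeometry

#: CSV column names shared by the simulator and the tracker.
CSV_COLUMNS = ("t_s", "L_mm")
CSV_COLUMNS_WITH_TRUTH = ("t_s", "L_mm_true", "L_mm_noisy")


@dataclass
class PlugLengthSeries:
    """Time series of foam-plug length.

    Attributes
    ----------
    times
        Sample times, s, strictly increasing and (near-)uniformly spaced.
    lengths
        Plug length at each time, mm, >= 0. Frames where no plug is
        detected carry L = 0, never NaN, so phase detection always sees a
        complete series.
    geometry
        Phantom geometry, when known.
    source
        ``"simulated"`` or ``"tracked"``.
    truth
        Noise-free ground-truth lengths (simulated series only).
    """

    times: np.ndarray
    lengths: np.ndarray
    geometry: TubeGeometry | None = None
    source: str = "tracked"
    truth: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.lengths.shape:
            raise InvalidParameterError(
                "times and lengths must be 1-D arrays of equal length"
            )
        if self.times.size and not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("times must be strictly increasing")
        if np.any(~np.isfinite(self.lengths)) or np.any(self.lengths < 0):
            raise InvalidParameterError("lengths must be finite and >= 0")
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=float)
            if self.truth.shape != self.times.shape:
                raise InvalidParameterError("truth must match times in shape")

    def __len__(self) -> int:
        return self.times.size

    @property
    def frame_interval(self) -> float:
        """Median sample spacing, s."""
        return float(np.median(np.diff(self.times)))

    def to_csv(self, path: str | Path, include_truth: bool = False) -> Path:
        """Write the series as CSV (``t_s,L_mm``; with ground truth,
        ``t_s,L_mm_true,L_mm_noisy``)."""
        path = Path(path)
        if include_truth:
            if self.truth is None:
                raise InvalidParameterError("series carries no ground truth")
            df = pd.DataFrame(
                {"t_s": self.times, "L_mm_true": self.truth, "L_mm_noisy": self.lengths}
            )
        else:
            df = pd.DataFrame({"t_s": self.times, "L_mm": self.lengths})
        df.to_csv(path, index=False, float_format="%.6f")
        return path

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        geometry: TubeGeometry | None = None,
        source: str = "tracked",
    ) -> "PlugLengthSeries":
        """Read a series written by :meth:`to_csv` (either dialect)."""
        df = pd.read_csv(path)
        cols = tuple(df.columns)
        if set(CSV_COLUMNS) <= set(cols):
            return cls(df["t_s"].to_numpy(), df["L_mm"].to_numpy(), geometry, source)
        if set(CSV_COLUMNS_WITH_TRUTH) <= set(cols):
            return cls(
                df["t_s"].to_numpy(),
                df["L_mm_noisy"].to_numpy(),
                geometry,
                "simulated",
                truth=df["L_mm_true"].to_numpy(),
            )
        raise OSError(
            f"{path}: unrecognised series CSV header {cols!r}; expected "
            f"{CSV_COLUMNS} or {CSV_COLUMNS_WITH_TRUTH}"
        )
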