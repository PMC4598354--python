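"""Plug kinetics: formation rate, degradation rate (DR) and dwell time (DT).

Both experimental phases of a foam plug — expansion while the foam is
injected, recession as it degrades — are well described by straight lines,
so each is summarised by the ordinary-least-squares slope of L(t) over the
phase:

* **formation rate** (mm/s): |slope| during expansion, the effective speed
  at which the plug front advances;
* **degradation rate, DR** (mm/s): |slope| during recession; lower DR means
  a more cohesive foam;
* **dwell time, DT** (s/cm): ``DT = 10 / DR`` — the time the receding foam
  spends in contact with each cm of vessel wall, the clinically meaningful
  inverse of DR (the factor 10 converts mm to cm).

The module follows the statsmodels convention: build a
:class:`PlugKineticsModel` from a :class:`~foamplug.series.PlugLengthSeries`
and call :meth:`~PlugKineticsModel.fit` for a :class:`PlugKineticsResults`
carrying estimates, fit diagnostics and a ``summary()`` table. The phase
splitting and per-phase fits are also exposed as plain functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.ndimage import median_filter

from .errors import IncompleteDegradation, InvalidParameterError, NoPlugFormed
from .series import PlugLengthSeries

#: mm -> cm bridge used in DT = 10 / DR.
_MM_PER_CM = 10.0


@dataclass(frozen=True)
class PhaseSplit:
    """Index partition of a series into expansion and degradation phases.

    Ranges are inclusive ``(start, stop)`` index pairs; the expansion range
    ends at the peak and the degradation range starts there.
    """

    peak_index: int
    expansion_range: tuple[int, int]
    degradation_range: tuple[int, int]


def _effective_window(window: int, n: int) -> int:
    """Clamp the smoothing window to the largest odd integer <= n//2 (>=1)
    so short series are not over-smoothed."""
    w = min(window, max(1, n // 2))
    return w if w % 2 == 1 else w - 1


def split_phases(
    series: PlugLengthSeries,
    smooth_window: int = 5,
    plug_gate: float = 5.0,
    end_frac: float = 0.05,
) -> PhaseSplit:
    """Split a series at its peak into expansion and degradation phases.

    The peak is the argmax of a moving-median-smoothed copy of the series
    (earliest index on ties; the median is robust to single-frame
    dropouts). Phase endpoints are where the smoothed series crosses
    ``end_frac`` of its peak value, which keeps the pre-injection and
    post-degradation noise floors out of the fits.

    Raises
    ------
    NoPlugFormed
        If the smoothed maximum never reaches ``plug_gate`` (mm) — the foam
        failed to form a stable plug.
    IncompleteDegradation
        If the recording ends before the plug declines (fewer than 3
        degradation samples).
    """
    L = series.lengths
    n = L.size
    if n < 5:
        raise InvalidParameterError(f"need at least 5 samples, got {n}")
    if plug_gate <= 0:
        raise InvalidParameterError(f"plug_gate must be > 0, got {plug_gate}")
    w = _effective_window(smooth_window, n)
    smoothed = median_filter(L, size=w, mode="nearest") if w > 1 else L
    peak_val = float(smoothed.max())
    if peak_val < plug_gate:
        raise NoPlugFormed(
            f"max smoothed plug length {peak_val:.2f} mm is below the "
            f"{plug_gate:.2f} mm detection gate"
        )
    peak = int(np.argmax(smoothed))
    # The median filter can displace the argmax by up to half a window;
    # refine to the raw argmax within that neighbourhood (earliest on ties).
    lo_w = max(0, peak - w // 2)
    hi_w = min(n, peak + w // 2 + 1)
    peak = lo_w + int(np.argmax(L[lo_w:hi_w]))
    tol = end_frac * peak_val
    above = np.flatnonzero(smoothed > tol)
    start = int(above[0])
    end = int(above[-1])
    if peak >= n - 1 or end - peak < 2:
        raise IncompleteDegradation(
            "series ends before the plug has receded; cannot fit a "
            "degradation rate"
        )
    return PhaseSplit(
        peak_index=peak,
        expansion_range=(start, peak),
        degradation_range=(peak, end),
    )


def fit_rate(
    series: PlugLengthSeries, index_range: tuple[int, int]
) -> tuple[float, float]:
    """OLS slope of L vs t over an inclusive index range.

    Returns ``(rate, r2)`` with the rate as the magnitude of the slope
    (mm/s); the sign carries no information once phases are split.
    """
    lo, hi = index_range
    if not (0 <= lo <= hi < len(series)):
        raise InvalidParameterError(f"index_range {index_range} outside series")
    if hi - lo + 1 < 3:
        raise InvalidParameterError("need at least 3 samples to fit a rate")
    t = series.times[lo : hi + 1]
    L = series.lengths[lo : hi + 1]
    if np.ptp(t) == 0:
        raise InvalidParameterError("degenerate fit range: all times equal")
    res = stats.linregress(t, L)
    r2 = 0.0 if math.isnan(res.rvalue) else float(res.rvalue**2)
    return abs(float(res.slope)), r2


def dwell_time(dr: float) -> float:
    """Dwell time DT (s/cm) from a degradation rate DR (mm/s): DT = 10/DR."""
    if not (math.isfinite(dr) and dr > 0):
        raise InvalidParameterError(f"degradation rate must be > 0, got {dr}")
    return _MM_PER_CM / dr


def linear_to_volumetric(
    rate_mm_s: float, inner_diameter_mm: float, ndigits: int | None = None
) -> float:
    """Convert a linear front speed (mm/s) in a tube of circular
    cross-section to a volumetric rate (mL/s): ``rate * pi (d/2)^2 / 1000``.

    Full precision is returned unless ``ndigits`` is given (display
    convention: 2 decimal places).
    """
    if not (math.isfinite(rate_mm_s) and rate_mm_s >= 0):
        raise InvalidParameterError(f"rate must be >= 0, got {rate_mm_s}")
    if not (math.isfinite(inner_diameter_mm) and inner_diameter_mm > 0):
        raise InvalidParameterError(f"diameter must be > 0, got {inner_diameter_mm}")
    ml_s = rate_mm_s * math.pi * (inner_diameter_mm / 2.0) ** 2 / 1000.0
    return round(ml_s, ndigits) if ndigits is not None else ml_s


def injection_duration(volume_ml: float, rate_ml_s: float) -> float:
    """Time (s) to inject ``volume_ml`` at ``rate_ml_s``."""
    if not (math.isfinite(volume_ml) and volume_ml > 0):
        raise InvalidParameterError(f"volume must be > 0, got {volume_ml}")
    if not (math.isfinite(rate_ml_s) and rate_ml_s > 0):
        raise InvalidParameterError(f"rate must be > 0, got {rate_ml_s}")
    return volume_ml / rate_ml_s


def normalise_dt(dts) -> np.ndarray:
    """Normalise dwell times to the highest value (max maps to 1)."""
    dts = np.asarray(dts, dtype=float)
    if dts.size == 0:
        raise InvalidParameterError("empty dwell-time list")
    if np.any(~np.isfinite(dts)) or np.any(dts <= 0):
        raise InvalidParameterError("dwell times must be finite and > 0")
    return dts / dts.max()


class PlugKineticsModel:
    """Piecewise-linear kinetics model for one plug-length series.

    Parameters
    ----------
    series
        The L(t) series (tracked or simulated).
    smooth_window
        Moving-median window (frames) used only for phase detection.
    plug_gate
        Minimum smoothed peak length (mm) for the plug to count as formed.
        The default 5 mm suits the 4 and 10 mm phantoms; pass 10 % of the
        rendered tube length if that is larger.
    settle_skip
        Number of initial expansion-phase frames to drop before fitting
        (default 0: all phase samples are used).
    """

    def __init__(
        self,
        series: PlugLengthSeries,
        smooth_window: int = 5,
        plug_gate: float = 5.0,
        settle_skip: int = 0,
    ) -> None:
        self.series = series
        self.smooth_window = smooth_window
        self.plug_gate = plug_gate
        self.settle_skip = settle_skip

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "PlugKineticsModel":
        """Build a model from a ``t_s,L_mm`` series CSV."""
        return cls(PlugLengthSeries.from_csv(path), **kwargs)

    def fit(self) -> "PlugKineticsResults":
        """Split phases and fit both OLS lines."""
        split = split_phases(
            self.series, smooth_window=self.smooth_window, plug_gate=self.plug_gate
        )
        exp_lo, exp_hi = split.expansion_range
        exp_lo = min(exp_lo + self.settle_skip, exp_hi)
        deg_lo, deg_hi = split.degradation_range
        # The sample at the peak sits on the kink between the two lines and
        # belongs to neither; exclude it from each fit when enough samples
        # remain, so exact piecewise-linear input is recovered exactly.
        if exp_hi - exp_lo >= 3:
            exp_hi -= 1
        if deg_hi - deg_lo >= 3:
            deg_lo += 1
        formation_rate, r2_exp = fit_rate(self.series, (exp_lo, exp_hi))
        dr, r2_deg = fit_rate(self.series, (deg_lo, deg_hi))
        if formation_rate <= 0:
            raise NoPlugFormed("expansion phase has zero slope")
        if dr <= 0:
            raise IncompleteDegradation("degradation phase has zero slope")
        return PlugKineticsResults(
            model=self,
            phase_split=split,
            formation_rate=formation_rate,
            degradation_rate=dr,
            dwell_time_s_cm=dwell_time(dr),
            r2_expansion=r2_exp,
            r2_degradation=r2_deg,
            peak_length=float(self.series.lengths[split.peak_index]),
            n_expansion=exp_hi - exp_lo + 1,
            n_degradation=deg_hi - deg_lo + 1,
        )


@dataclass(frozen=True)
class PlugKineticsResults:
    """Fitted kinetics of one injection replicate."""

    model: PlugKineticsModel
    phase_split: PhaseSplit
    formation_rate: float  # mm/s
    degradation_rate: float  # mm/s (DR)
    dwell_time_s_cm: float  # s/cm (DT = 10/DR)
    r2_expansion: float
    r2_degradation: float
    peak_length: float  # mm
    n_expansion: int
    n_degradation: int

    def volumetric_formation_rate(self, ndigits: int | None = None) -> float:
        """Formation rate as a volumetric injection rate (mL/s), using the
        series' tube geometry."""
        geom = self.model.series.geometry
        if geom is None:
            raise InvalidParameterError("series carries no tube geometry")
        return linear_to_volumetric(
            self.formation_rate, geom.inner_diameter_mm, ndigits=ndigits
        )

    def to_dict(self) -> dict:
        """JSON-ready record of the replicate."""
        return {
            "formation_rate_mm_s": self.formation_rate,
            "dr_mm_s": self.degradation_rate,
            "dt_s_cm": self.dwell_time_s_cm,
            "r2_expansion": self.r2_expansion,
            "r2_degradation": self.r2_degradation,
            "peak_length_mm": self.peak_length,
            "n_expansion": self.n_expansion,
            "n_degradation": self.n_degradation,
        }

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            "Plug kinetics (piecewise-linear OLS)",
            "=" * 44,
            f"{'formation rate':<26}{self.formation_rate:>12.2f} mm/s",
            f"{'degradation rate (DR)':<26}{self.degradation_rate:>12.2f} mm/s",
            f"{'dwell time (DT)':<26}{self.dwell_time_s_cm:>12.2f} s/cm",
            f"{'peak plug length':<26}{self.peak_length:>12.1f} mm",
            f"{'r2 expansion':<26}{self.r2_expansion:>12.4f}",
            f"{'r2 degradation':<26}{self.r2_degradation:>12.4f}",
            f"{'n expansion / degradation':<26}"
            f"{self.n_expansion:>7d} /{self.n_degradation:>4d}",
        ]
        geom = self.model.series.geometry
        if geom is not None:
            lines.append(
                f"{'volumetric formation rate':<26}"
                f"{self.volumetric_formation_rate():>12.2f} mL/s"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the series with both fitted phase lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.series
        ax.plot(s.times, s.lengths, ".", ms=2, color="0.6", label="L(t)")
        for (lo, hi), rate, sign, label in (
            (self.phase_split.expansion_range, self.formation_rate, 1, "expansion"),
            (
                self.phase_split.degradation_range,
                self.degradation_rate,
                -1,
                "degradation",
            ),
        ):
            t = s.times[lo : hi + 1]
            res = stats.linregress(t, s.lengths[lo : hi + 1])
            ax.plot(t, res.intercept + res.slope * t, lw=2, label=label)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("plug length (mm)")
        ax.legend()
        return ax
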