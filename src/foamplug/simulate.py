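"""Synthetic data generation: plug kinetics, phantom videos and bubble fields.

No raw videos were deposited with the study this pipeline reproduces, so
every downstream stage is validated against this module instead. The
simulator emulates exactly the features the analysis relies on:

* plug length follows a piecewise-linear rise/fall (both experimental
  phases are fitted by straight lines, so no curvature is simulated), with
  additive Gaussian tracking noise clipped at zero;
* the phantom video shows a bright foam plug advancing over a dark blood
  substitute inside a horizontal tube band, with bubble texture and sensor
  noise;
* bubble populations are lognormal in diameter, for which number- and
  volume-weighted statistics have closed forms usable as test oracles.

All randomness flows through explicit integer seeds; there is no global
random state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import InvalidParameterError, PackingError, RenderBoundsError
from .geometry import TubeGeometry
from .series import PlugLengthSeries

#: Ceiling (mm) on the plug length reached when ``plug_fails`` is set: kept
#: below the default 5 mm plug-detection gate so the kinetics stage raises
#: its no-plug error, mirroring foams that never displace the blood
#: substitute.
FAILED_PLUG_MAX_MM = 2.0


def _require_positive(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise InvalidParameterError(f"{name} must be finite and > 0, got {value}")


def _require_nonnegative(name: str, value: float) -> None:
    if not (math.isfinite(value) and value >= 0):
        raise InvalidParameterError(f"{name} must be finite and >= 0, got {value}")


@dataclass(frozen=True)
class SimKinetics:
    """Ground-truth parameters of one simulated injection.

    The plug is 0 until ``start_time``, expands linearly at
    ``formation_rate`` (mm/s) to ``max_length`` (mm), then recedes linearly
    at ``degradation_rate`` (mm/s) back to 0. ``plug_fails`` caps the peak
    at :data:`FAILED_PLUG_MAX_MM`, modelling a foam that cannot form a
    stable plug.
    """

    formation_rate: float
    degradation_rate: float
    max_length: float
    start_time: float = 0.0
    noise_sigma: float = 0.5
    seed: int = 0
    plug_fails: bool = False

    def __post_init__(self) -> None:
        _require_positive("formation_rate", self.formation_rate)
        _require_positive("degradation_rate", self.degradation_rate)
        _require_positive("max_length", self.max_length)
        _require_nonnegative("start_time", self.start_time)
        _require_nonnegative("noise_sigma", self.noise_sigma)

    @property
    def peak_length(self) -> float:
        """Peak length actually reached, mm."""
        if self.plug_fails:
            return min(self.max_length, FAILED_PLUG_MAX_MM)
        return self.max_length

    @property
    def t_peak(self) -> float:
        """Time at which the peak is reached, s."""
        return self.start_time + self.peak_length / self.formation_rate

    @property
    def t_end(self) -> float:
        """Time at which the plug has fully degraded, s."""
        return self.t_peak + self.peak_length / self.degradation_rate

    def true_length(self, t: np.ndarray) -> np.ndarray:
        """Noise-free piecewise-linear trajectory L(t), mm."""
        t = np.asarray(t, dtype=float)
        rising = self.formation_rate * (t - self.start_time)
        falling = self.peak_length - self.degradation_rate * (t - self.t_peak)
        L = np.where(t < self.t_peak, rising, falling)
        return np.clip(L, 0.0, self.peak_length)


def simulate_series(
    kin: SimKinetics,
    frame_interval: float = 0.030,
    duration: float | None = None,
    geometry: TubeGeometry | None = None,
) -> PlugLengthSeries:
    """Sample a plug-length trajectory at the camera frame interval.

    Gaussian noise of sd ``kin.noise_sigma`` is added i.i.d. per sample and
    the result clipped at 0 (a tracker never reports negative length). The
    noise-free trajectory is retained in ``series.truth``. Identical seeds
    give bit-identical output.

    ``duration`` defaults to the full rise-peak-fall plus a 5 % margin.
    """
    _require_positive("frame_interval", frame_interval)
    if duration is None:
        duration = kin.t_end * 1.05 + frame_interval
    if duration <= 0:
        raise InvalidParameterError(f"duration must be > 0, got {duration}")
    n = int(math.floor(duration / frame_interval)) + 1
    t = np.arange(n) * frame_interval
    truth = kin.true_length(t)
    rng = np.random.default_rng(kin.seed)
    noisy = truth + rng.normal(0.0, kin.noise_sigma, size=n) if kin.noise_sigma > 0 else truth.copy()
    noisy = np.clip(noisy, 0.0, None)
    return PlugLengthSeries(t, noisy, geometry=geometry, source="simulated", truth=truth)


@dataclass(frozen=True)
class SimRender:
    """Rendering parameters for synthetic phantom (and flow-cell) frames.

    The tube is drawn as a horizontal band filling the frame: axial pixel 0
    is the injection end, foam renders bright against the darker
    glycerol/water blood substitute. ``medium_viscosity`` (Pa s) and
    ``medium_density`` (kg/m^3) are metadata describing that substitute;
    they do not enter the rendering.
    """

    mm_per_pixel: float = 0.25
    frame_interval: float = 0.030
    tube_axis_length: int = 800
    tube_width: int = 100
    foam_intensity: float = 0.9
    liquid_intensity: float = 0.2
    bubble_texture_density: float = 0.25  # bubbles per mm^2 of projected lumen
    intensity_noise_sigma: float = 0.02
    medium_viscosity: float = 0.003
    medium_density: float = 1078.0

    def __post_init__(self) -> None:
        _require_positive("mm_per_pixel", self.mm_per_pixel)
        _require_positive("frame_interval", self.frame_interval)
        if self.tube_axis_length < 1 or self.tube_width < 1:
            raise InvalidParameterError("tube dimensions must be >= 1 px")
        for name in ("foam_intensity", "liquid_intensity", "intensity_noise_sigma"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")
        if not self.foam_intensity > self.liquid_intensity:
            raise InvalidParameterError(
                "foam_intensity must exceed liquid_intensity "
                f"({self.foam_intensity} <= {self.liquid_intensity})"
            )
        _require_nonnegative("bubble_texture_density", self.bubble_texture_density)

    @property
    def tube_length_mm(self) -> float:
        return self.tube_axis_length * self.mm_per_pixel


def _foam_texture(render: SimRender, rng: np.random.Generator) -> np.ndarray:
    """Static foam texture: bright field with darker bubble discs."""
    tex = np.full((render.tube_width, render.tube_axis_length), render.foam_intensity)
    area_mm2 = render.tube_length_mm * render.tube_width * render.mm_per_pixel
    n_bubbles = int(round(render.bubble_texture_density * area_mm2))
    if n_bubbles:
        ys = rng.uniform(0, render.tube_width, n_bubbles)
        xs = rng.uniform(0, render.tube_axis_length, n_bubbles)
        radii = rng.uniform(1.0, 3.0, n_bubbles)
        shade = 0.5 * (render.foam_intensity + render.liquid_intensity)
        for y, x, r in zip(ys, xs, radii):
            _draw_disc(tex, y, x, r, shade)
    return tex


def _draw_disc(img: np.ndarray, y: float, x: float, r: float, value: float) -> None:
    """Paint a filled disc, touching only its bounding box."""
    h, w = img.shape
    y0, y1 = max(0, int(y - r) - 1), min(h, int(y + r) + 2)
    x0, x1 = max(0, int(x - r) - 1), min(w, int(x + r) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1][(yy - y) ** 2 + (xx - x) ** 2 <= r**2] = value


def render_video(
    series: PlugLengthSeries,
    render: SimRender,
    seed: int = 0,
) -> "np.ndarray":
    """Render a plug-length series as a stack of grayscale frames.

    Returns an array of shape ``(n_frames, tube_width, tube_axis_length)``
    with values in [0, 1]. Pixels whose axial coordinate (mm from the
    injection end) is below L(t) show foam (with bubble texture), the rest
    the blood substitute; Gaussian sensor noise is added per frame.
    """
    max_L = float(np.max(series.lengths))
    if max_L > render.tube_length_mm:
        raise RenderBoundsError(
            f"plug length {max_L:.1f} mm exceeds rendered tube "
            f"({render.tube_length_mm:.1f} mm)"
        )
    rng = np.random.default_rng(seed)
    texture = _foam_texture(render, rng)
    n = len(series)
    frames = np.empty((n, render.tube_width, render.tube_axis_length))
    for i, L in enumerate(series.lengths):
        n_foam = int(round(L / render.mm_per_pixel))
        frame = np.full(
            (render.tube_width, render.tube_axis_length), render.liquid_intensity
        )
        if n_foam > 0:
            frame[:, :n_foam] = texture[:, :n_foam]
        if render.intensity_noise_sigma > 0:
            frame = frame + rng.normal(
                0.0, render.intensity_noise_sigma, size=frame.shape
            )
        frames[i] = np.clip(frame, 0.0, 1.0)
    return frames


def write_frames(
    frames: np.ndarray,
    out_dir: str | Path,
    mm_per_pixel: float,
    frame_interval: float,
    ground_truth: dict | None = None,
) -> Path:
    """Write frames as numbered 8-bit grayscale PNGs plus a sidecar JSON.

    Files are named ``frame_000001.png`` ... and the sidecar
    ``metadata.json`` records the spatial/temporal calibration and any
    ground-truth parameters supplied.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames, start=1):
        img = np.clip(np.round(frame * 255), 0, 255).astype(np.uint8)
        iio.imwrite(out_dir / f"frame_{i:06d}.png", img)
    meta = {
        "mm_per_pixel": mm_per_pixel,
        "frame_interval": frame_interval,
        "n_frames": int(len(frames)),
    }
    if ground_truth:
        meta["ground_truth"] = ground_truth
    (out_dir / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return out_dir


# ---------------------------------------------------------------------------
# Bubble populations


@dataclass(frozen=True)
class SimBubblePopulation:
    """Lognormal bubble-diameter population (diameters in µm).

    ``ln(d) ~ N(log_mean, log_sigma^2)``. The volume-weighted (d^3-biased)
    distribution of a lognormal is again lognormal with its log-mean shifted
    by ``3 log_sigma^2``, so the analytic volume-weighted median is
    ``exp(log_mean + 3 log_sigma^2)`` — used as an independent oracle by the
    bubble-sizing tests.

    ``max_diameter`` optionally truncates the population (rejection
    sampling), emulating narrow microfoam populations with no bubbles above
    a cutoff.
    """

    log_mean: float
    log_sigma: float
    count: int
    seed: int = 0
    max_diameter: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.log_sigma) and self.log_sigma > 0):
            raise InvalidParameterError(
                f"log_sigma must be > 0, got {self.log_sigma}"
            )
        if not math.isfinite(self.log_mean):
            raise InvalidParameterError("log_mean must be finite")
        if self.count < 1:
            raise InvalidParameterError(f"count must be >= 1, got {self.count}")
        if self.max_diameter is not None:
            _require_positive("max_diameter", self.max_diameter)

    @property
    def volume_weighted_median(self) -> float:
        """Analytic volume-weighted median diameter of the *untruncated*
        population, µm."""
        return math.exp(self.log_mean + 3.0 * self.log_sigma**2)


def sample_bubbles(pop: SimBubblePopulation) -> np.ndarray:
    """Draw ``pop.count`` diameters (µm), seeded and strictly positive."""
    rng = np.random.default_rng(pop.seed)
    if pop.max_diameter is None:
        return rng.lognormal(pop.log_mean, pop.log_sigma, pop.count)
    out: list[np.ndarray] = []
    need = pop.count
    for _ in range(1000):
        draw = rng.lognormal(pop.log_mean, pop.log_sigma, max(need * 2, 16))
        draw = draw[draw <= pop.max_diameter]
        out.append(draw[:need])
        need -= len(out[-1])
        if need == 0:
            return np.concatenate(out)
    raise InvalidParameterError(
        "truncation bound rejects essentially the whole population"
    )


def render_bubble_frame(
    diameters_um: np.ndarray,
    render: SimRender,
    seed: int = 0,
    max_tries: int = 2000,
) -> np.ndarray:
    """Render dispersed bubbles as dark, non-overlapping discs on a bright
    background (the flow-cell cuvette view).

    The frame is ``tube_width x tube_axis_length`` px at
    ``render.mm_per_pixel`` (so µm per px = 1000 * mm_per_pixel);
    background intensity is ``foam_intensity`` and disc intensity
    ``liquid_intensity``. Discs are placed largest-first by seeded rejection
    sampling with a 1 px clearance, kept clear of the border; failure to
    place one within ``max_tries`` raises :class:`PackingError`.
    """
    diameters_um = np.asarray(diameters_um, dtype=float)
    h, w = render.tube_width, render.tube_axis_length
    um_per_px = render.mm_per_pixel * 1000.0
    frame = np.full((h, w), render.foam_intensity)
    rng = np.random.default_rng(seed)
    if diameters_um.size:
        radii = np.sort(diameters_um)[::-1] / um_per_px / 2.0
        if 2 * radii[0] > min(h, w) - 2:
            raise PackingError(
                f"bubble of {2 * radii[0]:.0f} px does not fit in a {h}x{w} frame"
            )
        placed = np.empty((0, 3))
        for r in radii:
            for _ in range(max_tries):
                y = rng.uniform(r + 1, h - r - 1)
                x = rng.uniform(r + 1, w - r - 1)
                if not placed.size or np.all(
                    (y - placed[:, 0]) ** 2 + (x - placed[:, 1]) ** 2
                    > (r + placed[:, 2] + 1.0) ** 2
                ):
                    placed = np.vstack([placed, [y, x, r]])
                    _draw_disc(frame, y, x, r, render.liquid_intensity)
                    break
            else:
                raise PackingError(
                    f"could not place a {2 * r:.1f} px bubble after "
                    f"{max_tries} tries ({len(placed)} placed)"
                )
    if render.intensity_noise_sigma > 0:
        frame = frame + rng.normal(0.0, render.intensity_noise_sigma, frame.shape)
    return np.clip(frame, 0.0, 1.0)


def render_bubble_frames(
    diameters_um: np.ndarray,
    render: SimRender,
    seed: int = 0,
    max_per_frame: int = 150,
) -> list[np.ndarray]:
    """Render a large population across several frames (an acquisition
    interval), ``max_per_frame`` bubbles per frame."""
    diameters_um = np.asarray(diameters_um, dtype=float)
    frames = []
    for k, lo in enumerate(range(0, diameters_um.size, max_per_frame)):
        chunk = diameters_um[lo : lo + max_per_frame]
        frames.append(render_bubble_frame(chunk, render, seed=seed + k))
    return frames
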