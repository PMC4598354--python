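"""Plug tracking: from phantom video frames to a calibrated L(t) series.

The measurement is one-dimensional: the tube is imaged as a horizontal band,
so each frame is collapsed to an axial intensity profile (mean across the
transverse direction), background-subtracted against a foam-free reference
frame, binarised (Otsu by default) and the plug read off as the longest
above-threshold run. Plug length is the axial distance from the injection
end to the run's leading edge, in mm.

The whole chain is deterministic: the same frames and configuration always
give the same series.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import median_filter
from skimage.filters import threshold_otsu

from .errors import CalibrationError, InvalidParameterError
from .geometry import TubeGeometry
from .series import PlugLengthSeries

_FRAME_EXTENSIONS = (".png", ".tif", ".tiff")


@dataclass
class FrameSequence:
    """An ordered stack of grayscale frames with uniform timestamps.

    ``frames`` has shape (n, height, width) with values in [0, 1]; ``roi``
    is the transverse (row) band covering the tube lumen, default the full
    frame height.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    roi: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise InvalidParameterError("frames must be a (n, H, W) stack")
        if self.timestamps.shape != (self.frames.shape[0],):
            raise InvalidParameterError("one timestamp per frame required")
        dt = np.diff(self.timestamps)
        if dt.size:
            if np.any(dt <= 0):
                raise InvalidParameterError("timestamps must be strictly increasing")
            if np.ptp(dt) > 0.01 * np.median(dt):
                raise InvalidParameterError(
                    "timestamps must be uniformly spaced within 1 %"
                )
        if self.roi is not None:
            lo, hi = self.roi
            if not (0 <= lo < hi <= self.frames.shape[1]):
                raise InvalidParameterError(f"roi {self.roi} outside frame height")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_interval(self) -> float:
        return float(np.median(np.diff(self.timestamps)))


def _natural_key(path: Path) -> tuple:
    parts = re.split(r"(\d+)", path.name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _to_grayscale_unit(img: np.ndarray, name: str) -> np.ndarray:
    if img.ndim == 3:  # RGB(A): average colour channels
        img = img[..., :3].mean(axis=-1)
    if img.ndim != 2:
        raise OSError(f"{name}: expected a 2-D grayscale image, got shape {img.shape}")
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    if img.dtype == np.uint16:
        return img.astype(float) / 65535.0
    return np.clip(img.astype(float), 0.0, 1.0)


def load_sequence(
    path: str | Path,
    geometry: TubeGeometry | None = None,
    frame_interval: float = 0.030,
    roi: tuple[int, int] | None = None,
) -> FrameSequence:
    """Load an image-stack directory (numbered PNG/TIFF) or an AVI file.

    Frames are normalised to [0, 1]; timestamps are ``index *
    frame_interval``. Directories are read in natural (numeric-aware) name
    order. Raises ``OSError`` naming the offending file on unreadable input
    or inconsistent frame sizes.
    """
    if frame_interval <= 0 or not math.isfinite(frame_interval):
        raise InvalidParameterError(f"frame_interval must be > 0, got {frame_interval}")
    path = Path(path)
    frames: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS),
            key=_natural_key,
        )
        if not files:
            raise OSError(f"{path}: no PNG/TIFF frames found")
        for f in files:
            try:
                img = iio.imread(f)
            except Exception as exc:  # noqa: BLE001 - re-raise with file name
                raise OSError(f"{f}: unreadable image ({exc})") from exc
            frames.append(_to_grayscale_unit(img, str(f)))
            if frames[-1].shape != frames[0].shape:
                raise OSError(
                    f"{f}: frame size {frames[-1].shape} differs from "
                    f"{files[0].name} {frames[0].shape}"
                )
    elif path.is_file():
        try:
            for img in iio.imiter(path):
                frames.append(_to_grayscale_unit(np.asarray(img), str(path)))
        except Exception as exc:  # no suitable decoder plugin, corrupt file, ...
            raise OSError(f"{path}: cannot decode video ({exc})") from exc
        if not frames:
            raise OSError(f"{path}: no frames decoded")
    else:
        raise OSError(f"{path}: no such file or directory")
    stack = np.stack(frames)
    timestamps = np.arange(stack.shape[0]) * frame_interval
    return FrameSequence(stack, timestamps, roi=roi)


def axial_profile(frame: np.ndarray, roi: tuple[int, int] | None = None) -> np.ndarray:
    """Mean intensity across the transverse (row) direction at each axial
    position; output length equals the frame width."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise InvalidParameterError("frame must be 2-D")
    if roi is not None:
        lo, hi = roi
        if not (0 <= lo < hi <= frame.shape[0]):
            raise InvalidParameterError(f"roi {roi} empty or outside frame")
        frame = frame[lo:hi]
    return frame.mean(axis=0)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a boolean vector."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def segment_plug(
    profile: np.ndarray,
    background_profile: np.ndarray,
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
    min_run_px: int = 5,
    noise_floor_mult: float = 6.0,
) -> tuple[int, int] | None:
    """Locate the foam plug in one background-subtracted axial profile.

    The profile is assumed oriented with axial pixel 0 at the injection
    end. The difference ``profile - background_profile`` is binarised at an
    Otsu threshold (or ``fixed_threshold``), floored at ``noise_floor_mult``
    times a high-frequency noise estimate so that a foam-free frame yields
    no plug. The plug is the longest above-threshold run of at least
    ``min_run_px`` pixels (ties broken toward the injection end). Returns
    the half-open pixel run ``(start, stop)``, or ``None`` when no plug is
    present — absence is a result, not an error.
    """
    profile = np.asarray(profile, dtype=float)
    background_profile = np.asarray(background_profile, dtype=float)
    if profile.shape != background_profile.shape or profile.ndim != 1:
        raise InvalidParameterError("profile and background must be equal-length 1-D")
    diff = profile - background_profile
    if np.ptp(diff) == 0:
        return None
    # Noise floor from first differences: robust to the step itself, scales
    # with any global intensity rescaling of the frames.
    sigma_hf = 1.4826 * np.median(np.abs(np.diff(diff))) / math.sqrt(2.0)
    floor = noise_floor_mult * sigma_hf
    if threshold_method == "fixed":
        if fixed_threshold is None:
            raise InvalidParameterError("fixed_threshold required with method 'fixed'")
        thr = fixed_threshold
    elif threshold_method == "otsu":
        thr = max(float(threshold_otsu(diff)), floor)
    else:
        raise InvalidParameterError(f"unknown threshold_method {threshold_method!r}")
    # A run qualifies when it is long enough on its own, or when it is
    # anchored at the injection end (within the gate) with its leading edge
    # past the gate — the plug's trailing edge is x = 0 by definition, so a
    # foam sliver present in the background frame may eat the first pixels.
    runs = [
        r
        for r in _runs_above(diff > thr)
        if (r[1] - r[0] >= min_run_px) or (r[0] < min_run_px <= r[1])
    ]
    if not runs:
        return None
    best_len = max(r[1] - r[0] for r in runs)
    return min((r for r in runs if r[1] - r[0] == best_len), key=lambda r: r[0])


def track(
    sequence: FrameSequence,
    geometry: TubeGeometry,
    background: np.ndarray | None = None,
    min_plug_mm: float = 5.0,
    median_window: int = 1,
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
) -> PlugLengthSeries:
    """Track the plug's leading edge through a sequence.

    Per frame, ``L = leading_edge_px * mm_per_pixel`` measured from the
    injection end; frames with no detected plug give L = 0. An optional
    running median (``median_window`` = 3) can suppress single-frame
    dropouts; monotonicity is never enforced — noise is legitimate data.

    ``background`` supplies a foam-free reference frame; by default the
    first frame is used after a check that it does not already contain
    foam (raises :class:`CalibrationError` otherwise).
    """
    roi = sequence.roi
    min_run_px = max(1, int(round(min_plug_mm / geometry.mm_per_pixel)))
    if background is None:
        first = axial_profile(sequence.frames[0], roi)
        smooth = median_filter(first, size=5, mode="nearest")
        # Foam renders as a bright band well above the blood substitute; a
        # plug-sized such band in the reference frame breaks background
        # subtraction. Sub-gate slivers (noise at the injection port) are
        # tolerated.
        n_bright = int(np.sum(smooth > np.median(smooth) + 0.25))
        if n_bright >= min_run_px:
            raise CalibrationError(
                "no background frame supplied and the first frame appears "
                "to contain foam (bright plug-sized band); pass a foam-free "
                "background frame explicitly"
            )
        bg_profile = first
    else:
        bg_profile = axial_profile(np.asarray(background, dtype=float), roi)

    flip = geometry.injection_end == "right"
    if flip:
        bg_profile = bg_profile[::-1]

    lengths = np.zeros(len(sequence))
    for i in range(len(sequence)):
        profile = axial_profile(sequence.frames[i], roi)
        if flip:
            profile = profile[::-1]
        run = segment_plug(
            profile,
            bg_profile,
            threshold_method=threshold_method,
            fixed_threshold=fixed_threshold,
            min_run_px=min_run_px,
        )
        if run is not None:
            lengths[i] = run[1] * geometry.mm_per_pixel
    if median_window > 1:
        lengths = median_filter(lengths, size=median_window, mode="nearest")
    return PlugLengthSeries(
        sequence.timestamps.copy(), lengths, geometry=geometry, source="tracked"
    )
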