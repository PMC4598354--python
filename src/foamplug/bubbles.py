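"""Bubble sizing: per-bubble equivalent diameters and volume-fraction
distributions.

Flow-cell frames show dispersed bubbles as dark discs on a bright
background. Detection is deliberately simple and deterministic: Otsu
threshold, hole filling, connected components, then gates on minimum
diameter, border contact and circularity (to reject clumps and truncated
bubbles). Each bubble is summarised by its equivalent-circle diameter
``2 sqrt(area / pi)`` scaled to µm.

Distributions are volume weighted: each bubble contributes in proportion to
d^3 (spherical volume), the q3 convention of particle sizing. Replicates
are pooled by total volume — an acquisition interval with more bubbles
weighs more — not by averaging fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_fill_holes
from skimage.measure import label, regionprops

from .errors import InvalidParameterError, NoBubblesDetected

#: Default bin grid: 50 µm bins spanning 0–1550 µm (the displayed range of
#: the reference distributions).
DEFAULT_BIN_EDGES = np.arange(0.0, 1600.0, 50.0)
#: Default thresholds for the "volume fraction above" summaries. 500 µm
#: separates microfoam-like populations from those with large, unstable
#: bubbles.
DEFAULT_THRESHOLDS = (500.0,)


@dataclass(frozen=True)
class BubbleRecord:
    """One detected bubble."""

    frame_index: int
    equivalent_diameter_um: float
    centroid_px: tuple[float, float]
    circularity: float

    def __post_init__(self) -> None:
        if self.equivalent_diameter_um <= 0:
            raise InvalidParameterError("equivalent diameter must be > 0")
        if not (0 <= self.circularity <= 1):
            raise InvalidParameterError("circularity must be in [0, 1]")


def detect_bubbles(
    frame: np.ndarray,
    um_per_pixel: float,
    min_diameter_um: float | None = None,
    min_circularity: float = 0.6,
    min_contrast: float = 0.1,
    frame_index: int = 0,
) -> list[BubbleRecord]:
    """Detect dark bubbles on a bright background in one grayscale frame.

    Components smaller than ``min_diameter_um`` (default: 2 px equivalent),
    touching the frame border, or with circularity ``4 pi A / P^2`` below
    ``min_circularity`` are discarded. Frames whose Otsu split separates
    the classes by less than ``min_contrast`` intensity units are treated
    as bubble-free. An empty list is a valid result.
    """
    from skimage.filters import threshold_otsu

    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise InvalidParameterError("frame must be 2-D grayscale")
    if um_per_pixel <= 0:
        raise InvalidParameterError(f"um_per_pixel must be > 0, got {um_per_pixel}")
    floor_um = 2.0 * um_per_pixel
    min_diameter_um = max(min_diameter_um or 0.0, floor_um)
    if np.ptp(frame) == 0:
        return []
    thr = float(threshold_otsu(frame))
    dark = frame < thr
    if not dark.any() or dark.all():
        return []
    if frame[~dark].mean() - frame[dark].mean() < min_contrast:
        return []  # unimodal frame: Otsu split is just sensor noise
    mask = binary_fill_holes(dark)
    h, w = mask.shape
    records: list[BubbleRecord] = []
    for prop in regionprops(label(mask)):
        minr, minc, maxr, maxc = prop.bbox
        if minr == 0 or minc == 0 or maxr == h or maxc == w:
            continue  # truncated at the border
        d_um = 2.0 * np.sqrt(prop.area / np.pi) * um_per_pixel
        if d_um < min_diameter_um:
            continue
        perimeter = max(prop.perimeter, 1.0)
        circularity = min(4.0 * np.pi * prop.area / perimeter**2, 1.0)
        if circularity < min_circularity:
            continue
        records.append(
            BubbleRecord(
                frame_index=frame_index,
                equivalent_diameter_um=float(d_um),
                centroid_px=(float(prop.centroid[0]), float(prop.centroid[1])),
                circularity=float(circularity),
            )
        )
    return records


def detect_bubbles_stack(
    frames, um_per_pixel: float, **kwargs
) -> list[BubbleRecord]:
    """Run :func:`detect_bubbles` over a stack of frames."""
    records: list[BubbleRecord] = []
    for i, frame in enumerate(frames):
        records.extend(
            detect_bubbles(frame, um_per_pixel, frame_index=i, **kwargs)
        )
    return records


@dataclass
class BubbleSizeDistribution:
    """Binned, volume-fraction-weighted bubble-diameter distribution.

    ``volume_fraction`` sums to 1 over the bins; ``frac_above`` maps each
    configured threshold (µm) to the volume fraction strictly above it.
    ``total_volume`` (arbitrary d^3 units) is retained so replicates can be
    pooled by volume; ``diameters`` keeps the underlying sample when
    available for exact weighted quantiles.
    """

    bin_edges: np.ndarray
    volume_fraction: np.ndarray
    n_bubbles: int
    n_replicates: int
    frac_above: dict[float, float]
    total_volume: float
    diameters: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise InvalidParameterError("bin_edges must be strictly increasing")
        if self.volume_fraction.size != self.bin_edges.size - 1:
            raise InvalidParameterError("one fraction per bin required")
        if np.any(self.volume_fraction < -1e-12):
            raise InvalidParameterError("volume fractions must be >= 0")
        if abs(self.volume_fraction.sum() - 1.0) > 1e-9:
            raise InvalidParameterError("volume fractions must sum to 1")

    def volume_weighted_median(self) -> float:
        """Median of the d^3-weighted diameter distribution, µm.

        Exact when the underlying diameters were retained; otherwise
        interpolated within the bins.
        """
        if self.diameters is not None and self.diameters.size:
            d = np.sort(self.diameters)
            cum = np.cumsum(d**3)
            return float(d[np.searchsorted(cum, 0.5 * cum[-1])])
        cum = np.concatenate(([0.0], np.cumsum(self.volume_fraction)))
        return float(np.interp(0.5, cum, self.bin_edges))

    def to_frame(self) -> pd.DataFrame:
        """Distribution as a DataFrame (``bin_lo_um,bin_hi_um,volume_fraction``)."""
        return pd.DataFrame(
            {
                "bin_lo_um": self.bin_edges[:-1],
                "bin_hi_um": self.bin_edges[1:],
                "volume_fraction": self.volume_fraction,
            }
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.8f")
        return path

    def summary(self) -> str:
        lines = [
            "Bubble size distribution (volume weighted)",
            "=" * 44,
            f"{'bubbles':<28}{self.n_bubbles:>12d}",
            f"{'replicates':<28}{self.n_replicates:>12d}",
            f"{'volume-weighted median':<28}{self.volume_weighted_median():>10.1f} um",
        ]
        for thr, frac in sorted(self.frac_above.items()):
            lines.append(f"{f'volume fraction > {thr:.0f} um':<28}{frac:>12.4f}")
        return "\n".join(lines)


def _prepare_edges(diameters: np.ndarray, bin_edges) -> np.ndarray:
    if bin_edges is None:
        edges = DEFAULT_BIN_EDGES.copy()
    else:
        edges = np.asarray(bin_edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise InvalidParameterError("bin_edges must be monotone with >= 2 edges")
    # Extend by whole bins so every bubble is counted and fractions sum to 1.
    width = edges[-1] - edges[-2]
    dmax = diameters.max()
    while dmax >= edges[-1]:
        edges = np.append(edges, edges[-1] + width)
    return edges


def volume_distribution(
    records,
    bin_edges=None,
    thresholds=DEFAULT_THRESHOLDS,
) -> BubbleSizeDistribution:
    """Bin bubbles into a volume-fraction distribution.

    ``records`` may be :class:`BubbleRecord` objects or raw diameters (µm).
    Each bubble is weighted by d^3; per-bin weights are normalised to sum
    to 1. Raises :class:`NoBubblesDetected` on an empty input so "no
    bubbles" is distinguishable from an all-zero histogram.
    """
    if hasattr(records, "__len__") and len(records) == 0:
        raise NoBubblesDetected("no bubbles detected: cannot form a distribution")
    first = records[0]
    if isinstance(first, BubbleRecord):
        diameters = np.array([r.equivalent_diameter_um for r in records], dtype=float)
    else:
        diameters = np.asarray(records, dtype=float)
    if np.any(diameters <= 0):
        raise InvalidParameterError("diameters must be > 0")
    edges = _prepare_edges(diameters, bin_edges)
    weights = diameters**3
    total = float(weights.sum())
    hist, _ = np.histogram(diameters, bins=edges, weights=weights)
    frac_above = {
        float(thr): float(weights[diameters > thr].sum() / total) for thr in thresholds
    }
    return BubbleSizeDistribution(
        bin_edges=edges,
        volume_fraction=hist / total,
        n_bubbles=int(diameters.size),
        n_replicates=1,
        frac_above=frac_above,
        total_volume=total,
        diameters=diameters,
    )


def aggregate_replicates(distributions) -> BubbleSizeDistribution:
    """Pool replicate distributions by total volume weight.

    All replicates must share the same bin grid. Pooling is physical: bin
    volumes (fraction x total volume) are summed across replicates and
    renormalised, so a replicate with more bubbles contributes more.
    """
    distributions = list(distributions)
    if not distributions:
        raise InvalidParameterError("no distributions to aggregate")
    edges = distributions[0].bin_edges
    for d in distributions[1:]:
        if d.bin_edges.shape != edges.shape or not np.allclose(d.bin_edges, edges):
            raise InvalidParameterError("replicates have mismatched bin edges")
    bin_volumes = sum(d.volume_fraction * d.total_volume for d in distributions)
    total = float(sum(d.total_volume for d in distributions))
    thresholds = set().union(*(d.frac_above for d in distributions))
    frac_above = {
        thr: float(
            sum(d.frac_above.get(thr, 0.0) * d.total_volume for d in distributions)
            / total
        )
        for thr in thresholds
    }
    diameters = None
    if all(d.diameters is not None for d in distributions):
        diameters = np.concatenate([d.diameters for d in distributions])
    return BubbleSizeDistribution(
        bin_edges=edges.copy(),
        volume_fraction=bin_volumes / total,
        n_bubbles=sum(d.n_bubbles for d in distributions),
        n_replicates=sum(d.n_replicates for d in distributions),
        frac_above=frac_above,
        total_volume=total,
        diameters=diameters,
    )


def records_to_frame(records) -> pd.DataFrame:
    """Per-bubble table (``frame,diameter_um,circularity``)."""
    return pd.DataFrame(
        {
            "frame": [r.frame_index for r in records],
            "diameter_um": [r.equivalent_diameter_um for r in records],
            "circularity": [r.circularity for r in records],
        }
    )
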