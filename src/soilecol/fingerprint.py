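"""Community fingerprint analysis from densitometric gel traces.

A lane of a denaturing-gradient gel (or, equivalently, a T-RFLP
electropherogram) is a 1-D intensity trace over a migration axis.  The
processing chain mirrors standard gel-analysis software: rolling-ball
background subtraction, peak (band) detection with a minimum-slope criterion
and a relative-height cutoff, cross-lane matching of band positions into band
classes, and finally per-lane diversity indices (richness R, Shannon H',
Simpson dominance D, Pielou evenness J) plus pairwise Dice / Jaccard /
Bray-Curtis comparisons, each band being treated as one operational taxonomic
unit (OTU).

Band positions are expressed as relative migration Rf in [0, 1], which makes
profiles from different lanes directly comparable once gels are aligned on
reference markers (alignment is assumed done upstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from skimage.restoration import rolling_ball

__all__ = [
    "LaneTrace",
    "Band",
    "BandProfile",
    "BandMatrix",
    "subtract_background",
    "detect_bands",
    "match_bands",
    "richness",
    "shannon",
    "simpson",
    "evenness",
    "dice_similarity",
    "jaccard_similarity",
    "bray_curtis",
]


@dataclass(frozen=True)
class LaneTrace:
    """Densitometric trace over a uniform migration grid spanning Rf 0..1."""

    intensities: np.ndarray
    lane_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", arr)
        if arr.ndim != 1 or arr.size < 50:
            raise ValueError("trace must be 1-D with length >= 50")
        if not np.all(np.isfinite(arr)):
            raise ValueError("trace contains non-finite values")

    def __len__(self) -> int:
        return int(self.intensities.size)


@dataclass(frozen=True)
class Band:
    position: float  # Rf in [0, 1]
    height: float
    area: float = 0.0


@dataclass(frozen=True)
class BandProfile:
    """Called bands of one lane, sorted by position."""

    bands: tuple[Band, ...]
    lane_id: str = ""

    def __post_init__(self) -> None:
        pos = [b.position for b in self.bands]
        if any(h.height <= 0 for h in self.bands):
            raise ValueError("band intensities must be positive")
        if any(b - a <= 0 for a, b in zip(pos, pos[1:])):
            raise ValueError("band positions must be strictly increasing")

    def positions(self) -> np.ndarray:
        return np.array([b.position for b in self.bands])

    def intensities(self, basis: str = "height") -> np.ndarray:
        if basis == "height":
            return np.array([b.height for b in self.bands])
        if basis == "area":
            return np.array([b.area for b in self.bands])
        raise ValueError("intensity basis must be 'height' or 'area'")


@dataclass(frozen=True)
class BandMatrix:
    """Lanes x matched band classes.

    presence is binary; intensity is zero wherever presence is zero;
    relative_intensity rows sum to 1 (all-zero rows allowed for empty lanes).
    """

    lanes: tuple[str, ...]
    band_classes: np.ndarray  # class centroid Rf positions
    presence: np.ndarray
    intensity: np.ndarray
    relative_intensity: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if np.any((self.presence == 0) & (self.intensity != 0)):
            raise ValueError("intensity must be zero where a band is absent")
        totals = self.intensity.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            rel = np.where(totals > 0, self.intensity / np.where(totals > 0, totals, 1), 0.0)
        object.__setattr__(self, "relative_intensity", rel)

    def lane_index(self, lane_id: str) -> int:
        return self.lanes.index(lane_id)


def subtract_background(trace: LaneTrace, ball_radius: int = 50) -> LaneTrace:
    """Remove a rolling-ball baseline (radius in grid units); clamp at zero.

    A constant trace maps to all zeros; a narrow peak on a flat background is
    preserved because the ball cannot follow it.
    """
    if ball_radius < 1:
        raise ValueError("ball_radius must be >= 1")
    if ball_radius >= len(trace):
        raise ValueError("ball_radius must be smaller than the trace length")
    background = rolling_ball(trace.intensities, radius=ball_radius)
    out = np.clip(trace.intensities - background, 0.0, None)
    return LaneTrace(out, lane_id=trace.lane_id)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(x, pad, mode="edge")
    sm = np.convolve(padded, kernel, mode="same")
    return sm[pad : pad + x.size]


def detect_bands(
    trace: LaneTrace,
    min_slope: float = 200.0,
    smoothing_window: int = 3,
    min_peak_fraction: float = 0.02,
) -> BandProfile:
    """Call bands as local maxima of the (smoothed) background-free trace.

    A peak is kept when its steepest rising-edge slope (intensity per grid
    unit, on the smoothed trace) reaches ``min_slope`` and its height is at
    least ``min_peak_fraction`` of the tallest retained candidate.  Positions
    are reported as Rf; the peak area is integrated between the flanking
    minima (trapezoid rule on the Rf axis).

    Note ``min_slope`` is meaningful only relative to the intensity scaling of
    the trace; the default suits 8-bit-style traces with band heights in the
    hundreds to thousands.
    """
    if not 0.0 <= min_peak_fraction < 1.0:
        raise ValueError("min_peak_fraction must lie in [0, 1)")
    x = trace.intensities
    if x.size == 0:
        raise ValueError("empty trace")
    n = x.size
    grid_step = 1.0 / (n - 1)
    sm = _moving_average(x, smoothing_window)
    peaks, props = find_peaks(sm, height=0.0)
    if peaks.size == 0:
        return BandProfile(bands=(), lane_id=trace.lane_id)

    slope = np.diff(sm)
    keep = []
    for p in peaks:
        # steepest rise between the preceding minimum and the peak apex
        left = p
        while left > 0 and sm[left - 1] <= sm[left]:
            left -= 1
        rise = slope[left:p]
        max_rise = rise.max() if rise.size else 0.0
        if max_rise >= min_slope:
            keep.append(p)
    if not keep:
        return BandProfile(bands=(), lane_id=trace.lane_id)

    heights = sm[keep]
    cutoff = min_peak_fraction * heights.max()
    bands = []
    for p, h in zip(keep, heights):
        if h < cutoff:
            continue
        lo = p
        while lo > 0 and sm[lo - 1] < sm[lo]:
            lo -= 1
        hi = p
        while hi < n - 1 and sm[hi + 1] < sm[hi]:
            hi += 1
        area = float(np.trapezoid(sm[lo : hi + 1], dx=grid_step))
        bands.append(Band(position=p * grid_step, height=float(h), area=area))
    return BandProfile(bands=tuple(bands), lane_id=trace.lane_id)


def match_bands(
    profiles: list[BandProfile],
    position_tolerance: float = 0.01,
    intensity_basis: str = "height",
) -> BandMatrix:
    """Group band positions across lanes into shared band classes.

    Single-linkage in 1-D: pooled positions are sorted and split wherever the
    gap between neighbours exceeds the tolerance, which is exactly the
    transitive closure of the "within tolerance" relation.  When one lane
    contributes several bands to a class, the band nearest the class centroid
    is kept (ties resolved toward smaller Rf), so each lane has at most one
    band per class.
    """
    if position_tolerance <= 0:
        raise ValueError("position_tolerance must be positive")
    lanes = tuple(p.lane_id for p in profiles)
    entries = []  # (position, lane index, intensity)
    for li, prof in enumerate(profiles):
        vals = prof.intensities(intensity_basis)
        for band, v in zip(prof.bands, vals):
            entries.append((band.position, li, float(v)))
    if not entries:
        return BandMatrix(
            lanes=lanes,
            band_classes=np.empty(0),
            presence=np.zeros((len(lanes), 0), dtype=int),
            intensity=np.zeros((len(lanes), 0)),
        )
    entries.sort(key=lambda e: e[0])
    groups: list[list[tuple[float, int, float]]] = [[entries[0]]]
    for prev, cur in zip(entries, entries[1:]):
        if cur[0] - prev[0] > position_tolerance:
            groups.append([cur])
        else:
            groups[-1].append(cur)

    centroids = np.array([np.mean([e[0] for e in g]) for g in groups])
    presence = np.zeros((len(lanes), len(groups)), dtype=int)
    intensity = np.zeros((len(lanes), len(groups)))
    for gi, g in enumerate(groups):
        chosen: dict[int, tuple[float, int, float]] = {}
        for e in g:
            li = e[1]
            if li not in chosen:
                chosen[li] = e
            else:
                d_new = abs(e[0] - centroids[gi])
                d_old = abs(chosen[li][0] - centroids[gi])
                if d_new < d_old or (d_new == d_old and e[0] < chosen[li][0]):
                    chosen[li] = e
        for li, e in chosen.items():
            presence[li, gi] = 1
            intensity[li, gi] = e[2]
    return BandMatrix(
        lanes=lanes, band_classes=centroids, presence=presence, intensity=intensity
    )


# ---------------------------------------------------------------------------
# diversity indices (per lane)


def richness(presence_row: np.ndarray) -> int:
    """Richness R: number of bands present in the lane."""
    return int(np.count_nonzero(np.asarray(presence_row)))


def _check_relative(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty abundance vector")
    if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("relative intensities must be nonnegative and sum to 1")
    return p


def shannon(relative: np.ndarray, base: float = math.e) -> float:
    """Shannon-Weaver diversity H' = -sum P_i log P_i (0 log 0 = 0)."""
    p = _check_relative(relative)
    p = p[p > 0]
    return float(-np.sum(p * np.log(p) / math.log(base)))


def simpson(relative: np.ndarray) -> float:
    """Simpson dominance D = sum P_i^2; high D means few dominant bands."""
    p = _check_relative(relative)
    return float(np.sum(p**2))


def evenness(h_prime: float, r: int) -> float:
    """Pielou evenness J = H'/ln R; J = 1 for a single-band lane (H' = 0)."""
    if r < 1:
        raise ValueError("evenness undefined for richness 0")
    if r == 1:
        return 1.0
    return h_prime / math.log(r)


# ---------------------------------------------------------------------------
# pairwise comparisons


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rows must be 1-D with equal length")
    return a, b


def dice_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) on presence rows; 1 if both empty."""
    a, b = _check_pair(a, b)
    pa, pb = a > 0, b > 0
    denom = pa.sum() + pb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.sum(pa & pb) / denom)


def jaccard_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard coefficient |A∩B| / |A∪B| on presence rows; 1 if both empty."""
    a, b = _check_pair(a, b)
    pa, pb = a > 0, b > 0
    union = np.sum(pa | pb)
    if union == 0:
        return 1.0
    return float(np.sum(pa & pb) / union)


def bray_curtis(a: np.ndarray, b: np.ndarray) -> float:
    """Bray-Curtis dissimilarity 1 - 2 C_ij / (S_i + S_j).

    C_ij is the sum over shared species of the smaller abundance; S_i and S_j
    are the abundance totals of the two samples.
    """
    a, b = _check_pair(a, b)
    if a.min() < 0 or b.min() < 0:
        raise ValueError("abundances must be nonnegative")
    total = a.sum() + b.sum()
    if total == 0:
        raise ValueError("Bray-Curtis undefined for two empty samples")
    c = np.minimum(a, b).sum()
    return float(1.0 - 2.0 * c / total)
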