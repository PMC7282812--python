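"""Western-blot densitometry with total-protein lane normalization.

The protein content of a band is the signal mass (summed intensity above a
local background) inside a rectangle enclosing the band on the blot scan,
divided by a normalization factor computed on the source gel: the average
total-protein signal in a large area of the corresponding lane above its
own background, optionally excluding the molecular-weight range of the
proteins of interest.  Images are "positive" (light = signal) and handled
on their native 8/12/16-bit scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RectROI",
    "BandSignal",
    "NormalizedContent",
    "band_mass",
    "lane_normalization",
    "normalized_content",
    "linearity_check",
]


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangular region of interest, in pixel coordinates.

    ``excluded_y_range`` (y_lo, y_hi), half-open, removes a molecular-weight
    interval from lane averaging.
    """

    x0: int
    y0: int
    width: int
    height: int
    role: str = "band"  # band | background | lane | lane_background
    image_id: str = ""
    excluded_y_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI must have width, height >= 1")
        if self.role not in ("band", "background", "lane", "lane_background"):
            raise ValueError(f"unknown ROI role {self.role!r}")

    @property
    def n_pixels(self) -> int:
        return self.width * self.height

    def extract(self, image: np.ndarray) -> np.ndarray:
        ny, nx = image.shape
        if self.x0 < 0 or self.y0 < 0 or self.x0 + self.width > nx or self.y0 + self.height > ny:
            raise ValueError(
                f"ROI ({self.x0},{self.y0},{self.width},{self.height}) outside "
                f"image of shape {image.shape}"
            )
        return image[self.y0 : self.y0 + self.height, self.x0 : self.x0 + self.width]


@dataclass(frozen=True)
class BandSignal:
    """Background-subtracted integrated band signal."""

    signal_mass: float  # counts
    background_level: float  # mean counts/pixel in the background ROI
    n_pixels: int
    negative: bool = False  # mass came out below zero (not clamped)


@dataclass(frozen=True)
class NormalizedContent:
    """Band mass divided by the gel lane normalization factor."""

    value: float
    signal_mass: float
    lane_factor: float


def band_mass(blot_image: np.ndarray, band: RectROI, bg: RectROI) -> BandSignal:
    """Integrated band signal above the mean level of a background rectangle.

    signal_mass = sum(band pixels) - mean(background pixels) * n_band_pixels.
    Negative masses are reported, flagged, never clamped.
    """
    band_px = band.extract(np.asarray(blot_image, dtype=float))
    bg_px = bg.extract(np.asarray(blot_image, dtype=float))
    bg_level = float(bg_px.mean())
    mass = float(band_px.sum() - bg_level * band_px.size)
    return BandSignal(mass, bg_level, band_px.size, negative=mass < 0)


def lane_normalization(
    gel_image: np.ndarray,
    lane: RectROI,
    lane_bg: RectROI,
    excluded_y_range: tuple[int, int] | None = None,
) -> float:
    """Average total-protein signal in the lane above its background.

    ``excluded_y_range`` (absolute image rows, half-open) removes the
    molecular-weight region of the proteins of interest from the average.
    """
    gel = np.asarray(gel_image, dtype=float)
    lane_px = lane.extract(gel)
    excl = excluded_y_range if excluded_y_range is not None else lane.excluded_y_range
    if excl is not None:
        lo, hi = excl
        rows = np.arange(lane.y0, lane.y0 + lane.height)
        keep = (rows < lo) | (rows >= hi)
        if not keep.any():
            raise ValueError("exclusion interval removes every lane pixel")
        lane_px = lane_px[keep, :]
    factor = float(lane_px.mean() - lane_bg.extract(gel).mean())
    if factor <= 0:
        raise ValueError(
            f"non-positive lane normalization factor ({factor:.3g}) for lane ROI at "
            f"x0={lane.x0}"
        )
    return factor


def normalized_content(band: BandSignal, lane_factor: float) -> NormalizedContent:
    """Band signal mass divided by the lane's total-protein factor."""
    if lane_factor <= 0:
        raise ValueError("lane factor must be positive")
    return NormalizedContent(band.signal_mass / lane_factor, band.signal_mass, lane_factor)


def linearity_check(
    amounts: np.ndarray, values: np.ndarray
) -> tuple[float, float]:
    """Proportionality of measured content to loaded amount.

    Returns the least-squares slope of the line through the origin and the
    Pearson r.  r is returned as 0.0 (degenerate) when either series is
    constant.
    """
    amounts = np.asarray(amounts, dtype=float)
    values = np.asarray([v.value if isinstance(v, NormalizedContent) else v for v in values],
                        dtype=float)
    if amounts.size < 3 or values.size != amounts.size:
        raise ValueError("need >= 3 paired points")
    denom = float(np.dot(amounts, amounts))
    if denom == 0:
        raise ValueError("all amounts are zero")
    slope = float(np.dot(amounts, values) / denom)
    if np.ptp(values) == 0 or np.ptp(amounts) == 0:
        return slope, 0.0
    r = float(stats.pearsonr(amounts, values).statistic)
    return slope, r
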