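"""Digital image analysis (DIA) of power-Doppler still frames.

Power-Doppler instruments overlay saturated color-coded flow signal on a
grayscale B-mode image, so a pixel is classified as Doppler signal when its
chroma — ``max(R, G, B) − min(R, G, B)`` — strictly exceeds a threshold
(default 24 of 255). Gray pixels (R ≈ G ≈ B) are never color. The *color
fraction* (CF) is the share of pixels inside a manually selected region of
interest (the total lymph-node area) classified as color; the PD relative
signal of a video is the mean CF over its captured snapshots (canonically
three, taken at 5-second intervals).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DIAError",
    "PDFrame",
    "ColorFractionResult",
    "TrendReport",
    "DEFAULT_CHROMA_THRESHOLD",
    "classify_color_pixels",
    "color_fraction",
    "pd_relative_signal",
    "grade_signal_monotonicity",
    "polygon_to_mask",
]

DEFAULT_CHROMA_THRESHOLD = 24


class DIAError(ValueError):
    """Raised for unusable frames or regions of interest."""


@dataclass
class PDFrame:
    """One power-Doppler snapshot: 8-bit RGB raster plus its ROI mask."""

    pixels: np.ndarray
    roi_mask: np.ndarray
    frame_index: int = 0
    nominal_grade: Optional[int] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise DIAError(f"pixels must be an (H, W, 3) raster, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise DIAError(f"pixels must be 8-bit per channel (uint8), got {px.dtype}")
        mask = np.asarray(self.roi_mask).astype(bool)
        if mask.shape != px.shape[:2]:
            raise DIAError(
                f"roi_mask shape {mask.shape} does not match raster {px.shape[:2]}"
            )
        self.pixels = px
        self.roi_mask = mask


@dataclass(frozen=True)
class ColorFractionResult:
    color_pixels: int
    roi_pixels: int

    @property
    def fraction(self) -> float:
        return self.color_pixels / self.roi_pixels


@dataclass(frozen=True)
class TrendReport:
    """Per-grade mean color fractions and a Kruskal-Wallis test across grades."""

    grade_means: Dict[int, float]
    kruskal_statistic: float
    p_value: float
    monotone: bool


def classify_color_pixels(
    frame: PDFrame | np.ndarray, chroma_threshold: int = DEFAULT_CHROMA_THRESHOLD
) -> np.ndarray:
    """Binary raster of pixels classified as Doppler color signal.

    A pixel is color iff its chroma ``max(R,G,B) − min(R,G,B)`` is *strictly*
    greater than ``chroma_threshold``; a pixel exactly at the threshold is not
    color. The rule is invariant to adding a constant to all three channels
    (up to clipping), so overall image brightness does not matter.
    """
    pixels = frame.pixels if isinstance(frame, PDFrame) else np.asarray(frame)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise DIAError(f"expected an (H, W, 3) raster, got shape {pixels.shape}")
    if pixels.dtype != np.uint8:
        raise DIAError(f"expected an 8-bit raster (uint8), got {pixels.dtype}")
    chroma = pixels.max(axis=2).astype(np.int16) - pixels.min(axis=2).astype(np.int16)
    return chroma > chroma_threshold


def color_fraction(
    frame: PDFrame,
    chroma_threshold: int = DEFAULT_CHROMA_THRESHOLD,
) -> ColorFractionResult:
    """Color fraction inside the frame's ROI: (# color pixels in ROI) / (# ROI pixels).

    Pixels outside the ROI are ignored entirely. An empty ROI makes the frame
    unusable and raises :class:`DIAError`.
    """
    roi = frame.roi_mask
    roi_pixels = int(roi.sum())
    if roi_pixels == 0:
        raise DIAError("empty ROI: frame is unusable for quantification")
    color = classify_color_pixels(frame, chroma_threshold)
    return ColorFractionResult(
        color_pixels=int((color & roi).sum()), roi_pixels=roi_pixels
    )


def pd_relative_signal(
    frames: Sequence[PDFrame],
    chroma_threshold: int = DEFAULT_CHROMA_THRESHOLD,
) -> float:
    """Mean color fraction over a video's snapshots (each with its own ROI)."""
    frames = list(frames)
    if not frames:
        raise DIAError("pd_relative_signal requires at least one frame")
    fractions = [color_fraction(f, chroma_threshold).fraction for f in frames]
    return float(np.mean(fractions))


def grade_signal_monotonicity(
    frames_by_grade: Dict[int, Sequence[PDFrame]],
    chroma_threshold: int = DEFAULT_CHROMA_THRESHOLD,
) -> TrendReport:
    """Relate DIA color fractions to the semiquantitative PD grade.

    Computes the per-grade mean fraction, a Kruskal-Wallis test across the
    grade groups, and a flag for whether group means are nondecreasing with
    grade (the expected behaviour when the ordinal grading discriminates
    underlying vascularity).
    """
    if len(frames_by_grade) < 2:
        raise DIAError("need at least two grade groups")
    groups = {}
    for grade in sorted(frames_by_grade):
        fracs = [color_fraction(f, chroma_threshold).fraction for f in frames_by_grade[grade]]
        if len(fracs) < 2:
            raise DIAError(f"grade {grade}: need at least two frames per group")
        groups[int(grade)] = fracs
    stat, p = stats.kruskal(*groups.values())
    means = {g: float(np.mean(v)) for g, v in groups.items()}
    ordered = [means[g] for g in sorted(means)]
    monotone = all(b >= a for a, b in zip(ordered, ordered[1:]))
    return TrendReport(
        grade_means=means,
        kruskal_statistic=float(stat),
        p_value=float(p),
        monotone=monotone,
    )


def polygon_to_mask(vertices: Iterable[tuple], shape: tuple) -> np.ndarray:
    """Rasterize a closed ROI polygon into a boolean mask.

    ``vertices`` are (x, y) pixel coordinates, origin top-left, 0-based;
    classification is by pixel centers. ``shape`` is the (H, W) raster shape.
    """
    from skimage.draw import polygon2mask

    pts = np.asarray(list(vertices), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise DIAError("polygon needs at least three (x, y) vertices")
    # polygon2mask expects (row, col) = (y, x)
    return polygon2mask(tuple(shape), pts[:, ::-1])
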