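"""Morphometry of signal-void luminal structures (Schlemm's canal, aqueous vein).

Both SC and the aqueous vein appear in label-free two-photon sections as
autofluorescence voids at a known anatomical position.  A lumen is detected
as the largest below-threshold 8-connected component inside an ROI; its size
is measured as the mean of several chord lengths through the centroid at
uniformly spaced orientations — a deterministic surrogate for repeated
manual caliper measurements ("measured five times, then averaged").
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    DegenerateImageError,
    InvalidRangeError,
    NoLumenFoundError,
    NonConvexLumenWarning,
)
from .porosity import RegionOfInterest, enhance, histogram_threshold
from .stack import ImageStack

#: Rejection floor for noise specks: area of a 10 μm-diameter circle (μm²),
#: smaller than any lumen reported for the rat outflow pathway.
MIN_LUMEN_AREA_UM2 = math.pi * 5.0**2

#: A genuine signal void is far darker than the surrounding collagen.  When
#: the below-threshold class of an auto-thresholded ROI has a mean above
#: this fraction of the bright-class mean, the split is just noise on a
#: unimodal patch and no lumen is present.
VOID_CONTRAST_RATIO = 0.25

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass
class LumenRegion:
    """One detected lumen cross-section (mask in ROI-crop coordinates)."""

    depth_um: float
    mask: np.ndarray
    centroid: tuple[float, float]  # (row, col), px, within the crop
    area_px: int


@dataclass
class DiameterEntry:
    depth_um: float
    repeats_um: list[float]
    mean_diameter_um: float


@dataclass
class DiameterProfile:
    """Per-depth mean diameters with their individual chord repeats."""

    entries: list[DiameterEntry]
    missing: list[tuple[float, str]] = field(default_factory=list)

    @property
    def depths(self) -> np.ndarray:
        return np.array([e.depth_um for e in self.entries])

    @property
    def means(self) -> np.ndarray:
        return np.array([e.mean_diameter_um for e in self.entries])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {"depth_um": e.depth_um, "found": True}
            row.update(
                {f"repeat_{i + 1}": r for i, r in enumerate(e.repeats_um)}
            )
            row["mean_diameter_um"] = e.mean_diameter_um
            rows.append(row)
        for depth, reason in self.missing:
            rows.append({"depth_um": depth, "found": False, "reason": reason})
        return pd.DataFrame(rows).sort_values("depth_um", ignore_index=True)


# ---------------------------------------------------------------------------
# Detection and measurement
# ---------------------------------------------------------------------------

def detect_lumen(
    image: np.ndarray,
    roi: RegionOfInterest | None,
    threshold: float,
    *,
    pitch_um: float,
    depth_um: float = 0.0,
    min_area_um2: float = MIN_LUMEN_AREA_UM2,
) -> LumenRegion:
    """Largest below-threshold 8-connected component inside the ROI.

    Parameters
    ----------
    image
        2D intensity slice (full frame; the ROI box is applied here).
    roi
        In-plane box to search; ``None`` searches the whole slice.
    threshold
        Intensity below which a pixel counts as signal void.
    pitch_um
        Lateral pixel pitch, used to convert the area floor to pixels.
    min_area_um2
        Components smaller than this are treated as noise specks.
    """
    image = np.asarray(image)
    if roi is not None:
        crop = image[roi.row0: roi.row1, roi.col0: roi.col1]
    else:
        crop = image
    dark = crop < threshold
    lab, n = ndimage.label(dark, structure=_EIGHT_CONNECTED)
    if n == 0:
        raise NoLumenFoundError("no below-threshold component in ROI")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    min_px = min_area_um2 / pitch_um**2
    if sizes.max() < min_px:
        raise NoLumenFoundError(
            f"largest dark component ({sizes.max():.0f} px) below the "
            f"{min_px:.0f} px area floor"
        )
    best = int(np.argmax(sizes)) + 1
    mask = lab == best
    centroid = ndimage.center_of_mass(mask)
    return LumenRegion(
        depth_um=depth_um,
        mask=mask,
        centroid=(float(centroid[0]), float(centroid[1])),
        area_px=int(mask.sum()),
    )


def _chord_length_px(mask: np.ndarray, centroid: tuple[float, float],
                     theta: float, step: float = 0.25) -> float:
    """Extent of the mask along the line through the centroid at angle theta.

    The line is sampled at sub-pixel steps with nearest-neighbour lookup;
    the chord is the distance between the extreme in-mask samples.  Nearest
    pixel lookup already extends half a pixel beyond the extreme pixel
    centres on each side, so no extra width correction is applied.
    """
    nr, nc = mask.shape
    drow, dcol = math.sin(theta), math.cos(theta)
    t_max = math.hypot(nr, nc)
    ts = np.arange(-t_max, t_max + step, step)
    rows = np.rint(centroid[0] + ts * drow).astype(int)
    cols = np.rint(centroid[1] + ts * dcol).astype(int)
    ok = (rows >= 0) & (rows < nr) & (cols >= 0) & (cols < nc)
    hit = np.zeros_like(ts, dtype=bool)
    hit[ok] = mask[rows[ok], cols[ok]]
    if not hit.any():
        return 0.0
    t_in = ts[hit]
    return float(t_in.max() - t_in.min())


def measure_diameter(
    region: LumenRegion,
    *,
    pitch_um: float,
    n_repeats: int = 5,
) -> tuple[list[float], float]:
    """Chord lengths through the centroid at ``n_repeats`` orientations.

    Orientations are uniformly spaced at 0, π/n, 2π/n, …; each repeat is the
    extent of the mask along that direction through the centroid, in μm.
    Returns ``(repeats, mean)`` with the mean the exact arithmetic average.
    A centroid outside the mask (non-convex lumen) raises a warning; chords
    are measured anyway.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if region.area_px <= 0:
        raise NoLumenFoundError("empty lumen region")
    r, c = int(round(region.centroid[0])), int(round(region.centroid[1]))
    nr, nc = region.mask.shape
    if not (0 <= r < nr and 0 <= c < nc) or not region.mask[r, c]:
        warnings.warn(
            "lumen centroid falls outside the mask; chords measured anyway",
            NonConvexLumenWarning,
            stacklevel=2,
        )
    repeats = [
        _chord_length_px(region.mask, region.centroid, i * math.pi / n_repeats)
        * pitch_um
        for i in range(n_repeats)
    ]
    return repeats, float(np.mean(repeats))


def diameter_profile(
    stack: ImageStack,
    roi: RegionOfInterest,
    depth_range: tuple[float, float] | None = None,
    *,
    n_repeats: int = 5,
    threshold: float | None = None,
    min_area_um2: float = MIN_LUMEN_AREA_UM2,
) -> DiameterProfile:
    """Detect and size the lumen on every slice of a depth window.

    Per slice: percentile enhancement, Otsu threshold (unless ``threshold``
    is supplied), largest-dark-component detection, ``n_repeats``-chord
    diameter.  Slices with no acceptable lumen are recorded as missing with
    the reason.  Entries come out sorted by depth.
    """
    lo, hi = depth_range if depth_range is not None else (
        roi.depth_min_um, roi.depth_max_um)
    if hi < lo:
        raise InvalidRangeError(f"empty depth range [{lo}, {hi}]")
    depths = stack.depths
    sel = np.flatnonzero((depths >= lo - 1e-6) & (depths <= hi + 1e-6))
    if len(sel) == 0:
        raise InvalidRangeError(
            f"depth range [{lo}, {hi}] μm contains no slice of the stack")
    roi.validate(stack)

    entries: list[DiameterEntry] = []
    missing: list[tuple[float, str]] = []
    for k in sel:
        depth = stack.depth_of(int(k))
        crop_view = stack.intensities[k]
        try:
            enhanced_crop = enhance(
                crop_view[roi.row0: roi.row1, roi.col0: roi.col1])
            if threshold is not None:
                thr = threshold
            else:
                thr = histogram_threshold(enhanced_crop)
                dark = enhanced_crop[enhanced_crop < thr]
                bright = enhanced_crop[enhanced_crop >= thr]
                if (len(dark) == 0 or len(bright) == 0
                        or dark.mean() > VOID_CONTRAST_RATIO * bright.mean()):
                    raise NoLumenFoundError(
                        "ROI lacks signal-void contrast (no lumen present)")
            # detection operates on the enhanced crop directly
            region = detect_lumen(
                enhanced_crop, None, thr,
                pitch_um=stack.lateral_pitch, depth_um=depth,
                min_area_um2=min_area_um2,
            )
            repeats, mean = measure_diameter(
                region, pitch_um=stack.lateral_pitch, n_repeats=n_repeats)
        except (NoLumenFoundError, DegenerateImageError) as err:
            missing.append((depth, str(err)))
            continue
        entries.append(DiameterEntry(
            depth_um=depth, repeats_um=repeats, mean_diameter_um=mean))
    entries.sort(key=lambda e: e.depth_um)
    return DiameterProfile(entries=entries, missing=missing)


# ---------------------------------------------------------------------------
# Default measurement ROIs for the calibrated synthetic presets
# ---------------------------------------------------------------------------

def default_sc_roi() -> RegionOfInterest:
    """Box around Schlemm's canal in the default presets (depths 190–215 μm)."""
    return RegionOfInterest(row0=196, row1=316, col0=330, col1=450,
                            depth_min_um=190.0, depth_max_um=215.0)


def default_vein_roi() -> RegionOfInterest:
    """Box around the aqueous-vein trunk in the default presets (95–120 μm)."""
    return RegionOfInterest(row0=115, row1=185, col0=385, col1=455,
                            depth_min_um=95.0, depth_max_um=120.0)
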