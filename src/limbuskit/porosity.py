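"""Depth-resolved trabecular-meshwork porosity from optical-section stacks.

Pipeline per slice: crop the valid TM region → percentile contrast stretch →
gray-histogram (Otsu) threshold → pores are the below-threshold (signal-void)
class → porosity = pore pixels / valid pixels.  One threshold per slice so
that depth-dependent signal attenuation is absorbed by the enhancement and
thresholding rather than biasing the pore fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateImageError, InvalidROIError
from .stack import ImageStack

_DEPTH_EPS = 1e-6


@dataclass(frozen=True)
class RegionOfInterest:
    """Axis-aligned box (half-open row/col bounds) over a depth window (μm).

    The same in-plane box applies to every slice whose depth lies in
    ``[depth_min_um, depth_max_um]`` (inclusive).
    """

    row0: int
    row1: int
    col0: int
    col1: int
    depth_min_um: float
    depth_max_um: float

    def validate(self, stack: ImageStack) -> None:
        _, nr, nc = stack.shape
        if not (0 <= self.row0 < self.row1 <= nr and 0 <= self.col0 < self.col1 <= nc):
            raise InvalidROIError(
                f"ROI box ({self.row0}:{self.row1}, {self.col0}:{self.col1}) "
                f"outside image bounds ({nr}, {nc})"
            )
        if self.depth_min_um > self.depth_max_um:
            raise InvalidROIError("depth_min_um exceeds depth_max_um")
        if not len(self.slice_indices(stack)):
            raise InvalidROIError(
                f"depth window [{self.depth_min_um}, {self.depth_max_um}] μm "
                "contains no slice of the stack"
            )

    def slice_indices(self, stack: ImageStack) -> np.ndarray:
        depths = stack.depths
        sel = (depths >= self.depth_min_um - _DEPTH_EPS) & (
            depths <= self.depth_max_um + _DEPTH_EPS
        )
        return np.flatnonzero(sel)

    @classmethod
    def from_tm_roi(cls, config) -> "RegionOfInterest":
        """ROI matching a :class:`SyntheticSceneConfig`'s TM box."""
        (s0, s1), (r0, r1), (c0, c1) = config.tm_roi
        return cls(
            row0=r0, row1=r1, col0=c0, col1=c1,
            depth_min_um=config.depth_of(s0),
            depth_max_um=config.depth_of(s1 - 1),
        )


@dataclass
class PorosityEntry:
    depth_um: float
    porosity: float
    threshold: float
    pore_pixels: int
    valid_pixels: int


@dataclass
class PorosityProfile:
    """Per-depth porosity measurements plus any slices that failed."""

    entries: list[PorosityEntry]
    missing: list[tuple[float, str]] = field(default_factory=list)

    @property
    def depths(self) -> np.ndarray:
        return np.array([e.depth_um for e in self.entries])

    @property
    def porosities(self) -> np.ndarray:
        return np.array([e.porosity for e in self.entries])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "depth_um": e.depth_um,
                    "porosity": e.porosity,
                    "threshold": e.threshold,
                    "pore_pixels": e.pore_pixels,
                    "valid_pixels": e.valid_pixels,
                }
                for e in self.entries
            ]
        )


# ---------------------------------------------------------------------------
# Pipeline steps
# ---------------------------------------------------------------------------

def crop_valid(stack: ImageStack, roi: RegionOfInterest) -> ImageStack:
    """Crop the valid TM region; pitch preserved, depth origin adjusted."""
    roi.validate(stack)
    idx = roi.slice_indices(stack)
    sub = stack.intensities[idx[0]: idx[-1] + 1, roi.row0: roi.row1, roi.col0: roi.col1]
    return ImageStack(
        intensities=sub,
        lateral_pitch=stack.lateral_pitch,
        axial_step=stack.axial_step,
        depth_origin=stack.depth_of(int(idx[0])),
    )


def enhance(image: np.ndarray) -> np.ndarray:
    """Linear contrast stretch of the [p1, p99] window onto [0, 1].

    Strictly monotone on the non-clipped range, so pixel ordering (and hence
    any rank-based threshold) is preserved.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise DegenerateImageError("empty image")
    lo, hi = np.percentile(image, [1.0, 99.0])
    if hi <= lo:
        raise DegenerateImageError("image has (near-)constant intensity")
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def histogram_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Gray-histogram threshold maximizing between-class variance (Otsu).

    The histogram spans ``[min, max]`` with ``nbins`` bins; the returned
    threshold is the bin edge after the best cut, so it is strictly between
    the minimum and maximum intensity.  Ties break toward the lower cut.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise DegenerateImageError("empty image")
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        raise DegenerateImageError("image needs >= 2 distinct values")
    hist, edges = np.histogram(image, bins=nbins, range=(lo, hi))
    hist = hist.astype(np.float64)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    m0 = np.cumsum(hist * centers)
    m1 = m0[-1] - m0
    # between-class variance for a cut after each bin (last cut excluded)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0[:-1] / w0[:-1]
        mu1 = m1[:-1] / w1[:-1]
        var_b = w0[:-1] * w1[:-1] * (mu0 - mu1) ** 2
    var_b = np.where(np.isfinite(var_b), var_b, -np.inf)
    best = int(np.argmax(var_b))  # first max -> lower cut on ties
    return float(edges[best + 1])


def segment_pores(image: np.ndarray, threshold: float) -> np.ndarray:
    """Binary pore mask: pores are the strictly-below-threshold voids."""
    return np.asarray(image) < threshold


def porosity_profile(stack: ImageStack, roi: RegionOfInterest) -> PorosityProfile:
    """Crop → enhance → threshold → segment → area-ratio porosity, per slice.

    Slices on which no threshold exists (degenerate contrast) are recorded in
    ``missing`` with the reason instead of failing the whole profile.
    """
    sub = crop_valid(stack, roi)
    entries: list[PorosityEntry] = []
    missing: list[tuple[float, str]] = []
    for k in range(sub.n_slices):
        depth = sub.depth_of(k)
        try:
            enhanced = enhance(sub.intensities[k])
            thr = histogram_threshold(enhanced)
        except DegenerateImageError as err:
            missing.append((depth, str(err)))
            continue
        mask = segment_pores(enhanced, thr)
        pore = int(mask.sum())
        valid = int(mask.size)
        entries.append(
            PorosityEntry(
                depth_um=depth,
                porosity=pore / valid,
                threshold=thr,
                pore_pixels=pore,
                valid_pixels=valid,
            )
        )
    return PorosityProfile(entries=entries, missing=missing)
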