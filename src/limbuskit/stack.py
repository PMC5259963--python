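"""Image-stack and label-volume containers with TIFF + JSON sidecar I/O.

An :class:`ImageStack` is a 3D intensity volume acquired as serial optical
sections.  Axis order is ``(slice, row, col)``; the physical depth of slice
``k`` below the eye surface is ``depth_origin + k * axial_step`` (the surface
itself is depth 0).  A :class:`LabelVolume` carries voxel-aligned semantic
ground truth for synthetic scenes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

# Semantic label ids used throughout the package.
BACKGROUND = 0
CORNEA = 1
SCLERA = 2
TM_BEAM = 3
TM_PORE = 4
SC_LUMEN = 5
VEIN_LUMEN = 6

LABEL_LEGEND: dict[int, str] = {
    BACKGROUND: "background",
    CORNEA: "cornea",
    SCLERA: "sclera",
    TM_BEAM: "tm_beam",
    TM_PORE: "tm_pore",
    SC_LUMEN: "sc_lumen",
    VEIN_LUMEN: "vein_lumen",
}

#: Labels that contain collagen and therefore produce signal under SHG/2PAF.
COLLAGEN_LABELS = (CORNEA, SCLERA, TM_BEAM)
#: Fluid-filled labels that appear as signal voids.
VOID_LABELS = (TM_PORE, SC_LUMEN, VEIN_LUMEN)


@dataclass
class ImageStack:
    """3D non-negative intensity volume with physical voxel pitch.

    Parameters
    ----------
    intensities
        Array of shape ``(slices, rows, cols)``, non-negative and finite.
    lateral_pitch
        In-plane pixel pitch, μm/pixel.
    axial_step
        Distance between consecutive slices, μm.
    depth_origin
        Depth of slice 0 below the eye surface, μm.
    """

    intensities: np.ndarray
    lateral_pitch: float
    axial_step: float
    depth_origin: float = 0.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be 3D (slices, rows, cols)")
        if self.lateral_pitch <= 0 or self.axial_step <= 0:
            raise ValueError("voxel pitches must be positive")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    def depth_of(self, k: int) -> float:
        """Physical depth (μm) of slice ``k`` below the eye surface."""
        return self.depth_origin + k * self.axial_step

    @property
    def depths(self) -> np.ndarray:
        """Depths (μm) of every slice."""
        return self.depth_origin + self.axial_step * np.arange(self.n_slices)


@dataclass
class LabelVolume:
    """Voxel-aligned semantic labels with the same geometry as a stack."""

    labels: np.ndarray
    lateral_pitch: float
    axial_step: float
    depth_origin: float = 0.0
    legend: dict[int, str] = field(default_factory=lambda: dict(LABEL_LEGEND))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D (slices, rows, cols)")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"legend does not cover label ids {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def depths(self) -> np.ndarray:
        return self.depth_origin + self.axial_step * np.arange(self.labels.shape[0])

    def mask(self, *label_ids: int) -> np.ndarray:
        """Boolean volume that is True where the voxel has any given label."""
        return np.isin(self.labels, label_ids)


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF + JSON metadata sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(tiff_path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as 16-bit multi-page TIFF plus a JSON metadata sidecar.

    Intensities are rounded and clipped to the uint16 range; metadata
    (pitches, depth origin) goes to ``<path>.json``.
    """
    path = Path(path)
    data = np.clip(np.round(stack.intensities), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, data.astype(np.uint16))
    meta = {
        "lateral_pitch_um": stack.lateral_pitch,
        "axial_step_um": stack.axial_step,
        "depth_origin_um": stack.depth_origin,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a stack written by :func:`write_stack`."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta = json.loads(_sidecar_path(path).read_text())
    return ImageStack(
        intensities=data.astype(np.float64),
        lateral_pitch=meta["lateral_pitch_um"],
        axial_step=meta["axial_step_um"],
        depth_origin=meta["depth_origin_um"],
    )


def write_labels(labels: LabelVolume, path: str | Path) -> Path:
    """Write labels as 8-bit multi-page TIFF plus legend/metadata JSON."""
    path = Path(path)
    tifffile.imwrite(path, labels.labels.astype(np.uint8))
    meta = {
        "lateral_pitch_um": labels.lateral_pitch,
        "axial_step_um": labels.axial_step,
        "depth_origin_um": labels.depth_origin,
        "legend": {str(k): v for k, v in labels.legend.items()},
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_labels(path: str | Path) -> LabelVolume:
    """Read labels written by :func:`write_labels`."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta = json.loads(_sidecar_path(path).read_text())
    return LabelVolume(
        labels=data.astype(np.int64),
        lateral_pitch=meta["lateral_pitch_um"],
        axial_step=meta["axial_step_um"],
        depth_origin=meta["depth_origin_um"],
        legend={int(k): v for k, v in meta["legend"].items()},
    )
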