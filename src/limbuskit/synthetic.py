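"""Synthetic two-photon image stacks of the limbal drainage pathway.

The conventional aqueous-humor outflow pathway at the limbus — trabecular
meshwork (TM), Schlemm's canal (SC) and aqueous vein — shows up in label-free
two-photon imaging as bright collagen (cornea, sclera, TM beams) and dark
fluid-filled voids (TM pores, SC lumen, vein lumen).  This module builds 3D
scenes with voxel-exact ground truth:

* a porous TM band between cornea (left) and sclera (right) whose per-slice
  pore fraction follows a depth-interpolated porosity profile exactly,
* an elliptical signal-void SC beneath the sclera with depth-varying diameter,
* an aqueous vein (trunk + smaller branch) near the surface,
* an imaging model with depth attenuation, anisotropic Gaussian PSF, Poisson
  photon noise and Gaussian read noise.

The default configurations are calibrated to the measured ranges of the rat
eye study this package reanalyzes: intact-eye TM porosity rising 0.63 → 0.74
over depths 185–215 μm (0.44 → 0.59 after depressurization / high IOP), SC
diameter 48 → 64.67 μm with its 64.67 μm maximum at 207 μm depth, and vein
diameters 32–43 μm over depths 95–120 μm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import InfeasibleGeometryError
from .stack import (
    CORNEA,
    SC_LUMEN,
    SCLERA,
    TM_BEAM,
    TM_PORE,
    VEIN_LUMEN,
    ImageStack,
    LabelVolume,
)

#: Relative SHG/2PAF signal strength per tissue class at zero depth.
DEFAULT_REFLECTANCE = {CORNEA: 0.85, SCLERA: 1.0, TM_BEAM: 1.0}

#: Tolerance to which build_labels realizes the per-slice porosity target.
POROSITY_TOLERANCE = 0.02

#: Documented default seed of the calibrated presets.
DEFAULT_SEED = 20161228


@dataclass
class SyntheticSceneConfig:
    """Full description of a synthetic limbal scene.

    Geometry is voxel-indexed as ``(slice, row, col)``; depths and diameters
    are in μm.  ``tm_roi`` is ``((s0, s1), (r0, r1), (c0, c1))`` with
    half-open bounds.  ``porosity_profile`` holds ``(depth_um, porosity)``
    knots, linearly interpolated (clamped outside the knot range).
    ``sc_axis_path`` holds ``(depth_um, row, col, major_um, minor_um)`` knots
    of the SC lumen ellipse; ``vein_path`` and ``vein_branch`` hold
    ``(depth_um, row, col, diameter_um)`` polyline nodes of circular lumen
    cross-sections.  A structure exists only within the depth span of its
    knots.
    """

    stack_shape: tuple[int, int, int]
    lateral_pitch: float
    axial_step: float
    depth_origin: float
    tm_roi: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    porosity_profile: list[tuple[float, float]]
    sc_axis_path: list[tuple[float, float, float, float, float]]
    vein_path: list[tuple[float, float, float, float]]
    vein_branch: list[tuple[float, float, float, float]] = field(default_factory=list)
    beam_thickness_mean: float = 10.0
    noise: dict[str, float] = field(
        default_factory=lambda: {"photon_scale": 800.0, "read_sigma": 3.0}
    )
    attenuation_length: float = 150.0
    psf_sigma: tuple[float, float] = (1.0, 2.0)  # (lateral, axial) μm
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        ns, nr, nc = self.stack_shape
        if self.lateral_pitch <= 0 or self.axial_step <= 0:
            raise ValueError("voxel pitches must be positive")
        (s0, s1), (r0, r1), (c0, c1) = self.tm_roi
        if not (0 <= s0 < s1 <= ns and 0 <= r0 < r1 <= nr and 0 <= c0 < c1 <= nc):
            raise ValueError("tm_roi must fit inside stack_shape")
        depths = [d for d, _ in self.porosity_profile]
        if any(d2 <= d1 for d1, d2 in zip(depths, depths[1:])):
            raise ValueError("porosity knot depths must be strictly increasing")
        if any(not 0.0 <= p <= 1.0 for _, p in self.porosity_profile):
            raise ValueError("porosity knot values must lie in [0, 1]")
        for _, _, _, major, minor in self.sc_axis_path:
            if major <= 0 or minor <= 0:
                raise ValueError("SC diameters must be positive")
        for path in (self.vein_path, self.vein_branch):
            if any(d <= 0 for *_xyz, d in path):
                raise ValueError("vein diameters must be positive")
        if self.attenuation_length <= 0 or self.beam_thickness_mean <= 0:
            raise ValueError("attenuation_length and beam_thickness_mean must be positive")

    # -- geometry helpers ---------------------------------------------------

    def depth_of(self, k: int) -> float:
        return self.depth_origin + k * self.axial_step

    @property
    def depths(self) -> np.ndarray:
        return self.depth_origin + self.axial_step * np.arange(self.stack_shape[0])

    def porosity_at(self, depth_um: float | np.ndarray) -> np.ndarray:
        knots_d = np.array([d for d, _ in self.porosity_profile])
        knots_p = np.array([p for _, p in self.porosity_profile])
        return np.interp(depth_um, knots_d, knots_p)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSceneConfig":
        raw = json.loads(Path(path).read_text())
        raw["stack_shape"] = tuple(raw["stack_shape"])
        raw["tm_roi"] = tuple(tuple(b) for b in raw["tm_roi"])
        raw["psf_sigma"] = tuple(raw["psf_sigma"])
        for key in ("porosity_profile", "sc_axis_path", "vein_path", "vein_branch"):
            raw[key] = [tuple(k) for k in raw[key]]
        return cls(**raw)


def _interp_path(path: list[tuple], depth: float) -> tuple | None:
    """Linearly interpolate a per-depth knot path; None outside its span."""
    depths = [k[0] for k in path]
    if not path or depth < depths[0] - 1e-9 or depth > depths[-1] + 1e-9:
        return None
    cols = list(zip(*path))
    return tuple(float(np.interp(depth, depths, c)) for c in cols[1:])


# ---------------------------------------------------------------------------
# Default (calibrated) configurations
# ---------------------------------------------------------------------------

def default_intact_config() -> SyntheticSceneConfig:
    """Calibrated scene of the intact (normal-IOP) eye.

    The stack spans depths 90–220 μm in 5 μm steps (27 slices of 512×512 px
    at 2 μm/px) so that the TM window (185–215 μm), the SC window
    (190–215 μm) and the vein window (95–120 μm) coexist in one acquisition.
    TM porosity knots run 0.63 at 185 μm to 0.74 at 215 μm; the SC diameter
    profile rises from 48 μm at 190 μm depth to its 64.67 μm maximum at
    207 μm and falls off toward 215 μm; vein trunk diameters run 32 μm at
    95 μm depth to 43 μm at 120 μm, with a thinner branch diverging from the
    trunk below 104 μm depth.
    """
    return SyntheticSceneConfig(
        stack_shape=(27, 512, 512),
        lateral_pitch=2.0,
        axial_step=5.0,
        depth_origin=90.0,
        # slices 19..25 are depths 185..215 μm; cols 192..320 are the TM band
        tm_roi=((19, 26), (64, 448), (192, 320)),
        porosity_profile=[(185.0, 0.63), (215.0, 0.74)],
        sc_axis_path=[
            (190.0, 256.0, 390.0, 48.0, 48.0),
            (204.0, 256.0, 390.0, 64.0, 64.0),
            (207.0, 256.0, 390.0, 64.67, 64.67),
            (210.0, 256.0, 390.0, 64.0, 64.0),
            (215.0, 256.0, 390.0, 58.0, 58.0),
        ],
        vein_path=[(95.0, 150.0, 420.0, 32.0), (120.0, 150.0, 420.0, 43.0)],
        vein_branch=[(100.0, 150.0, 420.0, 18.0), (120.0, 186.0, 420.0, 18.0)],
        seed=DEFAULT_SEED,
    )


def default_broken_config() -> SyntheticSceneConfig:
    """Calibrated scene of the depressurized ("broken") / high-IOP eye.

    Identical geometry and seed to :func:`default_intact_config`; only the
    porosity knots differ (0.44 → 0.59), reflecting TM collapse once the
    IOP–EVP force balance is lost.
    """
    cfg = default_intact_config()
    cfg.porosity_profile = [(185.0, 0.44), (215.0, 0.59)]
    return cfg


#: The study's Abstract calls the second group "high IOP" while its Methods
#: describe a depressurized ("broken") eye; both names map to the same preset.
default_high_iop_config = default_broken_config


# ---------------------------------------------------------------------------
# Label volume construction
# ---------------------------------------------------------------------------

def _paint_disc(labels_slice: np.ndarray, row: float, col: float,
                a_px: float, b_px: float, label: int) -> None:
    """Paint an axis-aligned ellipse (semi-axes in px: a along cols, b rows)."""
    nr, nc = labels_slice.shape
    r0 = max(int(math.floor(row - b_px)) - 1, 0)
    r1 = min(int(math.ceil(row + b_px)) + 2, nr)
    c0 = max(int(math.floor(col - a_px)) - 1, 0)
    c1 = min(int(math.ceil(col + a_px)) + 2, nc)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = ((cc - col) / a_px) ** 2 + ((rr - row) / b_px) ** 2 <= 1.0
    labels_slice[r0:r1, c0:c1][inside] = label


def build_labels(config: SyntheticSceneConfig) -> LabelVolume:
    """Voxelize the scene into a ground-truth label volume.

    The TM band microstructure is carved from spatially correlated Gaussian
    noise (correlation length = ``beam_thickness_mean``): per slice, the
    threshold is placed at the order statistic matching the interpolated
    porosity target, so the realized pore fraction is exact to one voxel.
    Deterministic given ``config.seed``.

    Raises
    ------
    InfeasibleGeometryError
        If the TM ROI cross-section is too small to realize the porosity
        target within ±0.02 at the configured beam thickness.
    """
    config.validate()
    ns, nr, nc = config.stack_shape
    (s0, s1), (r0, r1), (c0, c1) = config.tm_roi
    n_pix = (r1 - r0) * (c1 - c0)
    sigma_lat = config.beam_thickness_mean / config.lateral_pitch
    if n_pix < 1.0 / POROSITY_TOLERANCE * 10 or min(r1 - r0, c1 - c0) < 4 * sigma_lat:
        raise InfeasibleGeometryError(
            f"TM ROI cross-section {(r1 - r0)}x{(c1 - c0)} px is too small to "
            f"realize porosity within ±{POROSITY_TOLERANCE} at beam thickness "
            f"{config.beam_thickness_mean} μm"
        )

    labels = np.empty((ns, nr, nc), dtype=np.uint8)
    band_mid = (c0 + c1) // 2
    labels[:, :, :c0] = CORNEA
    labels[:, :, c1:] = SCLERA
    # outside the TM depth window the band is plain limbal stroma
    labels[:, :, c0:band_mid] = CORNEA
    labels[:, :, band_mid:c1] = SCLERA

    # -- TM microstructure: correlated noise + per-slice quantile threshold --
    rng = np.random.default_rng(config.seed)
    field3d = rng.standard_normal((s1 - s0, r1 - r0, c1 - c0))
    sigma_ax = config.beam_thickness_mean / config.axial_step
    field3d = gaussian_filter(field3d, sigma=(sigma_ax, sigma_lat, sigma_lat))
    for k in range(s0, s1):
        target = float(config.porosity_at(config.depth_of(k)))
        fslice = field3d[k - s0]
        flat = fslice.ravel()
        n_pore = int(round(target * flat.size))
        band = np.full(fslice.shape, TM_BEAM, dtype=np.uint8)
        if n_pore >= flat.size:
            band[:] = TM_PORE
        elif n_pore > 0:
            thr = np.partition(flat, n_pore)[n_pore]
            band[fslice < thr] = TM_PORE
        labels[k, r0:r1, c0:c1] = band

    # -- SC and aqueous vein lumina ----------------------------------------
    half_lat = 2.0 * config.lateral_pitch
    for k in range(ns):
        depth = config.depth_of(k)
        sc = _interp_path(config.sc_axis_path, depth)
        if sc is not None:
            row, col, major, minor = sc
            _paint_disc(labels[k], row, col,
                        major / half_lat, minor / half_lat, SC_LUMEN)
        for path in (config.vein_path, config.vein_branch):
            node = _interp_path(path, depth)
            if node is not None:
                row, col, diam = node
                rad = diam / half_lat
                _paint_disc(labels[k], row, col, rad, rad, VEIN_LUMEN)

    return LabelVolume(
        labels=labels,
        lateral_pitch=config.lateral_pitch,
        axial_step=config.axial_step,
        depth_origin=config.depth_origin,
    )


# ---------------------------------------------------------------------------
# Imaging model
# ---------------------------------------------------------------------------

def render_intensities(
    labels: LabelVolume,
    config: SyntheticSceneConfig,
    reflectance: dict[int, float] | None = None,
) -> ImageStack:
    """Render a label volume into a noisy intensity stack.

    The imaging model is: per-class signal strength (collagen bright, fluid
    voids dark) × depth attenuation ``exp(-depth / attenuation_length)``,
    blurred by an anisotropic Gaussian PSF, then Poisson photon statistics at
    ``photon_scale`` expected counts for full signal, plus zero-mean Gaussian
    read noise, clipped at zero.  Setting ``photon_scale`` to ``inf`` and
    ``read_sigma`` to 0 yields the noise-free expectation (unit signal
    scale).  Deterministic given ``config.seed``; never mutates ``labels``.
    """
    if labels.shape != tuple(config.stack_shape):
        raise ValueError("labels and config shapes disagree")
    reflectance = DEFAULT_REFLECTANCE if reflectance is None else reflectance

    signal = np.zeros(labels.shape, dtype=np.float64)
    for lab, refl in reflectance.items():
        signal[labels.labels == lab] = refl
    atten = np.exp(-config.depths / config.attenuation_length)
    signal *= atten[:, None, None]

    sig_lat, sig_ax = config.psf_sigma
    if sig_lat > 0 or sig_ax > 0:
        signal = gaussian_filter(
            signal,
            sigma=(sig_ax / config.axial_step,
                   sig_lat / config.lateral_pitch,
                   sig_lat / config.lateral_pitch),
        )

    photon_scale = float(config.noise.get("photon_scale", math.inf))
    read_sigma = float(config.noise.get("read_sigma", 0.0))
    rng = np.random.default_rng(config.seed + 1)
    if math.isfinite(photon_scale):
        out = rng.poisson(photon_scale * signal).astype(np.float64)
    else:
        out = signal
    if read_sigma > 0:
        out = out + rng.normal(0.0, read_sigma, size=out.shape)
    if math.isfinite(photon_scale):
        np.round(out, out=out)  # detector counts are integers
    np.clip(out, 0.0, None, out=out)

    return ImageStack(
        intensities=out,
        lateral_pitch=config.lateral_pitch,
        axial_step=config.axial_step,
        depth_origin=config.depth_origin,
    )


def generate_scene(
    config: SyntheticSceneConfig | None = None,
) -> tuple[LabelVolume, ImageStack]:
    """Convenience: build labels and render intensities for a config."""
    cfg = default_intact_config() if config is None else config
    labels = build_labels(cfg)
    return labels, render_intensities(labels, cfg)
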