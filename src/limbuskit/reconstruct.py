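"""3D reconstruction: segmentation, region growing, editing, voxel meshing.

Mirrors the classic interactive reconstruction workflow — threshold
segmentation, region growing from a seed, binary morphological editing —
and converts the resulting voxel mask into a conforming linear-tetrahedral
mesh.  Each tissue voxel is split into 6 tetrahedra by the Kuhn
(Freudenthal) subdivision, which conserves volume exactly and is conforming
across shared cube faces by construction.  Boundary triangles can then be
labeled into pressure / fixed / free sets for the finite-element solver.

Every editing step is recorded in a replayable provenance list, so a
segmentation is a reproducible function of its source stack.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import (
    BoundaryLabelingError,
    EmptySegmentationError,
    InvalidSeedError,
    MeshError,
)
from .stack import ImageStack

# boundary-triangle labels
FACE_FREE = 0
FACE_PRESSURE = 1
FACE_FIXED = 2

FACE_LABELS = {FACE_FREE: "free", FACE_PRESSURE: "pressure", FACE_FIXED: "fixed"}


@dataclass
class SegmentedVolume:
    """Binary tissue mask with physical pitch and replayable provenance."""

    mask: np.ndarray
    lateral_pitch: float
    axial_step: float
    depth_origin: float = 0.0
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D (slices, rows, cols)")

    @property
    def voxel_volume_um3(self) -> float:
        return self.lateral_pitch**2 * self.axial_step

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class TetMesh:
    """Linear tetrahedral mesh with labeled boundary triangles.

    ``nodes`` are physical coordinates in μm (x = col·lateral_pitch,
    y = row·lateral_pitch, z = depth_origin + slice·axial_step).  ``tets``
    are positively oriented.  ``boundary_tris`` are the faces that belong to
    exactly one tet, ordered so their normal points out of the mesh;
    ``tri_labels`` assigns each one to the free / pressure / fixed set.
    """

    nodes: np.ndarray          # (N, 3) float64, μm
    tets: np.ndarray           # (T, 4) int
    boundary_tris: np.ndarray  # (B, 3) int, outward-ordered
    tri_labels: np.ndarray     # (B,) int in {FACE_FREE, FACE_PRESSURE, FACE_FIXED}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def tet_volumes(self) -> np.ndarray:
        """Signed volumes (μm³) of all tetrahedra."""
        p = self.nodes[self.tets]
        a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def boundary_normals(self) -> np.ndarray:
        """Unit outward normals of the boundary triangles."""
        p = self.nodes[self.boundary_tris]
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def boundary_areas(self) -> np.ndarray:
        """Areas (μm²) of the boundary triangles."""
        p = self.nodes[self.boundary_tris]
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(n, axis=1)

    def nodes_of(self, face_label: int) -> np.ndarray:
        """Sorted unique node ids on boundary triangles with a given label."""
        tris = self.boundary_tris[self.tri_labels == face_label]
        return np.unique(tris)


# ---------------------------------------------------------------------------
# Segmentation steps
# ---------------------------------------------------------------------------

def threshold_segment(stack: ImageStack, threshold: float) -> SegmentedVolume:
    """Tissue = voxels with intensity >= threshold (collagen is bright)."""
    mask = stack.intensities >= threshold
    if not mask.any():
        raise EmptySegmentationError(
            f"threshold {threshold} leaves no tissue voxel")
    return SegmentedVolume(
        mask=mask,
        lateral_pitch=stack.lateral_pitch,
        axial_step=stack.axial_step,
        depth_origin=stack.depth_origin,
        provenance=[{"op": "threshold", "threshold": float(threshold)}],
    )


def region_grow(
    volume: SegmentedVolume,
    seed: tuple[int, int, int],
    connectivity: int = 26,
) -> SegmentedVolume:
    """Keep only the connected component containing the seed voxel.

    ``connectivity`` is 6 (face neighbours) or 26 (face+edge+corner).
    """
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    seed = tuple(int(s) for s in seed)
    if not (0 <= seed[0] < volume.mask.shape[0]
            and 0 <= seed[1] < volume.mask.shape[1]
            and 0 <= seed[2] < volume.mask.shape[2]) or not volume.mask[seed]:
        raise InvalidSeedError(f"seed voxel {seed} is outside the tissue mask")
    structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    lab, _ = ndimage.label(volume.mask, structure=structure)
    grown = lab == lab[seed]
    return replace(
        volume,
        mask=grown,
        provenance=volume.provenance
        + [{"op": "region_grow", "seed": list(seed), "connectivity": connectivity}],
    )


def _ball_structure(radius_um: float, lateral_pitch: float,
                    axial_step: float) -> np.ndarray:
    """Anisotropic voxel ball of a given physical radius."""
    rz = int(math.floor(radius_um / axial_step))
    rxy = int(math.floor(radius_um / lateral_pitch))
    zz, yy, xx = np.mgrid[-rz: rz + 1, -rxy: rxy + 1, -rxy: rxy + 1]
    dist2 = ((zz * axial_step) ** 2 + (yy * lateral_pitch) ** 2
             + (xx * lateral_pitch) ** 2)
    return dist2 <= radius_um**2 + 1e-9


def morphological_edit(
    volume: SegmentedVolume,
    ops: list[dict],
) -> SegmentedVolume:
    """Apply binary morphology steps in order.

    Each op is ``{"op": "close" | "open" | "fill_holes", "radius_um": r}``
    with the ball structuring element converted to anisotropic voxel radii
    via the pitch (``fill_holes`` ignores the radius).  Radius 0 is the
    single-voxel element, i.e. the identity for open/close.
    """
    mask = volume.mask
    for op in ops:
        name = op["op"]
        radius = float(op.get("radius_um", 0.0))
        if radius < 0:
            raise ValueError("radius_um must be >= 0")
        if name == "fill_holes":
            mask = ndimage.binary_fill_holes(mask)
            continue
        se = _ball_structure(radius, volume.lateral_pitch, volume.axial_step)
        if name == "close":
            mask = ndimage.binary_closing(mask, structure=se)
        elif name == "open":
            mask = ndimage.binary_opening(mask, structure=se)
        else:
            raise ValueError(f"unknown morphological op {name!r}")
    return replace(
        volume,
        mask=mask,
        provenance=volume.provenance
        + [{"op": "morphological_edit",
            "ops": [dict(o) for o in ops]}],
    )


def replay_provenance(stack: ImageStack, provenance: list[dict]) -> SegmentedVolume:
    """Re-run a recorded provenance list against its source stack."""
    if not provenance or provenance[0]["op"] != "threshold":
        raise ValueError("provenance must start with a threshold step")
    vol = threshold_segment(stack, provenance[0]["threshold"])
    for step in provenance[1:]:
        if step["op"] == "region_grow":
            vol = region_grow(vol, tuple(step["seed"]), step["connectivity"])
        elif step["op"] == "morphological_edit":
            vol = morphological_edit(vol, step["ops"])
        else:
            raise ValueError(f"unknown provenance step {step['op']!r}")
    return vol


# ---------------------------------------------------------------------------
# Voxel → tetrahedral mesh (Kuhn subdivision)
# ---------------------------------------------------------------------------

# The 6 tetrahedra of the Kuhn subdivision follow the 6 monotone lattice
# paths from corner (0,0,0) to (1,1,1); every tet contains the cube's main
# diagonal, so shared cube faces are split along the same face diagonal in
# neighbouring cubes — the mesh is conforming without any bookkeeping.
_KUHN_PERMS = [
    (0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0),
]


def _perm_sign(perm: tuple[int, int, int]) -> int:
    inv = sum(1 for i in range(3) for j in range(i + 1, 3) if perm[i] > perm[j])
    return -1 if inv % 2 else 1


def _kuhn_corner_offsets() -> np.ndarray:
    """(6, 4, 3) int offsets of tet corners within a unit cube, +oriented."""
    tets = []
    for perm in _KUHN_PERMS:
        corner = np.zeros(3, dtype=np.int64)
        verts = [corner.copy()]
        for axis in perm:
            corner = corner.copy()
            corner[axis] += 1
            verts.append(corner)
        verts = np.array(verts)
        if _perm_sign(perm) < 0:  # odd permutation -> negative volume: swap
            verts[[2, 3]] = verts[[3, 2]]
        tets.append(verts)
    return np.array(tets)


_KUHN_OFFSETS = _kuhn_corner_offsets()


def voxel_to_tetmesh(volume: SegmentedVolume) -> TetMesh:
    """Split every tissue voxel into 6 Kuhn tetrahedra.

    Node coordinates are voxel *corners* in physical μm, so the total tet
    volume equals voxel volume × voxel count exactly (up to floating point).
    Boundary triangles are the faces on the mask surface, outward-ordered
    and initially all labeled free.
    """
    vox = np.argwhere(volume.mask)  # (n, 3) in (slice, row, col)
    if len(vox) == 0:
        raise MeshError("empty mask has no mesh")
    ns, nr, nc = volume.mask.shape
    grid = (ns + 1, nr + 1, nc + 1)

    # corner ids for all voxels × 6 tets × 4 vertices
    corners = vox[:, None, None, :] + _KUHN_OFFSETS[None, :, :, :]
    lin = np.ravel_multi_index(
        (corners[..., 0], corners[..., 1], corners[..., 2]), grid)
    used, tets = np.unique(lin, return_inverse=True)
    tets = tets.reshape(-1, 4)

    si, ri, ci = np.unravel_index(used, grid)
    nodes = np.column_stack([
        ci * volume.lateral_pitch,                       # x
        ri * volume.lateral_pitch,                       # y
        volume.depth_origin + si * volume.axial_step,    # z
    ]).astype(np.float64)

    # the index->physical map (slice,row,col)->(z,y,x) is an odd permutation,
    # so orient tets positively in *physical* space by swapping where needed
    p = nodes[tets]
    vols = np.einsum(
        "ij,ij->i", p[:, 1] - p[:, 0],
        np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0])) / 6.0
    neg = vols < 0
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]

    # faces: each tet contributes 4; boundary = faces used exactly once
    face_idx = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    faces = tets[:, face_idx].reshape(-1, 3)           # orientation-preserving
    opposite = tets[:, [0, 1, 2, 3]].reshape(-1)       # vertex opposite each face
    key = np.sort(faces, axis=1)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    key_sorted = key[order]
    new_group = np.ones(len(key_sorted), dtype=bool)
    new_group[1:] = np.any(key_sorted[1:] != key_sorted[:-1], axis=1)
    group_id = np.cumsum(new_group) - 1
    counts = np.bincount(group_id)
    boundary_rows = order[np.flatnonzero(counts[group_id] == 1)]
    btris = faces[boundary_rows]
    bopp = opposite[boundary_rows]

    # orient boundary faces outward: normal · (centroid - opposite vertex) > 0
    p = nodes[btris]
    normal = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    outward = np.einsum("ij,ij->i", normal, p.mean(axis=1) - nodes[bopp])
    flip = outward < 0
    btris[flip] = btris[flip][:, [0, 2, 1]]

    mesh = TetMesh(
        nodes=nodes,
        tets=tets,
        boundary_tris=btris,
        tri_labels=np.full(len(btris), FACE_FREE, dtype=np.int64),
    )
    if np.any(mesh.tet_volumes() <= 0):
        raise MeshError("non-positive tet volume in Kuhn subdivision")
    return mesh


def label_boundaries(
    mesh: TetMesh,
    pressure_normal: np.ndarray,
    angle_tol_deg: float = 30.0,
    fixed_region=None,
) -> TetMesh:
    """Label boundary triangles into pressure / fixed / free sets.

    A triangle whose outward normal lies within ``angle_tol_deg`` of
    ``pressure_normal`` is labeled *pressure*; one whose three vertices all
    satisfy ``fixed_region(points) -> bool array`` is labeled *fixed*
    (fixed wins on overlap); the rest stay *free*.

    Raises
    ------
    BoundaryLabelingError
        If either the pressure or the fixed set comes out empty — the FEM
        would be unloaded or singular.
    """
    n = np.asarray(pressure_normal, dtype=np.float64)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("pressure_normal must be non-zero")
    n = n / norm
    normals = mesh.boundary_normals()
    cos_tol = math.cos(math.radians(angle_tol_deg))
    is_pressure = normals @ n >= cos_tol - 1e-12

    labels = np.full(len(mesh.boundary_tris), FACE_FREE, dtype=np.int64)
    labels[is_pressure] = FACE_PRESSURE
    if fixed_region is not None:
        flat = mesh.nodes[mesh.boundary_tris.reshape(-1)]
        ok = np.asarray(fixed_region(flat), dtype=bool).reshape(-1, 3)
        labels[ok.all(axis=1)] = FACE_FIXED  # constraint wins
    if not np.any(labels == FACE_PRESSURE):
        raise BoundaryLabelingError("no pressure faces within angle tolerance")
    if fixed_region is not None and not np.any(labels == FACE_FIXED):
        raise BoundaryLabelingError("no boundary faces satisfy fixed_region")
    return replace(mesh, tri_labels=labels)


def scleral_side_fixed_region(mesh: TetMesh, axis: int = 0) -> "callable":
    """Default constraint: boundary points on the max-coordinate face
    along ``axis`` (x by default — the scleral side of the ROI box)."""
    limit = mesh.nodes[:, axis].max()
    tol = 1e-9 * max(1.0, abs(limit))

    def predicate(points: np.ndarray) -> np.ndarray:
        return points[:, axis] >= limit - tol

    return predicate
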