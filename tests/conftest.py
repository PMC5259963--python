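"""Shared fixtures: calibrated synthetic scenes and small FEM meshes."""

import numpy as np
import pytest

import limbuskit as lk


@pytest.fixture(scope="session")
def intact_config():
    return lk.default_intact_config()


@pytest.fixture(scope="session")
def broken_config():
    return lk.default_broken_config()


@pytest.fixture(scope="session")
def intact_scene(intact_config):
    labels = lk.build_labels(intact_config)
    stack = lk.render_intensities(labels, intact_config)
    return labels, stack


@pytest.fixture(scope="session")
def broken_scene(broken_config):
    labels = lk.build_labels(broken_config)
    stack = lk.render_intensities(labels, broken_config)
    return labels, stack


@pytest.fixture(scope="session")
def intact_stack(intact_scene):
    return intact_scene[1]


@pytest.fixture(scope="session")
def broken_stack(broken_scene):
    return broken_scene[1]


def small_scene_config(**overrides):
    """A fast, feasible scene for tests that do not need the full presets."""
    defaults = dict(
        stack_shape=(6, 96, 96),
        lateral_pitch=2.0,
        axial_step=5.0,
        depth_origin=0.0,
        tm_roi=((0, 6), (8, 88), (24, 72)),
        porosity_profile=[(0.0, 0.4), (25.0, 0.6)],
        sc_axis_path=[],
        vein_path=[],
        vein_branch=[],
        beam_thickness_mean=6.0,
        seed=7,
    )
    defaults.update(overrides)
    return lk.SyntheticSceneConfig(**defaults)


@pytest.fixture()
def bar_mesh():
    """Labeled bar of 10 voxels along z (L = 100 μm), 2×2 in plane.

    Pressure faces on top (+z), fixed region on the z = 0 base.
    """
    vol = lk.SegmentedVolume(
        np.ones((10, 2, 2), dtype=bool),
        lateral_pitch=10.0,
        axial_step=10.0,
        provenance=[{"op": "threshold", "threshold": 0.0}],
    )
    mesh = lk.voxel_to_tetmesh(vol)
    return lk.label_boundaries(
        mesh, [0, 0, 1], angle_tol_deg=10.0,
        fixed_region=lambda p: p[:, 2] <= 1e-9,
    )


def uniaxial_dofs(mesh):
    """Minimal constraints for a uniform uniaxial stress state along z.

    Base (fixed-face) nodes are held in z only, so lateral contraction stays
    free; in-plane rigid modes are pinned at two corner nodes.
    """
    base = mesh.nodes_of(lk.FACE_FIXED)
    dofs = [(int(n), 2) for n in base]
    pts = mesh.nodes[base]
    origin = int(base[np.argmin(pts[:, 0] + pts[:, 1])])
    on_x = int(base[np.argmax(pts[:, 0] - pts[:, 1])])
    dofs += [(origin, 0), (origin, 1), (on_x, 1)]
    return dofs
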