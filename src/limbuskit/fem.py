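"""Small-strain linear-elastic FEM on constant-strain tetrahedra.

Solves K u = f for the displacement of the trabecular meshwork under the
IOP–EVP pressure drop: isotropic Hooke material (default E = 162 Pa,
ν = 0.48), consistent pressure loading on labeled boundary faces, Dirichlet
constraints by elimination, sparse direct factorization (CG fallback).
Geometry enters in μm and is converted to SI metres at assembly, so with
pressures in Pa the forces are in N; displacements are reported back in μm.

The reported quantity follows the study design this package reanalyzes:
the *directional deformation* — the displacement component along the
applied-pressure direction — and its maximum over the model, swept over
pressures 10…160 Pa in 10 Pa steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import linalg as spla

from .errors import (
    DegenerateElementError,
    IncompressibleLimitError,
    InsufficientConstraintError,
    MeshError,
    SolverError,
    UnloadedModelError,
)
from .reconstruct import FACE_PRESSURE, TetMesh

_UM_TO_M = 1e-6

#: Pressure sweep of the study design: 10 … 160 Pa in 10 Pa steps.
DEFAULT_PRESSURES_PA = tuple(float(p) for p in range(10, 170, 10))


@dataclass(frozen=True)
class MaterialModel:
    """Isotropic linear-elastic material (trabecular meshwork default)."""

    young_modulus: float = 162.0   # Pa
    poisson_ratio: float = 0.48

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError("young_modulus must be positive")
        if not -1.0 < self.poisson_ratio < 0.5:
            if abs(self.poisson_ratio - 0.5) < 1e-12:
                raise IncompressibleLimitError(
                    "poisson_ratio = 0.5 is the incompressible limit")
            raise ValueError("poisson_ratio must lie in (-1, 0.5)")
        if 0.5 - self.poisson_ratio < 1e-9:
            raise IncompressibleLimitError(
                "poisson_ratio too close to the incompressible limit 0.5")

    @property
    def lame_lambda(self) -> float:
        e, nu = self.young_modulus, self.poisson_ratio
        return e * nu / ((1 + nu) * (1 - 2 * nu))

    @property
    def lame_mu(self) -> float:
        return self.young_modulus / (2 * (1 + self.poisson_ratio))


@dataclass
class LoadCase:
    """Pressure magnitude/direction plus the Dirichlet constraint sets.

    ``fixed_nodes`` pins all three dofs of each node; ``fixed_dofs`` adds
    individual ``(node, axis)`` constraints (axis 0/1/2 = x/y/z), which is
    what analytic patch tests with free lateral contraction need.
    """

    pressure: float                       # Pa
    pressure_normal: np.ndarray           # unit vector, outward of loaded face
    fixed_nodes: np.ndarray = field(default_factory=lambda: np.array([], int))
    fixed_dofs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pressure < 0:
            raise ValueError("pressure must be >= 0")
        n = np.asarray(self.pressure_normal, dtype=np.float64)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("pressure_normal must be non-zero")
        self.pressure_normal = n / norm
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=np.int64)

    def dirichlet_dofs(self) -> np.ndarray:
        """Sorted unique global dof indices held at zero."""
        dofs = [3 * self.fixed_nodes[:, None] + np.arange(3)]
        if self.fixed_dofs:
            extra = np.array([3 * n + a for n, a in self.fixed_dofs], dtype=np.int64)
            dofs.append(extra[:, None])
        return np.unique(np.concatenate([d.ravel() for d in dofs]))


@dataclass
class FEMResult:
    """Displacement field and directional-deformation summary for one load."""

    pressure: float                    # Pa
    displacements: np.ndarray          # (N, 3) μm
    directional_deformation: np.ndarray  # (N,) μm, u · pressure_normal
    max_directional_deformation: float   # μm, max over nodes of |·|
    max_node: int
    stats: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Element level
# ---------------------------------------------------------------------------

def elasticity_matrix(material: MaterialModel) -> np.ndarray:
    """6×6 isotropic Hooke matrix in Voigt order (xx, yy, zz, xy, yz, zx).

    Diagonal blocks 2μ+λ / off-diagonal λ on the normal strains, μ on the
    engineering shear strains; symmetric positive definite for any valid
    material.
    """
    lam, mu = material.lame_lambda, material.lame_mu
    d = np.zeros((6, 6))
    d[:3, :3] = lam
    d[np.arange(3), np.arange(3)] = 2 * mu + lam
    d[np.arange(3, 6), np.arange(3, 6)] = mu
    return d


def _tet_gradients(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Shape-function gradients (4, 3) and volume of a linear tet.

    ``coords`` is (4, 3) in consistent length units; the gradients carry the
    inverse of that unit.
    """
    m = np.hstack([np.ones((4, 1)), coords])
    vol = np.linalg.det(m) / 6.0
    if vol <= 0:
        raise DegenerateElementError(f"tetrahedron volume {vol} is not positive")
    grads = np.linalg.inv(m)[1:, :].T  # row i: ∇N_i
    return grads, vol


def strain_displacement_matrix(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Constant B matrix (6×12, Voigt engineering strains) and tet volume."""
    grads, vol = _tet_gradients(coords)
    b = np.zeros((6, 12))
    for i in range(4):
        bx, by, bz = grads[i]
        c = 3 * i
        b[0, c] = bx
        b[1, c + 1] = by
        b[2, c + 2] = bz
        b[3, c], b[3, c + 1] = by, bx       # γ_xy
        b[4, c + 1], b[4, c + 2] = bz, by   # γ_yz
        b[5, c], b[5, c + 2] = bz, bx       # γ_zx
    return b, vol


def element_stiffness(coords: np.ndarray, d_matrix: np.ndarray) -> np.ndarray:
    """12×12 stiffness K_e = V·BᵀDB of a constant-strain tetrahedron.

    Symmetric with a 6-dimensional rigid-body null space.  ``coords`` must be
    in metres for K_e to act on metres and yield newtons.
    """
    b, vol = strain_displacement_matrix(coords)
    ke = vol * b.T @ d_matrix @ b
    return 0.5 * (ke + ke.T)  # enforce exact symmetry against fp round-off


# ---------------------------------------------------------------------------
# Assembly and loading
# ---------------------------------------------------------------------------

def assemble(mesh: TetMesh, material: MaterialModel) -> sparse.csr_matrix:
    """Global sparse stiffness (SI units) of size 3N×3N.

    Before constraints the matrix of a single connected mesh has exactly the
    6 rigid-body modes in its null space.
    """
    if len(mesh.tets) == 0:
        raise MeshError("mesh has no tetrahedra")
    d = elasticity_matrix(material)
    coords_m = mesh.nodes * _UM_TO_M
    n_tet = len(mesh.tets)
    rows = np.empty(n_tet * 144, dtype=np.int64)
    cols = np.empty(n_tet * 144, dtype=np.int64)
    vals = np.empty(n_tet * 144, dtype=np.float64)
    for t, tet in enumerate(mesh.tets):
        ke = element_stiffness(coords_m[tet], d)
        dofs = (3 * tet[:, None] + np.arange(3)).ravel()
        rr, cc = np.meshgrid(dofs, dofs, indexing="ij")
        s = slice(t * 144, (t + 1) * 144)
        rows[s], cols[s], vals[s] = rr.ravel(), cc.ravel(), ke.ravel()
    n_dof = 3 * mesh.n_nodes
    k = sparse.coo_matrix((vals, (rows, cols)), shape=(n_dof, n_dof)).tocsr()
    # duplicate-summation order can leave ~1e-19 asymmetry; make it exact
    return ((k + k.T) * 0.5).tocsr()


def pressure_load(mesh: TetMesh, pressure: float,
                  pressure_normal: np.ndarray) -> np.ndarray:
    """Consistent nodal force vector (N) from pressure on labeled faces.

    Each pressure triangle of area A contributes p·A/3 per vertex along
    −pressure_normal (pressure pushes into the tissue); the total applied
    force is p × (total pressure-face area).
    """
    sel = mesh.tri_labels == FACE_PRESSURE
    if not sel.any():
        raise UnloadedModelError("no boundary faces labeled pressure")
    n = np.asarray(pressure_normal, dtype=np.float64)
    n = n / np.linalg.norm(n)
    tris = mesh.boundary_tris[sel]
    areas_m2 = mesh.boundary_areas()[sel] * _UM_TO_M**2
    f = np.zeros(3 * mesh.n_nodes)
    per_vertex = (pressure * areas_m2 / 3.0)[:, None] * (-n)[None, :]  # (B,3)
    for axis in range(3):
        np.add.at(f, 3 * tris.ravel() + axis,
                  np.repeat(per_vertex[:, axis], 3))
    return f


# ---------------------------------------------------------------------------
# Solve
# ---------------------------------------------------------------------------

def _reduced_solve(k_ff: sparse.csr_matrix, f_f: np.ndarray,
                   rtol: float = 1e-8) -> tuple[np.ndarray, dict]:
    stats: dict = {"solver": "splu"}
    try:
        lu = spla.splu(k_ff.tocsc())
        u = lu.solve(f_f)
    except RuntimeError as err:  # singular factorization
        raise InsufficientConstraintError(
            f"reduced stiffness is singular ({err}); rigid modes remain"
        ) from err
    f_norm = np.linalg.norm(f_f)
    residual = np.linalg.norm(k_ff @ u - f_f) / f_norm if f_norm > 0 else 0.0
    if residual > rtol:
        # diagonal-preconditioned CG fallback
        m = sparse.diags(1.0 / k_ff.diagonal())
        u, info = spla.cg(k_ff, f_f, x0=u, rtol=1e-10, maxiter=5000, M=m)
        residual = np.linalg.norm(k_ff @ u - f_f) / f_norm
        stats = {"solver": "splu+cg", "cg_info": int(info)}
        if info != 0 or residual > rtol:
            raise SolverError(f"solver stalled at relative residual {residual:.2e}")
    stats["residual"] = float(residual)
    return u, stats


def solve(mesh: TetMesh, material: MaterialModel, load: LoadCase) -> FEMResult:
    """Solve K u = f with the fixed dofs eliminated (rows/cols removed).

    Fixed dofs come out exactly zero; the relative residual on the free dofs
    is required to be ≤ 1e-8.  The directional deformation is
    u · pressure_normal per node, in μm.
    """
    k = assemble(mesh, material)
    f = (pressure_load(mesh, load.pressure, load.pressure_normal)
         if load.pressure > 0 else np.zeros(3 * mesh.n_nodes))
    fixed = load.dirichlet_dofs()
    if len(fixed) == 0:
        raise InsufficientConstraintError("fixed set is empty")
    free = np.setdiff1d(np.arange(3 * mesh.n_nodes), fixed)
    u = np.zeros(3 * mesh.n_nodes)
    if load.pressure > 0:
        u_f, stats = _reduced_solve(k[free][:, free].tocsr(), f[free])
        u[free] = u_f
    else:
        stats = {"solver": "trivial", "residual": 0.0}
    return _fill_result(mesh, load, u, stats)


def _fill_result(mesh: TetMesh, load: LoadCase, u_m: np.ndarray,
                 stats: dict) -> FEMResult:
    disp_um = u_m.reshape(-1, 3) / _UM_TO_M
    directional = disp_um @ load.pressure_normal
    idx = int(np.argmax(np.abs(directional)))
    return FEMResult(
        pressure=load.pressure,
        displacements=disp_um,
        directional_deformation=directional,
        max_directional_deformation=float(abs(directional[idx])),
        max_node=idx,
        stats=stats,
    )


def pressure_sweep(
    mesh: TetMesh,
    material: MaterialModel,
    pressures: tuple[float, ...] | None = None,
    *,
    pressure_normal: np.ndarray,
    fixed_nodes: np.ndarray = None,
    fixed_dofs: list[tuple[int, int]] | None = None,
) -> list[FEMResult]:
    """One solve per pressure, reusing a single factorization.

    ``pressures`` defaults to the 16-point study sweep 10 … 160 Pa.  Results
    come back sorted by pressure; for a fixed loaded mesh the maximum
    directional deformation grows strictly with pressure (linearity).
    """
    pressures = DEFAULT_PRESSURES_PA if pressures is None else tuple(pressures)
    if len(pressures) == 0:
        raise ValueError("pressures must be non-empty")
    if any(p < 0 for p in pressures):
        raise ValueError("pressures must be >= 0")
    fixed_nodes = np.array([], dtype=np.int64) if fixed_nodes is None else fixed_nodes
    base = LoadCase(
        pressure=max(max(pressures), 1.0),
        pressure_normal=pressure_normal,
        fixed_nodes=fixed_nodes,
        fixed_dofs=fixed_dofs or [],
    )
    k = assemble(mesh, material)
    fixed = base.dirichlet_dofs()
    if len(fixed) == 0:
        raise InsufficientConstraintError("fixed set is empty")
    free = np.setdiff1d(np.arange(3 * mesh.n_nodes), fixed)
    k_ff = k[free][:, free].tocsc()
    try:
        lu = spla.splu(k_ff)
    except RuntimeError as err:
        raise InsufficientConstraintError(
            f"reduced stiffness is singular ({err})") from err

    results = []
    for p in sorted(pressures):
        load = LoadCase(pressure=p, pressure_normal=pressure_normal,
                        fixed_nodes=fixed_nodes, fixed_dofs=fixed_dofs or [])
        u = np.zeros(3 * mesh.n_nodes)
        stats: dict = {"solver": "splu(shared)"}
        if p > 0:
            f = pressure_load(mesh, p, load.pressure_normal)
            u_f = lu.solve(f[free])
            f_norm = np.linalg.norm(f[free])
            residual = (np.linalg.norm(k_ff @ u_f - f[free]) / f_norm
                        if f_norm > 0 else 0.0)
            if residual > 1e-8:
                raise SolverError(
                    f"sweep solve at {p} Pa stalled (residual {residual:.2e})")
            stats["residual"] = float(residual)
            u[free] = u_f
        else:
            stats["residual"] = 0.0
        results.append(_fill_result(mesh, load, u, stats))
    return results


def deformation_report(results: list[FEMResult]) -> pd.DataFrame:
    """Summary table: pressure, max directional deformation, argmax node."""
    if not results:
        raise ValueError("results must be non-empty")
    return pd.DataFrame(
        [
            {
                "pressure_pa": r.pressure,
                "max_directional_deformation_um": r.max_directional_deformation,
                "node_id": r.max_node,
            }
            for r in results
        ]
    )
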