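"""Directional effective stiffness of binary volumes by linear voxel FEM.

Each solid voxel becomes a trilinear (8-node) hexahedral element with
isotropic elasticity (Young's modulus ``solid_modulus``, Poisson ratio
``poisson``); pore voxels are void.  The loading replicates a tensile test
between parallel rigid plates in the small-strain (linear) regime:

* loaded face: uniform axial displacement on every solid node (lateral
  components free),
* opposite face: axial displacement fixed (lateral free, plus minimal point
  constraints to remove the lateral rigid-body modes),
* lateral faces: traction-free.

The effective modulus along the load axis is E = F * l / (u * A) with F the
total axial reaction on the loaded face, l the domain length, u the applied
displacement and A the *full* domain cross-section (voids included), so E is
bounded by 0 and the Voigt estimate (volume fraction x solid modulus).

Because the problem is linear, E scales exactly with ``solid_modulus``;
:func:`calibrate_solid_modulus` exploits this to match a target effective
modulus with a single unit-modulus solve.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg, splu, LinearOperator

from .morphometry import percolates
from .volumes import BinaryMicrostructure, axis_index

# element-local corner offsets (i, j, k), fixed ordering shared with the
# shape functions in _element_stiffness
_CORNERS = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
            (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)]


class HomogenizationError(RuntimeError):
    pass


@lru_cache(maxsize=8)
def _element_stiffness(poisson: float) -> np.ndarray:
    """24x24 stiffness of a unit-cube trilinear hexahedron at E=1.

    2x2x2 Gauss quadrature; exact for this element.  Stiffness for edge
    length h scales by h, and linearly with E; both are applied at assembly.
    """
    nu = poisson
    lam = nu / ((1 + nu) * (1 - 2 * nu))
    mu = 1.0 / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.diag_indices(3)] = lam + 2 * mu
    D[3:, 3:] = np.eye(3) * mu

    g = 0.5 + np.array([-1, 1]) / (2 * np.sqrt(3.0))
    KE = np.zeros((24, 24))
    for gi in g:
        for gj in g:
            for gk in g:
                dN = np.zeros((8, 3))
                for a, (ci, cj, ck) in enumerate(_CORNERS):
                    ni = ci * gi + (1 - ci) * (1 - gi)
                    nj = cj * gj + (1 - cj) * (1 - gj)
                    nk = ck * gk + (1 - ck) * (1 - gk)
                    dni = 1.0 if ci else -1.0
                    dnj = 1.0 if cj else -1.0
                    dnk = 1.0 if ck else -1.0
                    dN[a] = [dni * nj * nk, ni * dnj * nk, ni * nj * dnk]
                B = np.zeros((6, 24))
                for a in range(8):
                    bx, by, bz = dN[a]
                    c = 3 * a
                    B[0, c] = bx
                    B[1, c + 1] = by
                    B[2, c + 2] = bz
                    B[3, c] = by
                    B[3, c + 1] = bx
                    B[4, c + 1] = bz
                    B[4, c + 2] = by
                    B[5, c] = bz
                    B[5, c + 2] = bx
                KE += B.T @ D @ B * (1.0 / 8.0)
    return KE


@dataclass
class HomogenizationResult:
    """Directional effective moduli of a binary volume (MPa)."""

    E_x: float
    E_y: float
    E_z: float
    solid_modulus: float
    poisson: float

    @property
    def anisotropy_ratio(self) -> float:
        """Longitudinal-to-transverse stiffness ratio E_z / mean(E_x, E_y)."""
        denom = 0.5 * (self.E_x + self.E_y)
        return self.E_z / denom if denom > 0 else float("inf")

    def to_dict(self) -> dict:
        return {
            "E_x_MPa": self.E_x,
            "E_y_MPa": self.E_y,
            "E_z_MPa": self.E_z,
            "solid_modulus_MPa": self.solid_modulus,
            "poisson": self.poisson,
            "anisotropy_ratio": self.anisotropy_ratio,
        }


def _solve_spd(
    K: sparse.csr_matrix,
    f: np.ndarray,
    x0: np.ndarray,
    rtol: float,
    block_inv: np.ndarray | None = None,
) -> np.ndarray:
    """Solve the SPD system: sparse LU when small, otherwise conjugate
    gradients with a 3x3 nodal block-Jacobi preconditioner (``block_inv``:
    inverted per-node diagonal blocks)."""
    n = K.shape[0]
    if n <= 40_000:
        return splu(
            K.tocsc(), permc_spec="MMD_AT_PLUS_A", options=dict(SymmetricMode=True)
        ).solve(f)
    if block_inv is not None:
        def apply_block(v):
            return np.einsum("nij,nj->ni", block_inv, v.reshape(-1, 3)).ravel()

        M = LinearOperator((n, n), matvec=apply_block)
    else:
        d = K.diagonal()
        M = LinearOperator((n, n), matvec=lambda v: v / d)
    x, info = cg(K, f, x0=x0, M=M, rtol=rtol, atol=0.0, maxiter=40_000)
    if info != 0:
        raise HomogenizationError(f"elasticity CG did not converge (info={info})")
    return x


def _effective_modulus_axis0(solid: np.ndarray, poisson: float, rtol: float) -> float:
    """Effective modulus (units of solid modulus) along axis 0 of ``solid``."""
    n0, n1, n2 = solid.shape
    KE = _element_stiffness(round(float(poisson), 12))

    # keep only load-bearing solid: vertex-connected components spanning the
    # two plates.  Fragments touching one or neither plate carry no load but
    # would contribute free rigid-body modes (singular stiffness).
    from scipy import ndimage

    labels, _ = ndimage.label(solid, structure=np.ones((3, 3, 3), dtype=bool))
    spanning = np.intersect1d(np.unique(labels[0]), np.unique(labels[-1]))
    spanning = spanning[spanning > 0]
    if spanning.size == 0:
        return 0.0
    solid = np.isin(labels, spanning)
    labels = np.where(solid, labels, 0)

    # node grid and element connectivity (only solid voxels carry elements)
    nn1, nn2 = n1 + 1, n2 + 1
    ei, ej, ek = np.nonzero(solid)
    n_el = ei.size
    if n_el == 0:
        return 0.0
    corner_nodes = np.empty((n_el, 8), dtype=np.int64)
    for a, (ci, cj, ck) in enumerate(_CORNERS):
        corner_nodes[:, a] = ((ei + ci) * nn1 + (ej + cj)) * nn2 + (ek + ck)

    used = np.unique(corner_nodes)
    remap = -np.ones((n0 + 1) * nn1 * nn2, dtype=np.int64)
    remap[used] = np.arange(used.size)
    conn = remap[corner_nodes]
    n_nodes = used.size
    ndof = 3 * n_nodes

    edof = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(n_el, 24)
    iK = np.repeat(edof, 24, axis=1).ravel()
    jK = np.tile(edof, (1, 24)).ravel()
    vK = np.tile(KE.ravel(), n_el)
    K = sparse.csr_matrix(
        (vK, (iK.astype(np.int32), jK.astype(np.int32))), shape=(ndof, ndof)
    )
    del iK, jK, vK

    # per-node 3x3 diagonal blocks, accumulated element-wise (for the
    # block-Jacobi preconditioner)
    blocks = np.zeros((n_nodes, 3, 3))
    for a in range(8):
        np.add.at(blocks, conn[:, a], KE[3 * a : 3 * a + 3, 3 * a : 3 * a + 3])

    # node coordinates (axial index and transverse coords of used nodes)
    ni = used // (nn1 * nn2)
    nj = (used // nn2) % nn1
    nk = used % nn2

    delta = 0.001 * n0  # 0.1% axial strain; linear problem, value cancels
    prescribed = np.zeros(ndof, dtype=bool)
    u = np.zeros(ndof)

    bottom = ni == 0
    top = ni == n0
    prescribed[3 * np.flatnonzero(bottom)] = True  # axial dof fixed
    top_ax = 3 * np.flatnonzero(top)
    prescribed[top_ax] = True
    u[top_ax] = delta

    # minimal point constraints against lateral rigid-body motion (axial
    # rotation + 2 translations), per spanning component
    elem_lab = labels[ei, ej, ek]
    for lab in spanning:
        sel = elem_lab == lab
        comp_bottom_nodes = np.unique(conn[sel][:, [0, 2, 4, 6]])  # ci == 0 corners
        comp_bottom_nodes = comp_bottom_nodes[ni[comp_bottom_nodes] == 0]
        if comp_bottom_nodes.size == 0:
            continue
        a = int(comp_bottom_nodes[0])
        prescribed[3 * a + 1] = True
        prescribed[3 * a + 2] = True
        dj = np.abs(nj[comp_bottom_nodes] - nj[a])
        dk = np.abs(nk[comp_bottom_nodes] - nk[a])
        if dj.max(initial=0) > 0:
            b = int(comp_bottom_nodes[int(np.argmax(dj))])
            prescribed[3 * b + 2] = True
        elif dk.max(initial=0) > 0:
            b = int(comp_bottom_nodes[int(np.argmax(dk))])
            prescribed[3 * b + 1] = True

    # constrained full-size system: zero prescribed rows/cols, 1 on their
    # diagonal — keeps the 3-dof nodal block structure for the preconditioner
    mask = np.ones(ndof)
    mask[prescribed] = 0.0
    D = sparse.diags(mask)
    Kc = (D @ K @ D + sparse.diags(1.0 - mask)).tocsr()
    b_full = np.empty(ndof)
    b_full[~prescribed] = -(K[~prescribed][:, prescribed] @ u[prescribed])
    b_full[prescribed] = u[prescribed]

    # zero prescribed rows/cols of the diagonal blocks accordingly
    pres3 = prescribed.reshape(-1, 3)
    blocks = np.where(pres3[:, :, None], 0.0, blocks)
    blocks = np.where(pres3[:, None, :], 0.0, blocks)
    eye = np.broadcast_to(np.eye(3), blocks.shape)
    blocks = blocks + eye * pres3[:, None, :]
    block_inv = np.linalg.inv(blocks)

    # initial guess: uniform axial strain ramp
    x0 = np.zeros(ndof)
    x0[0::3] = delta * ni / n0
    x0[prescribed] = u[prescribed]
    u = _solve_spd(Kc, b_full, x0, rtol, block_inv)

    reaction = K[top_ax] @ u
    F = float(reaction.sum())
    # E = F*l/(u*A) with l = n0, A = n1*n2 (voxel units; h cancels since the
    # unit-cube element stiffness corresponds to h=1 and K scales with h)
    return F * n0 / (delta * n1 * n2)


def homogenize_effective_moduli(
    binary: BinaryMicrostructure,
    solid_modulus: float,
    poisson: float = 0.49,
    axes: tuple = ("x", "y", "z"),
    rtol: float = 1e-7,
) -> HomogenizationResult:
    """Directional effective Young's moduli of the solid phase.

    Parameters
    ----------
    binary
        Two-phase volume; the solid phase carries the load.
    solid_modulus
        Young's modulus of the solid material, MPa.
    poisson
        Poisson ratio of the solid, in (0, 0.5); default 0.49
        (near-incompressible soft tissue).
    axes
        Axes to load; unlisted axes are reported as NaN.

    Axes along which the solid phase does not percolate get E = 0.
    """
    if not (0.0 < poisson < 0.5):
        raise ValueError("poisson must be in (0, 0.5)")
    if solid_modulus <= 0:
        raise ValueError("solid_modulus must be positive")
    E = {"x": float("nan"), "y": float("nan"), "z": float("nan")}
    for ax_name in axes:
        ax = axis_index(ax_name)
        if not percolates(binary.solid, ax, connectivity=26):
            E["zyx"[ax]] = 0.0
            continue
        order = (ax,) + tuple(i for i in range(3) if i != ax)
        solid = np.transpose(binary.solid, order)
        e_unit = _effective_modulus_axis0(solid, poisson, rtol)
        E["zyx"[ax]] = e_unit * solid_modulus
    return HomogenizationResult(
        E_x=E["x"], E_y=E["y"], E_z=E["z"],
        solid_modulus=solid_modulus, poisson=poisson,
    )


def calibrate_solid_modulus(
    binary: BinaryMicrostructure,
    target_E: float,
    axis: int | str = "z",
    poisson: float = 0.49,
    verify: bool = True,
    rtol: float = 1e-7,
) -> float:
    """Solid modulus whose effective modulus along ``axis`` equals ``target_E``.

    One homogenization at unit modulus gives E_unit; linearity then yields
    solid_modulus = target_E / E_unit.  With ``verify=True`` a confirming
    solve checks the match to 1%.
    """
    if target_E <= 0:
        raise ValueError("target_E must be positive")
    ax_name = "zyx"[axis_index(axis)]
    res = homogenize_effective_moduli(binary, 1.0, poisson, axes=(ax_name,), rtol=rtol)
    e_unit = getattr(res, f"E_{ax_name}")
    if e_unit <= 0:
        raise HomogenizationError(
            f"solid phase does not percolate along {ax_name}; cannot calibrate"
        )
    solid_modulus = target_E / e_unit
    if verify:
        chk = homogenize_effective_moduli(
            binary, solid_modulus, poisson, axes=(ax_name,), rtol=rtol
        )
        achieved = getattr(chk, f"E_{ax_name}")
        if abs(achieved - target_E) > 0.01 * target_E:
            raise HomogenizationError(
                f"calibration verification failed: achieved {achieved:.4g} "
                f"vs target {target_E:.4g} MPa"
            )
    return solid_modulus
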