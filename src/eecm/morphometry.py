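"""Microstructural morphometrics of two-phase voxel volumes.

Quantifies the descriptors that control transport and stiffness of a porous
tissue matrix: porosity, geodesic tortuosity of either phase along each axis,
surface area-to-volume ratio (SAVR), and pore / solid size distributions via
watershed object separation and equivalent spherical diameters (ESD).

Conventions
-----------
* Phase connectivity and geodesic paths use 26-connectivity with Euclidean
  edge weights (axis step ``h``, face-diagonal ``h*sqrt(2)``, body-diagonal
  ``h*sqrt(3)``), which has less directional bias than 6-connectivity.
* Tortuosity along an axis is the mean, over all phase voxels on the inlet
  face that belong to a percolating component, of the geodesic path length to
  the opposite face divided by the domain extent.  A half voxel is added at
  each path end so a straight path across ``n`` voxels measures exactly
  ``n*h`` and an unobstructed phase has tortuosity 1.0.
* SAVR counts only internal solid/pore interface; the cut faces where the
  solid meets the domain boundary are excluded, so the measure does not
  depend on where the region of interest was cropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from skimage import measure, morphology, segmentation

from .volumes import BinaryMicrostructure, axis_index

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class NonPercolatingError(RuntimeError):
    """Raised when a phase has no connected path between the two faces."""


def compute_porosity(binary: BinaryMicrostructure) -> float:
    """Pore-phase volume fraction (pore voxels / total voxels)."""
    if binary.solid.size == 0:
        raise ValueError("empty volume")
    return float(binary.pore.mean())


def savr_face_counting(binary: BinaryMicrostructure) -> float:
    """SAVR from counting internal solid/pore voxel faces, in um^-1.

    Overestimates the area of smooth curved interfaces (staircase effect,
    up to ~1.5x for a sphere) but is exact for axis-aligned planar walls;
    serves as an independent cross-check on the isosurface estimate.
    """
    s = binary.solid
    h = binary.voxel_size
    n_faces = 0
    for ax in range(3):
        a = np.swapaxes(s, 0, ax)
        n_faces += int(np.count_nonzero(a[1:] ^ a[:-1]))
    area = n_faces * h * h
    return area / (s.size * h**3)


def compute_savr(binary: BinaryMicrostructure) -> float:
    """Surface area-to-volume ratio of the solid phase, in um^-1.

    The solid/pore interface is triangulated by marching cubes on the solid
    indicator after a mild Gaussian pre-smoothing (sigma 0.7 voxels), which
    removes most of the staircase overestimate of curved interfaces (a
    voxel-sphere otherwise reads ~9% high) at the cost of slightly rounding
    sharp edges.  Faces on the domain boundary are not generated and are
    therefore excluded.  Returns 0 for an all-solid or all-pore volume (no
    internal interface).
    """
    s = binary.solid
    if not s.any():
        import warnings

        warnings.warn("empty solid phase; SAVR is 0", stacklevel=2)
        return 0.0
    h = binary.voxel_size
    vol = s.size * h**3
    field = ndimage.gaussian_filter(s.astype(np.float32), 0.7, mode="reflect")
    try:
        verts, faces, _, _ = measure.marching_cubes(
            field, level=0.5, spacing=(h, h, h)
        )
    except (ValueError, RuntimeError):
        return 0.0  # no 0.5 crossing: single-phase volume
    area = measure.mesh_surface_area(verts, faces)
    return float(area / vol)


def percolates(mask: np.ndarray, axis: int | str, connectivity: int = 26) -> bool:
    """True if ``mask`` has a connected component touching both faces normal to ``axis``."""
    ax = axis_index(axis)
    struct = _STRUCT26 if connectivity == 26 else ndimage.generate_binary_structure(3, 1)
    labels, _ = ndimage.label(mask, structure=struct)
    lo = np.unique(labels.take(0, axis=ax))
    hi = np.unique(labels.take(-1, axis=ax))
    common = np.intersect1d(lo, hi)
    return bool(common[common > 0].size)


def _voxel_graph(mask: np.ndarray, h: float) -> sparse.csr_matrix:
    """Sparse undirected 26-neighbourhood graph over True voxels of ``mask``,
    Euclidean edge weights, nodes indexed by flattened voxel index."""
    n = mask.size
    idx = np.arange(n).reshape(mask.shape)
    rows, cols, data = [], [], []
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) > (0, 0, 0)
    ]
    def _slices(o: int) -> tuple[slice, slice]:
        if o > 0:
            return slice(None, -o), slice(o, None)
        if o < 0:
            return slice(-o, None), slice(None, o)
        return slice(None), slice(None)

    for off in offsets:
        w = h * float(np.sqrt(sum(o * o for o in off)))
        pairs = [_slices(o) for o in off]
        src_sl = tuple(p[0] for p in pairs)
        dst_sl = tuple(p[1] for p in pairs)
        pair_ok = mask[src_sl] & mask[dst_sl]
        rows.append(idx[src_sl][pair_ok])
        cols.append(idx[dst_sl][pair_ok])
        data.append(np.full(int(pair_ok.sum()), w))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.concatenate(data)
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


@dataclass
class TortuosityResult:
    """Geodesic tortuosity of one phase along one axis."""

    mean: float
    min: float
    n_paths: int
    phase: str
    axis: str


def compute_tortuosity(
    binary: BinaryMicrostructure, phase: str, axis: int | str, *, full_result: bool = False
) -> float | TortuosityResult:
    """Geodesic tortuosity (>= 1) of ``phase`` along ``axis``.

    Raises :class:`NonPercolatingError` if the phase does not connect the
    two faces.  With ``full_result=True`` also returns the single-shortest
    path statistic and the number of inlet voxels averaged.
    """
    ax = axis_index(axis)
    mask = binary.phase_mask(phase)
    if not mask.any():
        raise NonPercolatingError(f"phase {phase!r} is empty")
    # restrict to components that span the two faces
    labels, _ = ndimage.label(mask, structure=_STRUCT26)
    lo = np.unique(labels.take(0, axis=ax))
    hi = np.unique(labels.take(-1, axis=ax))
    spanning = np.intersect1d(lo, hi)
    spanning = spanning[spanning > 0]
    if spanning.size == 0:
        raise NonPercolatingError(f"phase {phase!r} does not percolate along axis {axis}")
    mask = np.isin(labels, spanning)

    h = binary.voxel_size
    n_axis = mask.shape[ax]
    extent = n_axis * h
    graph = _voxel_graph(mask, h)

    # virtual source connected to every outlet-face voxel with zero weight
    n = mask.size
    outlet = np.zeros_like(mask)
    sl = [slice(None)] * 3
    sl[ax] = -1
    outlet[tuple(sl)] = mask[tuple(sl)]
    out_idx = np.flatnonzero(outlet)
    src = sparse.csr_matrix(
        (np.full(out_idx.size, 1e-300), (np.zeros(out_idx.size, int), out_idx)),
        shape=(1, n),
    )
    graph = sparse.bmat([[graph, src.T], [src, None]], format="csr")
    dist = dijkstra(graph, directed=False, indices=n)

    sl[ax] = 0
    inlet = np.zeros_like(mask)
    inlet[tuple(sl)] = mask[tuple(sl)]
    d_in = dist[np.flatnonzero(inlet)]
    d_in = d_in[np.isfinite(d_in)]
    if d_in.size == 0:
        raise NonPercolatingError(f"phase {phase!r} does not percolate along axis {axis}")
    tau = (d_in + h) / extent  # half-voxel entry + exit
    result = TortuosityResult(
        mean=float(tau.mean()),
        min=float(tau.min()),
        n_paths=int(tau.size),
        phase=phase,
        axis="zyx"[ax],
    )
    return result if full_result else result.mean


def separate_objects(
    binary: BinaryMicrostructure, phase: str, h_maxima: float = 2.0
) -> np.ndarray:
    """Split a phase into individual objects by marker-based watershed.

    Markers are the local maxima of the Euclidean distance transform of the
    phase after h-maxima suppression (``h_maxima`` in voxel units, default 2),
    which prevents spurious splits from voxelization roughness.  Watershed
    runs on the negated distance transform restricted to the phase, so every
    phase voxel receives exactly one label.
    """
    mask = binary.phase_mask(phase)
    if not mask.any():
        raise ValueError(f"phase {phase!r} is empty")
    edt = ndimage.distance_transform_edt(mask)
    if h_maxima > 0:
        maxima = morphology.h_maxima(edt, h_maxima)
    else:
        maxima = morphology.local_maxima(edt)
    maxima &= mask
    if not maxima.any():  # degenerate: thin phase, EDT flat
        maxima = mask
    markers, _ = ndimage.label(maxima, structure=_STRUCT26)
    labels = segmentation.watershed(-edt, markers=markers, mask=mask)
    # watershed can miss voxels disconnected from every marker under its own
    # connectivity; assign leftovers by connected-component labels
    leftover = mask & (labels == 0)
    if leftover.any():
        extra, n_extra = ndimage.label(leftover, structure=_STRUCT26)
        labels = labels + np.where(leftover, extra + labels.max(), 0)
    return labels


@dataclass
class ESDResult:
    """Equivalent-spherical-diameter statistics of separated objects."""

    esd: np.ndarray
    mean: float
    sd: float
    hist_counts: np.ndarray = field(default=None, repr=False)
    hist_edges: np.ndarray = field(default=None, repr=False)


def esd_distribution(labeled: np.ndarray, voxel_size: float, bins: int = 20) -> ESDResult:
    """Per-object equivalent spherical diameter, ESD = (6V/pi)^(1/3), in um."""
    counts = np.bincount(labeled.ravel())[1:]
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("no labeled objects")
    volumes = counts * voxel_size**3
    esd = (6.0 * volumes / np.pi) ** (1.0 / 3.0)
    hist_counts, hist_edges = np.histogram(esd, bins=bins)
    return ESDResult(
        esd=esd,
        mean=float(esd.mean()),
        sd=float(esd.std()),
        hist_counts=hist_counts,
        hist_edges=hist_edges,
    )


@dataclass
class MorphometryResult:
    """Full microstructural characterization of a binary volume."""

    porosity: float
    savr: float
    savr_face_counting: float
    tortuosity: dict
    pore_size_mean: float
    pore_size_sd: float
    solid_thickness_mean: float
    solid_thickness_sd: float
    pore_esd: ESDResult = field(repr=False, default=None)
    solid_esd: ESDResult = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "porosity": self.porosity,
            "savr_um^-1": self.savr,
            "savr_face_counting_um^-1": self.savr_face_counting,
            "tortuosity": self.tortuosity,
            "pore_size_mean_um": self.pore_size_mean,
            "pore_size_sd_um": self.pore_size_sd,
            "solid_thickness_mean_um": self.solid_thickness_mean,
            "solid_thickness_sd_um": self.solid_thickness_sd,
        }


def characterize(
    binary: BinaryMicrostructure,
    axes: tuple = ("x", "y", "z"),
    phases: tuple = ("solid", "pore"),
    h_maxima: float = 2.0,
) -> MorphometryResult:
    """Compute the full morphometric parameter set of a binary volume.

    Tortuosity is reported per phase and axis; non-percolating combinations
    are reported as ``None``.
    """
    tort: dict = {}
    for phase in phases:
        for ax in axes:
            try:
                tort[f"{phase}_{ax}"] = compute_tortuosity(binary, phase, ax)
            except NonPercolatingError:
                tort[f"{phase}_{ax}"] = None
    pore_esd = esd_distribution(separate_objects(binary, "pore", h_maxima), binary.voxel_size)
    solid_esd = esd_distribution(separate_objects(binary, "solid", h_maxima), binary.voxel_size)
    return MorphometryResult(
        porosity=compute_porosity(binary),
        savr=compute_savr(binary),
        savr_face_counting=savr_face_counting(binary),
        tortuosity=tort,
        pore_size_mean=pore_esd.mean,
        pore_size_sd=pore_esd.sd,
        solid_thickness_mean=solid_esd.mean,
        solid_thickness_sd=solid_esd.sd,
        pore_esd=pore_esd,
        solid_esd=solid_esd,
    )
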