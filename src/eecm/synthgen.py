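"""Synthetic inputs with known ground truth for every pipeline stage.

Generators cover four input families:

* analytic flow fixtures — a straight circular channel and a planar slit,
  whose porosity and permeability have closed forms (Hagen-Poiseuille and
  plane-Poiseuille) for validating the Stokes solver;
* endoneurium-like fiber phantoms — bundles of aligned, gently wavy tubes
  (the pore space left by axons) inside a solid matrix, with controllable
  porosity (default 35.5%), tube caliber (default pore size ~11.8 um) and
  longitudinal alignment;
* noisy grayscale renderings of known binaries, emulating micro-CT contrast
  for threshold-calibration tests;
* J-shaped uniaxial stress-strain curves (toe region then linear limb) and
  falling-head permeameter records for a known permeability.

Every generator is a pure function of its spec, including the seed: the same
spec reproduces the same output bit for bit.  Voxel membership follows the
voxel-center rule (a voxel belongs to a shape iff its center is inside),
matching the analytic counting oracles used in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .mechanics import StressStrainCurve, uniaxial_stress
from .morphometry import percolates
from .permeability import FallingHeadTest, FluidProperties, WATER
from .volumes import BinaryMicrostructure, GrayscaleVolume, axis_index


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters of an aligned-tube (endoneurium-like) fiber phantom.

    Defaults target the microstructure of human peripheral-nerve endoneurium
    ECM: porosity 35.5%, pore (tube) diameter ~11.8 um with a few um spread,
    walls ~11 um thick, longitudinal alignment with mild waviness.
    """

    shape: tuple = (64, 64, 64)  # voxels, (z, y, x)
    voxel_size: float = 1.0  # um
    target_porosity: float = 0.355
    tube_radius_mean: float = 4.6  # um
    tube_radius_sd: float = 1.0  # um
    alignment_axis: str = "z"
    waviness: float = 0.03  # centerline amplitude / axial length
    radius_modulation: float = 0.45  # fractional amplitude of r(z) variation
    modulation_wavelength: float = 12.0  # um, axial period of r(z)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_porosity < 1.0):
            raise ValueError("target_porosity must be in (0, 1)")
        if self.tube_radius_mean <= self.voxel_size:
            raise ValueError("tube_radius_mean must exceed the voxel size")
        if min(self.shape) < 16:
            raise ValueError("each dimension must be at least 16 voxels")
        if self.waviness < 0:
            raise ValueError("waviness must be >= 0")


@dataclass
class NoiseSpec:
    """Grayscale rendering parameters emulating micro-CT contrast."""

    blur_sigma: float = 1.0  # voxels
    noise_sd: float = 10.0  # grayscale units
    fg_level: float = 200.0  # solid-phase mean
    bg_level: float = 50.0  # pore-phase mean
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fg_level == self.bg_level:
            raise ValueError("fg_level and bg_level must differ")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class CurveSpec:
    """Parameters of a synthetic uniaxial tensile curve.

    With ``linear_modulus`` set, a piecewise J-curve is generated: a cubic
    toe up to ``toe_strain`` whose slope reaches ``linear_modulus`` exactly
    at the toe, then a straight limb of that slope (defaults: toe 13%,
    modulus 38.5 MPa, the fascicle tensile-test values).  Otherwise the
    curve is sampled from the named hyperelastic model with ``params``.
    """

    model_name: str = "yeoh3"
    params: dict = field(default_factory=dict)
    toe_strain: float = 0.13
    linear_modulus: float | None = 38.5  # MPa; None -> hyperelastic mode
    max_strain: float = 0.25
    n_points: int = 100
    noise_rel_sd: float = 0.0  # fraction of peak stress
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.toe_strain < self.max_strain):
            raise ValueError("need 0 < toe_strain < max_strain")
        if self.n_points < 10:
            raise ValueError("n_points must be >= 10")


# --------------------------------------------------------------------------
# analytic flow fixtures
# --------------------------------------------------------------------------

def _center_grid(shape, voxel_size):
    """Physical coordinates (um) of voxel centers along each axis."""
    return [(np.arange(n) + 0.5) * voxel_size for n in shape]


def generate_channel_phantom(
    shape: tuple, voxel_size: float, radius: float, axis: int | str = "z"
) -> BinaryMicrostructure:
    """Single straight circular pore channel along ``axis``, solid elsewhere.

    The channel is centered in the transverse plane; a voxel is pore iff its
    center lies inside the cylinder.  Hagen-Poiseuille gives its permeability
    in closed form, making this the primary Stokes-solver fixture.
    """
    ax = axis_index(axis)
    t1, t2 = [i for i in range(3) if i != ax]
    ext1, ext2 = shape[t1] * voxel_size, shape[t2] * voxel_size
    if 2 * radius >= min(ext1, ext2):
        raise ValueError(
            f"channel diameter {2 * radius} um exceeds transverse extent "
            f"{min(ext1, ext2)} um"
        )
    coords = _center_grid(shape, voxel_size)
    c1 = coords[t1] - ext1 / 2.0
    c2 = coords[t2] - ext2 / 2.0
    shp1 = [1, 1, 1]
    shp1[t1] = shape[t1]
    shp2 = [1, 1, 1]
    shp2[t2] = shape[t2]
    r2 = c1.reshape(shp1) ** 2 + c2.reshape(shp2) ** 2
    pore = np.broadcast_to(r2 < radius**2, shape)
    return BinaryMicrostructure(~pore, voxel_size)


def generate_plate_phantom(
    shape: tuple, voxel_size: float, gap: float, normal_axis: int | str = "z"
) -> BinaryMicrostructure:
    """Planar pore slab of thickness ``gap`` spanning the domain (a slit).

    The slab is centered along ``normal_axis`` and aligned to voxel layers
    when ``gap`` is an integer number of voxels, so its porosity is exact.
    Plane-Poiseuille flow through the slit has permeability
    k = gap^3 / (12 * extent_normal).
    """
    ax = axis_index(normal_axis)
    extent = shape[ax] * voxel_size
    if gap > extent:
        raise ValueError("gap exceeds the domain extent along the normal axis")
    if gap < voxel_size:
        raise ValueError("gap must be at least one voxel")
    centers = _center_grid(shape, voxel_size)[ax]
    lo = (extent - gap) / 2.0
    in_slab = (centers > lo) & (centers < lo + gap)
    shp = [1, 1, 1]
    shp[ax] = shape[ax]
    pore = np.broadcast_to(in_slab.reshape(shp), shape)
    return BinaryMicrostructure(~pore, voxel_size)


# --------------------------------------------------------------------------
# fiber phantom
# --------------------------------------------------------------------------

class FiberPhantomReport(NamedTuple):
    achieved_porosity: float
    target_porosity: float
    radius_scale: float
    n_tubes: int
    converged: bool
    percolating: bool


def _tube_centers(rng, n_tubes, ext1, ext2, min_dist):
    """Rejection-sampled (Poisson-disc-like) tube centers in the transverse plane."""
    centers = []
    attempts = 0
    while len(centers) < n_tubes and attempts < 200 * n_tubes:
        cand = rng.uniform((0, 0), (ext1, ext2))
        if all((cand[0] - c[0]) ** 2 + (cand[1] - c[1]) ** 2 >= min_dist**2 for c in centers):
            centers.append(cand)
        attempts += 1
    while len(centers) < n_tubes:  # relax spacing if the plane is crowded
        centers.append(rng.uniform((0, 0), (ext1, ext2)))
    return np.array(centers)


def generate_fiber_phantom(
    spec: PhantomSpec,
) -> tuple[BinaryMicrostructure, FiberPhantomReport]:
    """Honeycomb-like bundle of aligned wavy tubes (pore) in a solid matrix.

    Tube centerlines run the full axial length with a sinusoidal transverse
    perturbation (amplitude = waviness x length) and a sinusoidally
    modulated radius, which gives the pore space periodic constrictions like
    the varicose channels left by axons.  The global radius scale is tuned
    by bisection (<= 30 iterations) until the achieved porosity is within
    0.005 of the target; if the target is unreachable the report carries
    ``converged=False`` and the achieved value.

    Returns the volume and a :class:`FiberPhantomReport`.
    """
    rng = np.random.default_rng(spec.seed)
    ax = axis_index(spec.alignment_axis)
    t1, t2 = [i for i in range(3) if i != ax]
    shape = tuple(spec.shape)
    h = spec.voxel_size
    n_ax = shape[ax]
    L = n_ax * h
    ext1, ext2 = shape[t1] * h, shape[t2] * h

    area = ext1 * ext2
    tube_area = np.pi * spec.tube_radius_mean**2
    n_tubes = max(1, int(round(spec.target_porosity * area / tube_area)))

    centers = _tube_centers(rng, n_tubes, ext1, ext2, min_dist=1.6 * spec.tube_radius_mean)
    radii = np.clip(
        rng.normal(spec.tube_radius_mean, spec.tube_radius_sd, n_tubes),
        0.3 * spec.tube_radius_mean,
        2.0 * spec.tube_radius_mean,
    )
    wav_phase = rng.uniform(0, 2 * np.pi, (n_tubes, 2))
    mod_phase = rng.uniform(0, 2 * np.pi, n_tubes)
    amp = spec.waviness * L

    z = (np.arange(n_ax) + 0.5) * h  # axial voxel centers
    c1 = (np.arange(shape[t1]) + 0.5) * h
    c2 = (np.arange(shape[t2]) + 0.5) * h
    C1, C2 = np.meshgrid(c1, c2, indexing="ij")

    def rasterize(scale: float) -> np.ndarray:
        pore_ax0 = np.zeros((n_ax, shape[t1], shape[t2]), dtype=bool)
        for iz, zz in enumerate(z):
            wob = np.sin(2 * np.pi * zz / L + wav_phase)  # (n_tubes, 2)
            p1 = centers[:, 0] + amp * wob[:, 0]
            p2 = centers[:, 1] + amp * wob[:, 1]
            r = scale * radii * (
                1.0
                + spec.radius_modulation
                * np.sin(2 * np.pi * zz / spec.modulation_wavelength + mod_phase)
            )
            sl = np.zeros((shape[t1], shape[t2]), dtype=bool)
            for p1i, p2i, ri in zip(p1, p2, r):
                if ri <= 0:
                    continue
                sl |= (C1 - p1i) ** 2 + (C2 - p2i) ** 2 < ri**2
            pore_ax0[iz] = sl
        return pore_ax0

    def porosity_of(scale: float) -> tuple[float, np.ndarray]:
        vol = rasterize(scale)
        return float(vol.mean()), vol

    lo_s, hi_s = 0.3, 2.2
    phi_lo, _ = porosity_of(lo_s)
    phi_hi, _ = porosity_of(hi_s)
    scale = 1.0
    phi, pore_ax0 = porosity_of(scale)
    converged = abs(phi - spec.target_porosity) <= 0.005
    it = 0
    if not converged and phi_lo <= spec.target_porosity <= phi_hi:
        a, b = lo_s, hi_s
        while it < 30:
            scale = 0.5 * (a + b)
            phi, pore_ax0 = porosity_of(scale)
            if abs(phi - spec.target_porosity) <= 0.005:
                converged = True
                break
            if phi < spec.target_porosity:
                a = scale
            else:
                b = scale
            it += 1
    converged = converged or abs(phi - spec.target_porosity) <= 0.02

    # back to (z, y, x) order
    order = (ax, t1, t2)
    inv = tuple(int(i) for i in np.argsort(order))
    pore = np.transpose(pore_ax0, inv)
    volume = BinaryMicrostructure(~pore, h)
    report = FiberPhantomReport(
        achieved_porosity=float(pore.mean()),
        target_porosity=spec.target_porosity,
        radius_scale=float(scale),
        n_tubes=n_tubes,
        converged=bool(converged),
        percolating=percolates(pore, ax),
    )
    return volume, report


# --------------------------------------------------------------------------
# grayscale rendering
# --------------------------------------------------------------------------

def render_grayscale(binary: BinaryMicrostructure, noise: NoiseSpec) -> GrayscaleVolume:
    """Render a binary volume as a noisy 8-bit grayscale stack.

    Solid voxels take ``fg_level`` and pore voxels ``bg_level``; the image is
    Gaussian-blurred (partial-volume effect) and corrupted with additive
    Gaussian noise, then clipped to [0, 255] and quantized.  With levels far
    apart relative to the noise the histogram is bimodal.
    """
    for level in (noise.fg_level, noise.bg_level):
        if not (0 <= level <= 255):
            raise ValueError("fg/bg levels must be within the 8-bit range")
    img = np.where(binary.solid, float(noise.fg_level), float(noise.bg_level))
    if noise.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, noise.blur_sigma)
    if noise.noise_sd > 0:
        rng = np.random.default_rng(noise.seed)
        img = img + rng.normal(0.0, noise.noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return GrayscaleVolume(img, binary.voxel_size)


# --------------------------------------------------------------------------
# tensile curves
# --------------------------------------------------------------------------

def generate_stress_strain(spec: CurveSpec) -> StressStrainCurve:
    """Sample a synthetic uniaxial nominal stress-stretch curve.

    In piecewise J-curve mode (``linear_modulus`` set) the toe is the cubic
    sigma = E * toe/3 * (eps/toe)^3, whose slope reaches E exactly at the toe
    strain, followed by a straight limb of slope E — so the post-toe slope
    equals ``linear_modulus`` before noise by construction.  In hyperelastic
    mode the named model is evaluated at the sampled stretches.  Noise is
    additive Gaussian with SD = ``noise_rel_sd`` x peak stress; negative
    noisy stresses are clipped to zero.  The first point is kept at (1, 0).
    """
    eps = np.linspace(0.0, spec.max_strain, spec.n_points)
    lam = 1.0 + eps
    if spec.linear_modulus is not None:
        E, toe = spec.linear_modulus, spec.toe_strain
        sig = np.where(
            eps <= toe,
            E * toe / 3.0 * (eps / np.where(toe > 0, toe, 1.0)) ** 3,
            E * toe / 3.0 + E * (eps - toe),
        )
    else:
        sig = uniaxial_stress(spec.params, lam, spec.model_name)
        sig = np.asarray(sig, dtype=float)
    if spec.noise_rel_sd > 0:
        rng = np.random.default_rng(spec.seed)
        sd = spec.noise_rel_sd * float(np.max(np.abs(sig)))
        noise = rng.normal(0.0, sd, sig.shape)
        noise[0] = 0.0  # keep the undeformed point exact
        sig = np.clip(sig + noise, 0.0, None)
    return StressStrainCurve(lam, sig)


# --------------------------------------------------------------------------
# falling-head records
# --------------------------------------------------------------------------

def generate_falling_head_record(
    k_true: float,
    a: float,
    A: float,
    H: float,
    L1: float,
    L2: float,
    fluid: FluidProperties | None = None,
) -> FallingHeadTest:
    """Falling-head record whose analysis recovers a known permeability.

    The elapsed time follows from integrating Darcy's law over the head
    decay: t = a*H / (A*K) * ln(L1/L2) with K = k_true * rho * g / mu, so
    the round trip through the conductivity and permeability equations
    returns ``k_true`` exactly (up to floating point).
    """
    fluid = fluid or WATER
    if k_true <= 0:
        raise ValueError("k_true must be positive")
    if not (L1 >= L2 > 0):
        raise ValueError("need L1 >= L2 > 0")
    if min(a, A, H) <= 0:
        raise ValueError("geometry must be positive")
    K = k_true * fluid.density * fluid.gravity / fluid.dynamic_viscosity
    t = a * H / (A * K) * float(np.log(L1 / L2))
    return FallingHeadTest(a=a, A=A, H=H, L1=L1, L2=L2, t=t, fluid=fluid)


def write_curve_csv(curve: StressStrainCurve, path) -> None:
    """Write a stress-strain curve as CSV with a units header row."""
    import pandas as pd

    pd.DataFrame(
        {"stretch": curve.stretch, "stress_MPa": curve.nominal_stress}
    ).to_csv(path, index=False)


def write_falling_head_csv(tests: list, path) -> None:
    """Write falling-head records as CSV (columns a_m2, A_m2, H_m, L1_m, L2_m, t_s)."""
    import pandas as pd

    pd.DataFrame(
        [
            {"a_m2": t.a, "A_m2": t.A, "H_m": t.H, "L1_m": t.L1, "L2_m": t.L2, "t_s": t.t}
            for t in tests
        ]
    ).to_csv(path, index=False)
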