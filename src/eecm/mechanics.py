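"""Uniaxial tensile-curve analysis and hyperelastic constitutive fitting.

Soft fibrous tissues load along a J-shaped nominal stress-stretch curve: a
compliant toe region where crimped fibrils straighten, followed by a nearly
linear region whose slope is the tissue's operating Young's modulus.  This
module extracts that linear modulus and toe strain, fits incompressible
hyperelastic models (neo-Hookean, Mooney-Rivlin, first-order Ogden and
third-order Yeoh) to measured curves by least squares, ranks them by mean
squared error with a stability check, and converts macroscopic tensile loads
to representative-volume-element (RVE) loads at equal stress.

Nominal (first Piola-Kirchhoff) stress is used throughout: machine force
divided by the undeformed cross-section.  Uniaxial incompressible closed
forms, with I1 = lambda^2 + 2/lambda:

* neo-Hookean     sigma = 2(l - l^-2) C10
* Mooney-Rivlin   sigma = 2(l - l^-2) (C10 + C01 / l)
* Yeoh (3rd)      sigma = 2(l - l^-2) [C10 + 2 C20 (I1-3) + 3 C30 (I1-3)^2]
* Ogden (1st)     sigma = 2 mu1/alpha1 (l^(alpha1-1) - l^(-alpha1/2-1))

Small-strain Young's moduli: 6 C10, 6 (C10+C01), 6 C10, 3 mu1 respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

MODEL_COEFFS = {
    "neo_hookean": ("C10",),
    "mooney_rivlin": ("C10", "C01"),
    "yeoh3": ("C10", "C20", "C30"),
    "ogden1": ("mu1", "alpha1"),
}


@dataclass
class StressStrainCurve:
    """Paired stretch / nominal-stress samples from a uniaxial test.

    ``stretch`` is the axial stretch ratio (>= 1, strictly increasing); a
    first point (1, 0) is prepended if missing.  Stress is in MPa.
    """

    stretch: np.ndarray
    nominal_stress: np.ndarray
    gauge_length_mm: float | None = None
    diameter_mm: float | None = None
    strain_rate_mm_min: float | None = None

    def __post_init__(self) -> None:
        lam = np.asarray(self.stretch, dtype=float)
        sig = np.asarray(self.nominal_stress, dtype=float)
        if lam.shape != sig.shape or lam.ndim != 1:
            raise ValueError("stretch and stress must be 1D arrays of equal length")
        if lam[0] > 1.0 + 1e-12:
            lam = np.concatenate([[1.0], lam])
            sig = np.concatenate([[0.0], sig])
        if np.any(np.diff(lam) <= 0):
            raise ValueError("stretch must be strictly increasing")
        if np.any(sig < 0):
            raise ValueError("nominal stress must be non-negative")
        self.stretch = lam
        self.nominal_stress = sig

    @property
    def strain(self) -> np.ndarray:
        return self.stretch - 1.0

    @classmethod
    def from_csv(cls, path) -> "StressStrainCurve":
        """Read a CSV with columns ``stretch`` (or ``strain``) and ``stress_MPa``."""
        import pandas as pd

        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "stretch" in cols:
            lam = df[cols["stretch"]].to_numpy(float)
        elif "strain" in cols:
            lam = 1.0 + df[cols["strain"]].to_numpy(float)
        else:
            raise ValueError("CSV needs a 'stretch' or 'strain' column")
        stress_col = next((c for k, c in cols.items() if k.startswith("stress")), None)
        if stress_col is None:
            raise ValueError("CSV needs a 'stress_MPa' column")
        return cls(lam, df[stress_col].to_numpy(float))


@dataclass
class HyperelasticParams:
    """Fitted coefficients of one incompressible hyperelastic model."""

    model_name: str
    coefficients: dict
    fit_mse: float = 0.0
    stable: bool = True

    @property
    def small_strain_modulus(self) -> float:
        c = self.coefficients
        if self.model_name == "neo_hookean":
            return 6.0 * c["C10"]
        if self.model_name == "mooney_rivlin":
            return 6.0 * (c["C10"] + c["C01"])
        if self.model_name == "yeoh3":
            return 6.0 * c["C10"]
        if self.model_name == "ogden1":
            return 3.0 * c["mu1"]
        raise ValueError(f"unknown model {self.model_name!r}")


def uniaxial_stress(params: HyperelasticParams | dict, lam, model_name: str | None = None):
    """Nominal uniaxial stress (MPa) of an incompressible model at stretch ``lam``."""
    if isinstance(params, HyperelasticParams):
        name, c = params.model_name, params.coefficients
    else:
        if model_name is None:
            raise ValueError("model_name required when passing a coefficient dict")
        name, c = model_name, params
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    base = 2.0 * (lam - lam**-2)
    if name == "neo_hookean":
        out = base * c["C10"]
    elif name == "mooney_rivlin":
        out = base * (c["C10"] + c["C01"] / lam)
    elif name == "yeoh3":
        i1m3 = lam**2 + 2.0 / lam - 3.0
        out = base * (c["C10"] + 2.0 * c["C20"] * i1m3 + 3.0 * c["C30"] * i1m3**2)
    elif name == "ogden1":
        mu, al = c["mu1"], c["alpha1"]
        out = 2.0 * mu / al * (lam ** (al - 1.0) - lam ** (-al / 2.0 - 1.0))
    else:
        raise ValueError(f"unknown model {name!r}")
    return out if out.shape else float(out)


def _tangent_positive(params: HyperelasticParams, lam_lo: float, lam_hi: float) -> bool:
    lam = np.linspace(max(lam_lo, 1.0), lam_hi, 200)
    d = 1e-6
    slope = (uniaxial_stress(params, lam + d) - uniaxial_stress(params, lam - d)) / (2 * d)
    return bool(np.all(slope > 0))


def fit_hyperelastic(curve: StressStrainCurve, model_name: str) -> HyperelasticParams:
    """Least-squares fit of a model's uniaxial closed form to a tensile curve.

    Models linear in their coefficients (neo-Hookean, Mooney-Rivlin, Yeoh)
    are fitted by ordinary linear least squares on the exact design matrix;
    the Ogden model by nonlinear least squares seeded from the initial slope.
    The stability flag records whether the fitted tangent modulus stays
    positive over the data range.
    """
    names = MODEL_COEFFS.get(model_name)
    if names is None:
        raise ValueError(f"unknown model {model_name!r}")
    lam = curve.stretch
    sig = curve.nominal_stress
    if lam.size < 2 * len(names):
        raise ValueError(
            f"need at least {2 * len(names)} points to fit {model_name} "
            f"({len(names)} coefficients), got {lam.size}"
        )
    base = 2.0 * (lam - lam**-2)
    if model_name in ("neo_hookean", "mooney_rivlin", "yeoh3"):
        if model_name == "neo_hookean":
            X = base[:, None]
        elif model_name == "mooney_rivlin":
            X = np.column_stack([base, base / lam])
        else:
            i1m3 = lam**2 + 2.0 / lam - 3.0
            X = np.column_stack([base, 2.0 * base * i1m3, 3.0 * base * i1m3**2])
        coef, *_ = np.linalg.lstsq(X, sig, rcond=None)
        resid = X @ coef - sig
        coefficients = dict(zip(names, (float(v) for v in coef)))
    else:  # ogden1
        # seed: small-strain modulus from the first decade of points
        k = max(3, lam.size // 10)
        e0 = max(np.polyfit(lam[:k] - 1.0, sig[:k], 1)[0], 1e-6)
        x0 = np.array([e0 / 3.0, 2.0])

        def residual(x):
            return uniaxial_stress({"mu1": x[0], "alpha1": x[1]}, lam, "ogden1") - sig

        res = optimize.least_squares(residual, x0, bounds=([1e-12, 0.05], [np.inf, 60.0]))
        if not res.success:
            raise RuntimeError(f"ogden1 fit did not converge: {res.message}")
        resid = res.fun
        coefficients = {"mu1": float(res.x[0]), "alpha1": float(res.x[1])}
    params = HyperelasticParams(model_name, coefficients, fit_mse=float(np.mean(resid**2)))
    params.stable = _tangent_positive(params, float(lam.min()), float(lam.max()))
    return params


def select_best_model(
    curve: StressStrainCurve,
    candidates=("neo_hookean", "mooney_rivlin", "ogden1", "yeoh3"),
    tie_rel_tol: float = 0.05,
) -> list[HyperelasticParams]:
    """Fit all candidate models and rank them.

    Stable fits come first, ordered by MSE; among stable fits whose MSE is
    within ``tie_rel_tol`` (relative) of the best, the model with the fewest
    coefficients wins — a nested richer model never loses on MSE, so the tie
    rule is what lets the generating special case be recovered.  Unstable
    fits follow, also by MSE.  The selected model is the first list entry.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate model")
    fits, failures = [], []
    for name in candidates:
        try:
            fits.append(fit_hyperelastic(curve, name))
        except Exception as exc:  # noqa: BLE001 - collected as diagnostics
            failures.append(f"{name}: {exc}")
    if not fits:
        raise RuntimeError("all model fits failed: " + "; ".join(failures))
    stable = sorted((f for f in fits if f.stable), key=lambda f: f.fit_mse)
    unstable = sorted((f for f in fits if not f.stable), key=lambda f: f.fit_mse)
    if stable:
        best_mse = stable[0].fit_mse
        floor = (1e-9 * float(np.max(curve.nominal_stress, initial=0.0))) ** 2
        tied = [f for f in stable if f.fit_mse <= best_mse * (1.0 + tie_rel_tol) + floor]
        chosen = min(tied, key=lambda f: (len(f.coefficients), f.fit_mse))
        stable.remove(chosen)
        stable.insert(0, chosen)
    return stable + unstable


@dataclass
class LinearRegionFit:
    """Post-toe linear-region fit of a J-shaped tensile curve."""

    modulus: float  # MPa, slope of stress vs engineering strain
    toe_strain: float  # strain where the linear window begins
    r_squared: float
    window: tuple[int, int]  # [start, stop) point indices
    reached_r2: bool  # False if no window met the R^2 criterion


def linear_region_modulus(
    curve: StressStrainCurve,
    min_window_frac: float = 0.3,
    r2_threshold: float = 0.99,
) -> LinearRegionFit:
    """Identify the post-toe linear region and its Young's modulus.

    Two stages.  (1) Sliding windows are scanned from the widest down; the
    widest window (at least ``min_window_frac`` of the points) reaching
    R^2 >= ``r2_threshold`` locates the linear region.  (2) Because a wide
    window tolerates a gently curving tail, the toe boundary is then refined:
    scanning from high strain down, the toe is placed where the residual from
    the window's regression line first exceeds max(3 x window residual RMS,
    0.5% of peak stress), and the modulus is refit on the points above that
    boundary.  A purely linear curve refines to toe 0 and the exact slope.
    If no window reaches the threshold the best one is returned with
    ``reached_r2=False``.
    """
    eps = curve.strain
    sig = curve.nominal_stress
    n = eps.size
    if n < 10:
        raise ValueError("need at least 10 points")
    w_min = max(4, int(np.ceil(min_window_frac * n)))

    found = None  # (r2, slope, intercept, start, w, reached)
    best = None
    for w in range(n, w_min - 1, -1):
        for s in range(0, n - w + 1):
            x = eps[s : s + w]
            y = sig[s : s + w]
            sxx = np.var(x)
            syy = np.var(y)
            if sxx == 0 or syy == 0:
                continue
            sxy = np.mean((x - x.mean()) * (y - y.mean()))
            r2 = sxy * sxy / (sxx * syy)
            cand = (float(r2), float(sxy / sxx), s, w)
            if best is None or r2 > best[0]:
                best = cand
        if best is not None and best[0] >= r2_threshold and best[3] == w:
            found = best
            break
    if found is None:
        import warnings

        r2_best = best[0] if best else float("nan")
        warnings.warn(
            f"no window reached R^2 >= {r2_threshold}; returning best (R^2={r2_best:.4f})",
            stacklevel=2,
        )
        found = best
    r2, slope, s, w = found
    # reference line from the upper half of the window, which is clear of
    # any toe curvature the wide window may have tolerated
    s_top = s + w // 2 if (n - (s + w // 2)) >= 5 else s
    coeffs = np.polyfit(eps[s_top : s + w], sig[s_top : s + w], 1)
    slope, intercept = float(coeffs[0]), float(coeffs[1])

    # refine the toe boundary against that reference line
    resid = np.abs(sig - (intercept + slope * eps))
    rms = float(np.sqrt(np.mean(resid[s_top : s + w] ** 2)))
    thresh = max(3.0 * rms, 0.005 * float(sig.max(initial=0.0)))
    toe_idx = 0
    for i in range(min(s + w, n) - 1, -1, -1):
        # two consecutive exceedances so a lone noise spike cannot set the toe
        if resid[i] > thresh and (i == 0 or resid[i - 1] > thresh):
            toe_idx = min(i + 1, n - 1)
            break
    if toe_idx > 0 and n - toe_idx >= 3:
        coeffs = np.polyfit(eps[toe_idx:], sig[toe_idx:], 1)
        slope = float(coeffs[0])
    return LinearRegionFit(
        modulus=float(slope),
        toe_strain=float(eps[toe_idx]),
        r_squared=float(r2),
        window=(toe_idx, n),
        reached_r2=bool(found is not None and r2 >= r2_threshold),
    )


def scale_load_to_rve(F_macro: float, A_macro: float, A_rve: float) -> float:
    """Load on an RVE producing the same stress as ``F_macro`` on ``A_macro``."""
    if A_macro <= 0 or A_rve <= 0:
        raise ValueError("areas must be positive")
    return F_macro * A_rve / A_macro


# re-export the voxel homogenization API so the mechanics surface is complete
from .elasticity import (  # noqa: E402,F401
    HomogenizationResult,
    calibrate_solid_modulus,
    homogenize_effective_moduli,
)
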