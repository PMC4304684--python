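"""Equilibrium binding analysis for surface-biosensor (DPI-style) data.

Saturated equilibrium responses (mass, phase or density change) as a
function of ligand concentration are fitted with Langmuir saturation models:

    one site:  R(C) = Rmax C / (Kd + C)
    two site:  R(C) = Rmax1 C / (Kd1 + C) + Rmax2 C / (Kd2 + C)

Dissociation constants are handled internally in uM and log-parameterised so
positivity is structural.  The two models are nested, so "does a second site
improve the fit?" is answered by an extra-sum-of-squares F-test (alpha 0.05),
with small-sample AICc reported alongside.

The module also books adsorbed-layer quantities: given a resolved layer
thickness and refractive index, the de Feijter relation converts the
refractive-index excess over buffer into protein density, and density times
thickness gives the areal mass of the layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

from .errors import ValidationError

__all__ = [
    "BindingIsotherm",
    "OneSiteFit",
    "TwoSiteFit",
    "ModelChoice",
    "LayerState",
    "langmuir_one_site",
    "langmuir_two_site",
    "fit_one_site",
    "fit_two_site",
    "select_model",
    "layer_metrics",
]

_UNIT_TO_UM = {"M": 1e6, "mM": 1e3, "uM": 1.0, "µM": 1.0}


def langmuir_one_site(c, kd: float, rmax: float):
    """Single-site Langmuir saturation response."""
    c = np.asarray(c, dtype=float)
    return rmax * c / (kd + c)


def langmuir_two_site(c, kd1: float, kd2: float, rmax1: float, rmax2: float):
    """Sum of two independent Langmuir sites."""
    c = np.asarray(c, dtype=float)
    return rmax1 * c / (kd1 + c) + rmax2 * c / (kd2 + c)


@dataclass(frozen=True)
class BindingIsotherm:
    """Concentration (uM, strictly increasing) vs equilibrium response."""

    concentrations: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "responses", r)
        if c.size != r.size:
            raise ValidationError("concentration and response lengths differ")
        if c.size < 4:
            raise ValidationError("need at least 4 points")
        if np.any(c <= 0):
            raise ValidationError("concentrations must be positive")
        if np.any(np.diff(c) <= 0):
            raise ValidationError("concentrations must be strictly increasing")
        if not (np.isfinite(c).all() and np.isfinite(r).all()):
            raise ValidationError("non-finite values in isotherm")

    def __len__(self) -> int:
        return int(self.concentrations.size)

    @classmethod
    def from_values(cls, concentrations, responses, unit: str = "uM"):
        """Build an isotherm, normalising concentrations to uM."""
        if unit not in _UNIT_TO_UM:
            raise ValidationError(f"unknown concentration unit {unit!r}")
        c = np.asarray(concentrations, dtype=float) * _UNIT_TO_UM[unit]
        r = np.asarray(responses, dtype=float)
        order = np.argsort(c)
        return cls(concentrations=c[order], responses=r[order])


@dataclass(frozen=True)
class OneSiteFit:
    kd: float      # uM
    rmax: float    # response units
    rss: float
    converged: bool

    def predict(self, c):
        return langmuir_one_site(c, self.kd, self.rmax)


@dataclass(frozen=True)
class TwoSiteFit:
    kd1: float     # uM, kd1 <= kd2
    kd2: float
    rmax1: float
    rmax2: float
    rss: float
    converged: bool

    def predict(self, c):
        return langmuir_two_site(c, self.kd1, self.kd2, self.rmax1, self.rmax2)


@dataclass(frozen=True)
class ModelChoice:
    """Outcome of the nested one-site vs two-site comparison."""

    chosen: str          # "one_site" or "two_site"
    f_statistic: float
    p_value: float
    aicc_one: float
    aicc_two: float


def fit_one_site(iso: BindingIsotherm) -> OneSiteFit:
    """Fit the single-site Langmuir model by nonlinear least squares.

    Initialisation: Kd at the concentration where the response first reaches
    half its maximum, Rmax at 1.1x the maximum response.  Parameters are
    fitted on a log scale, enforcing positivity.  Non-convergence is flagged
    on the result rather than raised.
    """
    c, r = iso.concentrations, iso.responses
    rmax0 = 1.1 * float(r.max())
    if rmax0 <= 0:
        rmax0 = 1.0
    half = 0.5 * float(r.max())
    above = np.nonzero(r >= half)[0]
    kd0 = float(c[above[0]]) if above.size else float(np.median(c))

    def resid(theta):
        kd, rmax = np.exp(np.clip(theta, -40.0, 40.0))
        return langmuir_one_site(c, kd, rmax) - r

    sol = least_squares(resid, np.log([kd0, rmax0]), method="lm")
    kd, rmax = np.exp(sol.x)
    rss = float(np.sum(sol.fun**2))
    return OneSiteFit(kd=float(kd), rmax=float(rmax), rss=rss,
                      converged=bool(sol.success))


def fit_two_site(iso: BindingIsotherm, n_starts: int = 8, seed: int = 0) -> TwoSiteFit:
    """Fit the two-site Langmuir model with multistart least squares.

    The sum of two saturation terms has local minima (sites can swap or
    collapse), so at least five seeded starts spread over the concentration
    range are refined and the lowest residual sum of squares wins.  Sites are
    reported ordered kd1 <= kd2.
    """
    c, r = iso.concentrations, iso.responses
    if len(iso) < 6:
        raise ValidationError("two-site fit needs at least 6 points")
    n_starts = max(5, int(n_starts))
    rng = np.random.default_rng(seed)
    rtop = max(float(r.max()), 1e-12)
    lo, hi = np.log(c.min()), np.log(c.max())

    starts = [np.log([np.exp(lo + 0.25 * (hi - lo)), np.exp(lo + 0.75 * (hi - lo)),
                      0.55 * rtop, 0.55 * rtop])]
    for _ in range(n_starts - 1):
        k1, k2 = np.sort(np.exp(rng.uniform(lo, hi, size=2)))
        a1, a2 = rng.uniform(0.2, 1.0, size=2) * rtop
        starts.append(np.log([k1, k2, a1, a2]))

    def resid(theta):
        kd1, kd2, rm1, rm2 = np.exp(np.clip(theta, -40.0, 40.0))
        return langmuir_two_site(c, kd1, kd2, rm1, rm2) - r

    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, method="lm", max_nfev=2000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        return TwoSiteFit(np.nan, np.nan, np.nan, np.nan, np.inf, converged=False)
    rss, sol = best
    kd1, kd2, rm1, rm2 = np.exp(np.clip(sol.x, -40.0, 40.0))
    if kd1 > kd2:
        kd1, kd2, rm1, rm2 = kd2, kd1, rm2, rm1
    return TwoSiteFit(kd1=float(kd1), kd2=float(kd2), rmax1=float(rm1),
                      rmax2=float(rm2), rss=rss, converged=bool(sol.success))


def _aicc(rss: float, n: int, k: int) -> float:
    # Gaussian log-likelihood up to a constant; k counts the variance too
    if n - k - 1 <= 0:
        return np.inf
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    return aic + 2 * k * (k + 1) / (n - k - 1)


def select_model(one: OneSiteFit, two: TwoSiteFit, n_points: int,
                 alpha: float = 0.05) -> ModelChoice:
    """Choose between nested one- and two-site fits of the same data.

    Extra-sum-of-squares F-test with 2 extra parameters at ``alpha``; AICc
    for both models is reported for reference.  Refuses isotherms with 5 or
    fewer points (the two-site model would leave <= 1 residual degree of
    freedom).
    """
    if n_points <= 5:
        raise ValidationError("model comparison needs more than 5 points")
    if not (one.converged and two.converged):
        raise ValidationError("both fits must have converged")
    df2 = n_points - 4
    rss1, rss2 = one.rss, two.rss
    if rss2 <= 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = max(0.0, (rss1 - rss2) / 2.0) / (rss2 / df2)
        p = float(f_dist.sf(f_stat, 2, df2))
    chosen = "two_site" if p < alpha else "one_site"
    return ModelChoice(chosen=chosen, f_statistic=float(f_stat), p_value=p,
                       aicc_one=_aicc(rss1, n_points, 3),
                       aicc_two=_aicc(rss2, n_points, 5))


@dataclass(frozen=True)
class LayerState:
    """Adsorbed-layer bookkeeping: thickness, indices, density, areal mass."""

    thickness: float   # nm
    n_layer: float
    n_buffer: float
    density: float     # g/cm^3 (== g/ml)
    areal_mass: float  # ng/mm^2


def layer_metrics(thickness: float, n_layer: float, n_buffer: float,
                  dn_dc: float = 0.182) -> LayerState:
    """Compute layer density and areal mass from thickness and refractive index.

    The de Feijter relation gives the protein density of the layer as
    ``(n_layer - n_buffer) / dn_dc`` (g/ml) with the refractive-index
    increment ``dn_dc`` in ml/g (0.182 is the standard protein value).  The
    areal mass is density x thickness; in g/cm^3 x nm the conversion to
    ng/mm^2 is exactly 1.
    """
    if thickness < 0:
        raise ValidationError("thickness must be non-negative")
    if n_layer < n_buffer:
        raise ValidationError("layer index below buffer index")
    if dn_dc <= 0:
        raise ValidationError("dn_dc must be positive")
    density = (n_layer - n_buffer) / dn_dc
    areal_mass = density * thickness  # (g/cm^3) * nm == ng/mm^2
    return LayerState(thickness=thickness, n_layer=n_layer, n_buffer=n_buffer,
                      density=density, areal_mass=areal_mass)


def areal_mass(thickness: float, density: float) -> float:
    """Areal mass (ng/mm^2) of a layer of given thickness (nm) and density (g/cm^3)."""
    if thickness < 0 or density < 0:
        raise ValidationError("thickness and density must be non-negative")
    return density * thickness
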