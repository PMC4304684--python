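"""Synthetic melt curves, plates and binding isotherms with known ground truth.

The melt-curve model is the standard two-state van't Hoff unfolding
equilibrium: the unfolded fraction is

    fu(T) = 1 / (1 + exp[(dH_vH / R) (1/T - 1/Tm)]),   T in kelvin,

which equals 1/2 at Tm and sharpens with the van't Hoff enthalpy.  The
simulated fluorescence superimposes a (optionally sloped) native baseline, a
bright unfolded state and an exponential post-transition quench that mimics
dye loss upon aggregation, reproducing the rise-then-fall shape of real
Thermofluor traces.  The default temperature grid is a 1 degC ramp from 24 to
95 degC, the hold-per-degree protocol of a standard qPCR instrument.

All generators draw noise from a :class:`numpy.random.Generator` seeded
explicitly, so every fixture is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .melt_core import MeltCurve

__all__ = [
    "GAS_CONSTANT_KJ",
    "SynthParams",
    "fraction_unfolded",
    "two_state_curve",
    "two_transition_curve",
    "flat_curve",
    "synth_plate",
    "synth_isotherm",
]

#: Molar gas constant in kJ mol^-1 K^-1.
GAS_CONSTANT_KJ = 8.31446261815324e-3

_ZERO_C_IN_K = 273.15


@dataclass(frozen=True)
class SynthParams:
    """Ground-truth parameters of a simulated melt curve.

    ``tm`` is the transition midpoint (degC) and ``dh_vh`` the van't Hoff
    enthalpy (kJ/mol) controlling its width.  ``f_native``/``f_unfolded`` are
    the baseline fluorescence of folded and unfolded protein, ``native_slope``
    a linear drift of the folded baseline, ``quench_rate`` the exponential
    decay (per degC) of the unfolded signal past the end of the transition,
    and ``noise_sd`` the additive Gaussian noise level in fluorescence units.
    """

    tm: float = 60.0
    dh_vh: float = 400.0
    f_native: float = 1000.0
    f_unfolded: float = 10000.0
    native_slope: float = 0.0
    quench_rate: float = 0.0
    noise_sd: float = 0.0
    t_start: float = 24.0
    t_end: float = 95.0
    t_step: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dh_vh <= 0:
            raise ValidationError("dh_vh must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.t_step <= 0 or self.t_end <= self.t_start:
            raise ValidationError("invalid temperature grid")

    def grid(self) -> np.ndarray:
        return np.arange(self.t_start, self.t_end + self.t_step / 2, self.t_step)


def fraction_unfolded(t, tm: float, dh_vh: float):
    """Unfolded fraction of a two-state unfolding equilibrium.

    Parameters are the temperature(s) ``t`` and midpoint ``tm`` in degC and
    the van't Hoff enthalpy ``dh_vh`` in kJ/mol.  Strictly increasing in
    ``t`` and exactly 1/2 at ``tm``.
    """
    t_k = np.asarray(t, dtype=float) + _ZERO_C_IN_K
    tm_k = tm + _ZERO_C_IN_K
    exponent = (dh_vh / GAS_CONSTANT_KJ) * (1.0 / t_k - 1.0 / tm_k)
    with np.errstate(over="ignore"):  # far below Tm the exponent saturates
        out = 1.0 / (1.0 + np.exp(exponent))
    return out if out.ndim else float(out)


def _signal(params: SynthParams, t: np.ndarray, fu: np.ndarray) -> np.ndarray:
    native = params.f_native + params.native_slope * (t - params.t_start)
    unfolded = np.full_like(t, params.f_unfolded, dtype=float)
    if params.quench_rate > 0:
        above = fu > 0.99
        if above.any():
            t_agg = t[above][0]  # aggregation onset: transition essentially over
            unfolded = unfolded * np.exp(-params.quench_rate * np.maximum(0.0, t - t_agg))
    return native * (1.0 - fu) + unfolded * fu


def two_state_curve(
    params: SynthParams, well_id: str = "A1"
) -> tuple[MeltCurve, dict]:
    """Simulate a single-transition melt curve.

    Returns the curve and a ground-truth record (true Tm, enthalpy, seed).
    Deterministic per seed.
    """
    t = params.grid()
    fu = fraction_unfolded(t, params.tm, params.dh_vh)
    f = _signal(params, t, fu)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        f = f + rng.normal(0.0, params.noise_sd, size=t.size)
    truth = {"well_id": well_id, "tm": params.tm, "tm2": None,
             "dh_vh": params.dh_vh, "seed": params.seed}
    return MeltCurve(well_id, t, f), truth


def two_transition_curve(
    params: SynthParams,
    tm2: float,
    dh_vh2: float | None = None,
    weight: float = 0.5,
    well_id: str = "A1",
) -> tuple[MeltCurve, dict]:
    """Simulate a two-step melt: a weighted sum of two unfolding transitions."""
    if not (0.0 < weight < 1.0):
        raise ValidationError("weight must lie in (0, 1)")
    t = params.grid()
    fu1 = fraction_unfolded(t, params.tm, params.dh_vh)
    fu2 = fraction_unfolded(t, tm2, dh_vh2 if dh_vh2 is not None else params.dh_vh)
    fu = weight * fu1 + (1.0 - weight) * fu2
    f = _signal(params, t, fu)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        f = f + rng.normal(0.0, params.noise_sd, size=t.size)
    truth = {"well_id": well_id, "tm": min(params.tm, tm2), "tm2": max(params.tm, tm2),
             "dh_vh": params.dh_vh, "seed": params.seed}
    return MeltCurve(well_id, t, f), truth


def flat_curve(params: SynthParams, well_id: str = "A1") -> tuple[MeltCurve, dict]:
    """Simulate a no-signal well: flat baseline plus noise, no transition."""
    t = params.grid()
    f = np.full_like(t, params.f_native, dtype=float)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        f = f + rng.normal(0.0, params.noise_sd, size=t.size)
    truth = {"well_id": well_id, "tm": None, "tm2": None,
             "dh_vh": None, "seed": params.seed}
    return MeltCurve(well_id, t, f), truth


# ---------------------------------------------------------------------------
# plate-level generators

_ROWS = "ABCDEFGH"

#: pH -> true Tm map used by the ``ph_gradient`` layout: a smooth, peaked
#: stability profile with an optimum near neutral pH, emulating a typical
#: enzyme's bell-shaped pH-stability curve.
def _tm_of_ph(ph: np.ndarray | float, tm_opt: float = 72.0,
              ph_opt: float = 7.0, width: float = 2.5) -> np.ndarray | float:
    return tm_opt - 12.0 * ((np.asarray(ph, dtype=float) - ph_opt) / width) ** 2


def synth_plate(layout: str, seed: int = 0, noise_fraction: float = 0.01):
    """Generate a matched 96-well plate, screen table and ground-truth table.

    Layouts
    -------
    ``ph_gradient``
        Rows sweep pH 4..10; true Tm follows a bell-shaped pH-stability
        profile.  Wells carry ``ph25`` so pH profiles can be reconstructed.
    ``dilution_series``
        Each row is a 12-well two-fold serial dilution of one additive
        starting at 10 mM; the additive shifts Tm up with saturating
        (Langmuir-like, EC50 50 uM) concentration dependence, row H is an
        additive-free reference row.
    ``mixed``
        A pH gradient with interleaved no-signal and two-step wells,
        exercising every quality flag.

    Returns
    -------
    (plate, screen_rows, truth)
        ``plate``: dict well -> MeltCurve; ``screen_rows``: list of dicts in
        the screen CSV schema; ``truth``: list of ground-truth dicts.
    """
    if layout not in {"ph_gradient", "dilution_series", "mixed"}:
        raise ValidationError(f"unknown layout {layout!r}")
    rng = np.random.default_rng(seed)
    base = SynthParams()
    noise_sd = noise_fraction * (base.f_unfolded - base.f_native)
    plate: dict[str, MeltCurve] = {}
    screen_rows: list[dict] = []
    truth: list[dict] = []

    for ri, row in enumerate(_ROWS):
        for ci in range(1, 13):
            well = f"{row}{ci}"
            wseed = int(rng.integers(0, 2**31 - 1))
            p = replace(base, noise_sd=noise_sd, seed=wseed, quench_rate=0.05)

            if layout in {"ph_gradient", "mixed"}:
                ph = 4.0 + 6.0 * (ri * 12 + ci - 1) / 95.0
                tm = float(_tm_of_ph(ph))
                role = "reference" if well == "A1" else "sample"
                screen_rows.append({
                    "well": well, "component": "universal buffer",
                    "concentration": 0.1, "unit": "M", "ph25": round(ph, 2),
                    "dpka_per_degc": 0.0, "role": role,
                })
                if layout == "mixed" and row == "F":
                    curve, rec = flat_curve(p, well)
                elif layout == "mixed" and well in {"D1", "D7"}:
                    curve, rec = two_transition_curve(
                        replace(p, tm=50.0), 72.0, well_id=well)
                else:
                    curve, rec = two_state_curve(replace(p, tm=tm), well)
            else:  # dilution_series
                conc_mm = 10.0 / 2.0 ** (ci - 1)  # 10 mM halved across the row
                species = f"additive{ri + 1}"
                if row == "H":
                    role, comp = "reference", None
                else:
                    role, comp = "sample", species
                if comp is None:
                    screen_rows.append({
                        "well": well, "component": "", "concentration": "",
                        "unit": "", "ph25": "", "dpka_per_degc": "", "role": role,
                    })
                    tm = base.tm
                else:
                    screen_rows.append({
                        "well": well, "component": comp,
                        "concentration": conc_mm, "unit": "mM", "ph25": "",
                        "dpka_per_degc": "", "role": role,
                    })
                    conc_um = conc_mm * 1e3
                    tm = base.tm + 8.0 * conc_um / (50.0 + conc_um)  # saturating shift
                curve, rec = two_state_curve(replace(p, tm=tm), well)

            plate[well] = curve
            truth.append(rec)
    return plate, screen_rows, truth


# ---------------------------------------------------------------------------
# binding isotherms

def synth_isotherm(
    model: str,
    params: dict,
    concentrations,
    noise_fraction: float = 0.0,
    seed: int = 0,
):
    """Generate a Langmuir binding isotherm with multiplicative Gaussian noise.

    ``model`` is ``"one_site"`` (params ``kd``, ``rmax``) or ``"two_site"``
    (params ``kd1``, ``kd2``, ``rmax1``, ``rmax2``); concentrations are in uM.
    Returns a :class:`meltshift.dpi_binding.BindingIsotherm` plus the truth
    record.  Deterministic per seed.
    """
    from .dpi_binding import BindingIsotherm, langmuir_one_site, langmuir_two_site

    c = np.sort(np.asarray(concentrations, dtype=float))
    if np.any(c <= 0):
        raise ValidationError("concentrations must be positive")
    if model == "one_site":
        kd, rmax = float(params["kd"]), float(params["rmax"])
        if kd <= 0 or rmax <= 0:
            raise ValidationError("kd and rmax must be positive")
        r = langmuir_one_site(c, kd, rmax)
    elif model == "two_site":
        kd1, kd2 = float(params["kd1"]), float(params["kd2"])
        rmax1, rmax2 = float(params["rmax1"]), float(params["rmax2"])
        if min(kd1, kd2, rmax1, rmax2) <= 0:
            raise ValidationError("all two-site parameters must be positive")
        r = langmuir_two_site(c, kd1, kd2, rmax1, rmax2)
    else:
        raise ValidationError(f"unknown isotherm model {model!r}")
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        r = r * (1.0 + rng.normal(0.0, noise_fraction, size=c.size))
    truth = {"model": model, **params, "noise_fraction": noise_fraction, "seed": seed}
    return BindingIsotherm(concentrations=c, responses=r), truth
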