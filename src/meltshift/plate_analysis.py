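"""Plate-level screen analytics built on per-well Th calls.

Given per-well melting temperatures and the screen composition, this module
computes the shift of each condition against the plate's reference wells
(ΔTh), assigns the heat-map categories used to visualise a screen, extracts
pH-stability profiles per buffer system, and builds dose-response and
waterfall orderings for serial-dilution follow-up screens.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError, ValidationError
from .melt_core import (FLAG_NS, FLAG_OK, FLAG_TWO_STEP, FLAG_UNRELIABLE,
                        MeltCurve, ThResult)
from .screens import Condition, ScreenDefinition, corrected_ph, well_sort_key

__all__ = [
    "CATEGORIES",
    "WellSummary",
    "reference_th",
    "delta_th",
    "classify_wells",
    "summarize_plate",
    "ph_profile",
    "dose_response",
    "waterfall",
    "export_results",
    "import_results",
]

log = logging.getLogger(__name__)

CAT_NS = "NS"
CAT_UNRELIABLE = "UNRELIABLE"
CAT_TWO_STEP = "TWO_STEP"
CAT_INCREASE = "INCREASE"
CAT_DECREASE = "DECREASE"
CAT_NEUTRAL = "NEUTRAL"
CATEGORIES = (CAT_NS, CAT_UNRELIABLE, CAT_TWO_STEP,
              CAT_INCREASE, CAT_DECREASE, CAT_NEUTRAL)

_UNIT_TO_UM = {"M": 1e6, "mM": 1e3, "uM": 1.0}


@dataclass(frozen=True)
class WellSummary:
    """One well's Th call joined with its screen condition and ΔTh class."""

    well_id: str
    th_primary: float | None
    th_secondary: float | None
    window_size: int | None
    peak_rate: float | None
    flag: str
    delta_th: float | None
    category: str
    shade_bin: int | None  # |ΔTh| quartile 1..4 for INCREASE/DECREASE wells
    condition: Condition | None = None


def reference_th(results: dict[str, ThResult],
                 reference_wells) -> float:
    """Mean Th over the reference wells whose call has flag OK."""
    vals = [results[w].th_primary for w in reference_wells
            if w in results and results[w].flag == FLAG_OK
            and results[w].th_primary is not None]
    if not vals:
        raise AnalysisError("no reference well produced a usable Th")
    return float(np.mean(vals))


def delta_th(results: dict[str, ThResult],
             screen: ScreenDefinition) -> dict[str, float | None]:
    """ΔTh of every well relative to the screen's reference wells.

    Reference Th is the mean of ``th_primary`` over reference wells with an
    OK call; wells without a primary Th map to ``None``.
    """
    if not screen.reference_wells:
        raise AnalysisError(f"screen {screen.name!r} defines no reference wells")
    ref = reference_th(results, screen.reference_wells)
    return {
        w: (None if r.th_primary is None else r.th_primary - ref)
        for w, r in results.items()
    }


def classify_wells(results: dict[str, ThResult],
                   deltas: dict[str, float | None],
                   neutral_band: float = 0.5) -> dict[str, tuple[str, int | None]]:
    """Assign each well a heat-map category plus an |ΔTh| quartile shade bin.

    TWO_STEP and UNRELIABLE flags pass through; otherwise the sign of ΔTh
    against ``neutral_band`` decides INCREASE / DECREASE / NEUTRAL.
    """
    magnitudes = [abs(d) for w, d in deltas.items()
                  if d is not None and abs(d) > neutral_band
                  and results[w].flag == FLAG_OK]
    edges = (np.quantile(magnitudes, [0.25, 0.5, 0.75])
             if magnitudes else np.array([np.inf] * 3))
    out: dict[str, tuple[str, int | None]] = {}
    for well, res in results.items():
        d = deltas.get(well)
        if res.flag == FLAG_NS:
            out[well] = (CAT_NS, None)
        elif res.flag == FLAG_UNRELIABLE:
            out[well] = (CAT_UNRELIABLE, None)
        elif res.flag == FLAG_TWO_STEP:
            out[well] = (CAT_TWO_STEP, None)
        elif d is None or abs(d) <= neutral_band:
            out[well] = (CAT_NEUTRAL, None)
        else:
            shade = 1 + int(np.searchsorted(edges, abs(d), side="right"))
            shade = min(shade, 4)
            out[well] = (CAT_INCREASE if d > 0 else CAT_DECREASE, shade)
    return out


def summarize_plate(results: dict[str, ThResult],
                    screen: ScreenDefinition | None = None,
                    neutral_band: float = 0.5) -> list[WellSummary]:
    """Join Th calls, ΔTh and categories into per-well summaries."""
    if screen is not None:
        deltas = delta_th(results, screen)
    else:
        deltas = {w: None for w in results}
    cats = classify_wells(results, deltas, neutral_band)
    summaries = []
    for well in sorted(results, key=well_sort_key):
        res = results[well]
        cat, shade = cats[well]
        cond = screen.wells.get(well) if screen is not None else None
        summaries.append(WellSummary(
            well_id=well, th_primary=res.th_primary,
            th_secondary=res.th_secondary, window_size=res.window_size,
            peak_rate=res.peak_rate, flag=res.flag,
            delta_th=deltas.get(well), category=cat, shade_bin=shade,
            condition=cond))
    return summaries


def _buffer_system(cond: Condition) -> str:
    """Group label for pH profiles: the buffering component's name."""
    for comp in cond.components:
        if comp.name.startswith("buffer "):
            return comp.name
    if cond.components:
        return cond.components[0].name
    return "(no buffer)"


def ph_profile(results: dict[str, ThResult],
               screen: ScreenDefinition) -> dict[str, list[tuple[float, float]]]:
    """Th as a function of temperature-corrected pH, grouped by buffer system.

    Each series is sorted by the corrected pH (the pH the well actually had
    at its melting temperature, after the dpKa/dT correction).  Wells
    without a pH or without a called Th are skipped with a log note.
    """
    profiles: dict[str, list[tuple[float, float]]] = {}
    for well, res in results.items():
        cond = screen.wells.get(well)
        if cond is None or cond.ph25 is None:
            log.info("ph_profile: skipping well %s (no pH recorded)", well)
            continue
        if res.th_primary is None:
            log.info("ph_profile: skipping well %s (no Th called)", well)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # missing dpKa warns; 0 assumed
            ph = corrected_ph(cond, res.th_primary)
        profiles.setdefault(_buffer_system(cond), []).append((ph, res.th_primary))
    for series in profiles.values():
        series.sort()
    return profiles


def dose_response(results: dict[str, ThResult],
                  screen: ScreenDefinition,
                  species_name: str) -> list[tuple[float, float | None]]:
    """(concentration in uM, Th) for every well containing ``species_name``.

    Sorted ascending by concentration; wells without a called Th are carried
    with ``None``.  Only molar units participate (%, x-fold species have no
    common molar scale).
    """
    series: list[tuple[float, float | None]] = []
    for well, cond in screen.wells.items():
        comp = cond.component(species_name)
        if comp is None:
            continue
        if comp.unit not in _UNIT_TO_UM:
            raise ValidationError(
                f"{well}: {species_name} in unit {comp.unit!r} has no molar scale")
        conc_um = comp.concentration * _UNIT_TO_UM[comp.unit]
        th = results[well].th_primary if well in results else None
        series.append((conc_um, th))
    if len(series) < 2:
        raise ValidationError(
            f"species {species_name!r} found in {len(series)} wells; need >= 2")
    series.sort(key=lambda x: x[0])
    return series


def waterfall(plate: dict[str, MeltCurve],
              results: dict[str, ThResult],
              screen: ScreenDefinition,
              species_name: str,
              shift_threshold: float = 1.0) -> list[dict]:
    """Order a dilution series' curves by concentration and label shifts.

    Each entry carries the well, its curve, the species concentration (uM)
    and a label: ``shifted`` when |Th - reference Th| exceeds
    ``shift_threshold`` (default 1 degC), else ``no_shift``; wells without a
    Th carry ``None``.  Returns an empty list with a warning when no
    reference Th is available (e.g. an all-NS plate).
    """
    try:
        ref = reference_th(results, screen.reference_wells)
    except AnalysisError:
        warnings.warn("waterfall: no usable reference well; nothing to label",
                      stacklevel=2)
        return []
    entries = []
    for well, cond in screen.wells.items():
        comp = cond.component(species_name)
        if comp is None or well not in plate:
            continue
        conc_um = comp.concentration * _UNIT_TO_UM.get(comp.unit, np.nan)
        th = results[well].th_primary if well in results else None
        if th is None:
            label = None
        else:
            label = "shifted" if abs(th - ref) > shift_threshold else "no_shift"
        entries.append({"well": well, "curve": plate[well],
                        "concentration_um": float(conc_um), "th": th,
                        "label": label})
    entries.sort(key=lambda e: e["concentration_um"])
    return entries


_EXPORT_HEADER = ["well", "th1", "th2", "window_size", "peak_rate", "flag",
                  "delta_th", "category"]


def export_results(summaries: list[WellSummary], path) -> None:
    """Write per-well summaries (Th calls plus ΔTh and category) to CSV."""
    def fmt(x, digits=4):
        return "" if x is None else f"{x:.{digits}f}"

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_EXPORT_HEADER)
        for s in summaries:
            writer.writerow([
                s.well_id, fmt(s.th_primary, 2), fmt(s.th_secondary, 2),
                "" if s.window_size is None else s.window_size,
                fmt(s.peak_rate, 6), s.flag, fmt(s.delta_th, 2), s.category,
            ])


def import_results(path) -> list[WellSummary]:
    """Read back a summary CSV written by :func:`export_results`."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _EXPORT_HEADER:
            raise ValidationError(f"{path}: unexpected summary header")
        for rec in reader:
            def opt(key, conv=float):
                v = rec[key]
                return None if v in ("", None) else conv(v)
            out.append(WellSummary(
                well_id=rec["well"], th_primary=opt("th1"),
                th_secondary=opt("th2"), window_size=opt("window_size", int),
                peak_rate=opt("peak_rate"), flag=rec["flag"],
                delta_th=opt("delta_th"), category=rec["category"],
                shade_bin=None, condition=None))
    return out
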