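"""Reading and writing the toolkit's text formats.

Plate fluorescence exports come in two common shapes:

* long format — columns ``well,temperature,fluorescence``, one row per
  reading, rows per well contiguous or at least sortable by temperature;
* wide format — first column the temperature, one further column per well
  (a typical qPCR-instrument export).

Results are written as one CSV row per well with empty fields for absent
values.  Binding isotherms use ``concentration,concentration_unit,response``.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .dpi_binding import BindingIsotherm
from .errors import ValidationError
from .melt_core import MeltCurve, ThResult

__all__ = [
    "read_plate_long",
    "read_plate_wide",
    "write_plate_long",
    "write_results",
    "read_results",
    "read_isotherm",
    "write_isotherm",
]

RESULTS_HEADER = ["well", "th1", "th2", "window_size", "peak_rate", "flag"]


def read_plate_long(path) -> dict[str, MeltCurve]:
    """Read a long-format plate CSV into per-well melt curves."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"well", "temperature", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    plate: dict[str, MeltCurve] = {}
    for well, grp in df.groupby("well", sort=False):
        grp = grp.sort_values("temperature")
        plate[str(well)] = MeltCurve(
            str(well),
            grp["temperature"].to_numpy(dtype=float),
            grp["fluorescence"].to_numpy(dtype=float),
        )
    if not plate:
        raise ValidationError(f"{path}: no wells found")
    return plate


def read_plate_wide(path) -> dict[str, MeltCurve]:
    """Read a wide-format plate CSV (temperature column + one column per well)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need a temperature column and >= 1 well")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    plate: dict[str, MeltCurve] = {}
    for col in df.columns[1:]:
        plate[str(col)] = MeltCurve(str(col), t, df[col].to_numpy(dtype=float))
    return plate


def write_plate_long(plate: Mapping[str, MeltCurve], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["well", "temperature", "fluorescence"])
        for well, curve in plate.items():
            for t, f in zip(curve.temperatures, curve.fluorescence):
                writer.writerow([well, repr(float(t)), repr(float(f))])


def _fmt(x, digits: int = 4) -> str:
    return "" if x is None else f"{x:.{digits}f}"


def write_results(results: Mapping[str, ThResult], path) -> None:
    """Write per-well Th calls: ``well,th1,th2,window_size,peak_rate,flag``."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULTS_HEADER)
        for well, res in results.items():
            writer.writerow([
                well, _fmt(res.th_primary, 2), _fmt(res.th_secondary, 2),
                "" if res.window_size is None else res.window_size,
                _fmt(res.peak_rate, 6), res.flag,
            ])


def read_results(path) -> dict[str, ThResult]:
    """Read a results CSV back into :class:`ThResult` objects."""
    out: dict[str, ThResult] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or reader.fieldnames[:6] != RESULTS_HEADER:
            raise ValidationError(f"{path}: unexpected results header")
        for rec in reader:
            def opt(key, conv=float):
                v = rec[key]
                return None if v in ("", None) else conv(v)
            out[rec["well"]] = ThResult(
                well_id=rec["well"],
                th_primary=opt("th1"),
                th_secondary=opt("th2"),
                window_size=opt("window_size", int),
                peak_rate=opt("peak_rate"),
                flag=rec["flag"],
            )
    return out


def read_isotherm(path) -> BindingIsotherm:
    """Read ``concentration,concentration_unit,response`` into an isotherm (uM)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"concentration", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    units = (df["concentration_unit"] if "concentration_unit" in df.columns
             else pd.Series(["uM"] * len(df)))
    from .dpi_binding import _UNIT_TO_UM
    factors = units.map(_UNIT_TO_UM)
    if factors.isna().any():
        bad = units[factors.isna()].iloc[0]
        raise ValidationError(f"{path}: unknown concentration unit {bad!r}")
    c = df["concentration"].to_numpy(dtype=float) * factors.to_numpy(dtype=float)
    r = df["response"].to_numpy(dtype=float)
    order = np.argsort(c)
    return BindingIsotherm(concentrations=c[order], responses=r[order])


def write_isotherm(iso: BindingIsotherm, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["concentration", "concentration_unit", "response"])
        for c, r in zip(iso.concentrations, iso.responses):
            writer.writerow([repr(float(c)), "uM", repr(float(r))])
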