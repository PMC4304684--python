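"""Screen definitions: well compositions, universal buffers, pH correction.

A *screen* maps each well of a 96-well plate to a chemical condition
(components with concentrations, pH at 25 degC, a buffer-pKa temperature
coefficient, and a role).  Two screens are shipped as packaged fixtures:

``ph``
    Deconvolutes pH from buffer identity: single buffers spanning pH 4.2 to
    12.3 plus three universal (three-component) buffers A/B/C titrated over
    twelve acid:base mixing ratios, with malonate/NaCl add-back rows.
``salt``
    Common salts and osmolytes, designed to separate anionic from cationic
    effects, with a divalent-transition-metal block and denaturant series.

Concentrations stored are FINAL assay concentrations (the wet-lab stocks are
prepared at 2x and mixed 1:1 with protein plus dye); a 2x stock export is
available from :func:`save_screen`.

Because a buffer's pKa drifts with temperature, the effective pH at the
melting temperature differs from the pH measured at 25 degC;
:func:`corrected_ph` applies the linear ``dpKa/dT`` correction.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .errors import UnsupportedConditionError, ValidationError

__all__ = [
    "Component",
    "Condition",
    "ScreenDefinition",
    "SCREEN_CSV_HEADER",
    "UNIVERSAL_BUFFER_PH",
    "load_screen",
    "save_screen",
    "builtin_screen",
    "corrected_ph",
    "universal_buffer_series",
    "well_sort_key",
]

SCREEN_CSV_HEADER = ["well", "component", "concentration", "unit",
                     "ph25", "dpka_per_degc", "role"]

VALID_UNITS = {"M", "mM", "uM", "%", "x"}
VALID_ROLES = {"sample", "reference", "blank"}

_WELL_96 = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")

#: Measured pH of the three universal buffers at 25 degC for each of the
#: twelve acid:base mixing ratios (11:0 .. 0:11).  Buffer A is
#: succinate/phosphate/glycine, B is citrate/HEPES/CHES, C is
#: malonate/imidazole/borate; each conjugate pair at 200 mM.
UNIVERSAL_BUFFER_PH: dict[str, tuple[float, ...]] = {
    "A": (4.0, 4.4, 4.7, 5.0, 5.4, 5.6, 6.0, 6.4, 6.9, 7.6, 9.2, 10.0),
    "B": (4.0, 4.5, 4.9, 5.4, 5.9, 6.1, 6.6, 7.4, 7.5, 8.3, 9.1, 10.0),
    "C": (4.0, 5.0, 5.6, 5.8, 6.3, 6.8, 7.4, 7.8, 8.0, 8.5, 9.2, 10.0),
}

#: Components of each universal buffer (three conjugate acid-base pairs,
#: each at 200 mM in the titrated stock, 600 mM total).
UNIVERSAL_BUFFER_COMPONENTS: dict[str, tuple[str, ...]] = {
    "A": ("succinic acid", "NaH2PO4", "glycine"),
    "B": ("citric acid", "HEPES", "CHES"),
    "C": ("malonic acid", "imidazole", "boric acid"),
}


def well_sort_key(well_id: str) -> tuple[str, int]:
    """Sort key putting A1..A12 before B1..B12 etc."""
    m = re.match(r"^([A-Za-z]+)(\d+)$", well_id)
    if not m:
        return (well_id, 0)
    return (m.group(1), int(m.group(2)))


@dataclass(frozen=True)
class Component:
    name: str
    concentration: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValidationError(f"unknown unit {self.unit!r} for {self.name!r}")
        if not self.concentration > 0:
            raise ValidationError(f"non-positive concentration for {self.name!r}")


@dataclass(frozen=True)
class Condition:
    """Chemical condition of one well."""

    well_id: str
    components: tuple[Component, ...] = ()
    ph25: float | None = None
    dpka_per_degc: float | None = None
    role: str = "sample"

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValidationError(f"{self.well_id}: unknown role {self.role!r}")
        if self.role == "sample" and not self.components:
            raise ValidationError(f"{self.well_id}: sample well without components")
        if self.ph25 is not None and not (0.0 <= self.ph25 <= 14.0):
            raise ValidationError(f"{self.well_id}: pH {self.ph25} outside 0-14")

    def component(self, name: str) -> Component | None:
        for c in self.components:
            if c.name == name:
                return c
        return None


@dataclass(frozen=True)
class ScreenDefinition:
    name: str
    wells: Mapping[str, Condition]
    reference_wells: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for w in self.reference_wells:
            if w not in self.wells:
                raise ValidationError(f"reference well {w} not in screen")
        if len(self.wells) == 96:
            bad = [w for w in self.wells if not _WELL_96.match(w)]
            if bad:
                raise ValidationError(f"96-well screen has non-standard ids: {bad[:3]}")

    def __len__(self) -> int:
        return len(self.wells)


def _parse_float(text: str, what: str, rownum: int) -> float | None:
    if text is None or str(text).strip() == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise ValidationError(f"row {rownum}: bad {what} {text!r}") from None


def _read_rows(path) -> list[tuple[int, dict]]:
    with open(path, newline="", encoding="utf-8") as fh:
        lines = [(i + 1, ln) for i, ln in enumerate(fh) if not ln.startswith("#")]
    if not lines:
        raise ValidationError(f"{path}: empty screen file")
    nums, text = zip(*lines)
    reader = csv.reader(text)
    rows = list(reader)
    header = [h.strip() for h in rows[0]]
    if header != SCREEN_CSV_HEADER:
        raise ValidationError(
            f"{path}: bad header {header!r}; expected {SCREEN_CSV_HEADER!r}"
        )
    return [(nums[i], dict(zip(header, r))) for i, r in enumerate(rows[1:], start=1)]


def load_screen(csv_path, name: str | None = None) -> ScreenDefinition:
    """Read a screen composition CSV into a :class:`ScreenDefinition`.

    One row per (well, component); multiple rows per well aggregate into one
    condition.  Rows whose ``component`` is empty declare a component-free
    (blank/reference) well.  Validation errors name the offending CSV row.
    """
    csv_path = Path(csv_path)
    per_well: dict[str, dict] = {}
    for rownum, rec in _read_rows(csv_path):
        well = rec["well"].strip()
        if not well:
            raise ValidationError(f"{csv_path} row {rownum}: missing well id")
        entry = per_well.setdefault(
            well, {"components": [], "names": set(), "ph25": None,
                   "dpka": None, "role": None})
        comp_name = rec["component"].strip()
        if comp_name:
            if comp_name in entry["names"]:
                raise ValidationError(
                    f"{csv_path} row {rownum}: duplicate component "
                    f"{comp_name!r} in well {well}")
            conc = _parse_float(rec["concentration"], "concentration", rownum)
            unit = rec["unit"].strip()
            if conc is None:
                raise ValidationError(
                    f"{csv_path} row {rownum}: component without concentration")
            if unit not in VALID_UNITS:
                raise ValidationError(
                    f"{csv_path} row {rownum}: unknown unit {unit!r}")
            try:
                entry["components"].append(Component(comp_name, conc, unit))
            except ValidationError as exc:
                raise ValidationError(f"{csv_path} row {rownum}: {exc}") from None
            entry["names"].add(comp_name)
        ph = _parse_float(rec["ph25"], "ph25", rownum)
        if ph is not None:
            if not (0.0 <= ph <= 14.0):
                raise ValidationError(
                    f"{csv_path} row {rownum}: pH {ph} outside 0-14")
            if entry["ph25"] is not None and entry["ph25"] != ph:
                raise ValidationError(
                    f"{csv_path} row {rownum}: conflicting pH for well {well}")
            entry["ph25"] = ph
        dpka = _parse_float(rec["dpka_per_degc"], "dpka_per_degc", rownum)
        if dpka is not None:
            entry["dpka"] = dpka
        role = rec["role"].strip() or "sample"
        if role not in VALID_ROLES:
            raise ValidationError(f"{csv_path} row {rownum}: unknown role {role!r}")
        if entry["role"] not in (None, role):
            raise ValidationError(
                f"{csv_path} row {rownum}: conflicting role for well {well}")
        entry["role"] = role

    wells = {
        w: Condition(well_id=w, components=tuple(e["components"]),
                     ph25=e["ph25"], dpka_per_degc=e["dpka"], role=e["role"])
        for w, e in per_well.items()
    }
    refs = tuple(sorted((w for w, c in wells.items() if c.role == "reference"),
                        key=well_sort_key))
    return ScreenDefinition(name=name or csv_path.stem, wells=wells,
                            reference_wells=refs)


def save_screen(screen: ScreenDefinition, path, stock2x: bool = False) -> None:
    """Write a screen back to the CSV schema.

    With ``stock2x`` every concentration is doubled, producing the wet-lab
    stock plate that yields the screen's final concentrations after 1:1
    mixing with protein plus dye.
    """
    factor = 2.0 if stock2x else 1.0
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCREEN_CSV_HEADER)
        for well in sorted(screen.wells, key=well_sort_key):
            cond = screen.wells[well]
            ph = "" if cond.ph25 is None else cond.ph25
            dpka = "" if cond.dpka_per_degc is None else cond.dpka_per_degc
            if not cond.components:
                writer.writerow([well, "", "", "", ph, dpka, cond.role])
            for comp in cond.components:
                conc = comp.concentration * factor
                writer.writerow([well, comp.name, f"{conc:g}", comp.unit,
                                 ph, dpka, cond.role])


def builtin_screen(name: str) -> ScreenDefinition:
    """Return one of the packaged screens: ``"ph"`` or ``"salt"``."""
    if name not in {"ph", "salt"}:
        raise ValidationError(f"unknown builtin screen {name!r}; use 'ph' or 'salt'")
    ref = resources.files("meltshift.data") / f"{name}_screen.csv"
    with resources.as_file(ref) as path:
        return load_screen(path, name=name)


def corrected_ph(condition: Condition, th: float, t_ref: float = 25.0) -> float:
    """Effective pH of a buffered condition at temperature ``th``.

    Applies the linear pKa temperature coefficient:
    ``pH(th) = pH(25) + dpKa/dT * (th - t_ref)``.  A condition without a
    measured pH cannot be corrected; a missing coefficient warns and is
    treated as 0 (no correction).
    """
    if condition.ph25 is None:
        raise UnsupportedConditionError(
            f"{condition.well_id}: no pH recorded; cannot temperature-correct")
    dpka = condition.dpka_per_degc
    if dpka is None:
        warnings.warn(
            f"{condition.well_id}: no dpKa/degC recorded; assuming 0",
            stacklevel=2)
        dpka = 0.0
    return condition.ph25 + dpka * (th - t_ref)


def universal_buffer_series(n_steps: int = 12) -> list[tuple[int, int]]:
    """Acid:base mixing ratios of a universal-buffer titration.

    The default twelve steps are (11,0), (10,1), ..., (0,11): the acidic and
    basic stocks mixed in integer parts that always sum to ``n_steps - 1``.
    """
    if n_steps < 2:
        raise ValidationError("need at least 2 mixing steps")
    return [(n_steps - 1 - i, i) for i in range(n_steps)]
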