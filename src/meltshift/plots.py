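"""Plot export: melt curves, plate heat maps, pH profiles, waterfalls.

All figures are written straight to files (no interactive backend needed).
Heat-map colour semantics: blues for stabilising shifts (darker = larger),
yellow-to-red for destabilising, green for two-step melts, grey for
unreliable calls and white for no-signal wells.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .melt_core import AnalysisConfig, MeltCurve, call_th, rate_of_change, \
    select_denaturation_window, smooth_interpolate
from .plate_analysis import (CAT_DECREASE, CAT_INCREASE, CAT_NEUTRAL, CAT_NS,
                             CAT_TWO_STEP, CAT_UNRELIABLE, WellSummary)

__all__ = ["plot_curve", "render_heatmap", "plot_ph_profiles", "plot_waterfall"]

_ROWS = "ABCDEFGH"

_BLUES = ["#c6dbef", "#6baed6", "#2171b5", "#08306b"]
_REDS = ["#fee391", "#fe9929", "#d95f0e", "#993404"]


def plot_curve(curve: MeltCurve, path, config: AnalysisConfig | None = None) -> None:
    """Raw curve, interpolated rate of change, selected window and Th."""
    config = config or AnalysisConfig()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.temperatures, curve.fluorescence, "o", ms=3, color="#1f77b4",
            label="fluorescence")
    res = call_th(curve, config)
    sel = select_denaturation_window(curve, config)
    if sel is not None:
        w, start = sel
        rt, rates = rate_of_change(curve, w)
        spline = smooth_interpolate(rt, rates, config)
        dense = np.arange(rt[0], rt[-1], config.dense_grid_step)
        ax2 = ax.twinx()
        ax2.plot(dense, spline(dense), color="purple", lw=1.5,
                 label="interpolated dF/dT")
        ax2.set_ylabel("rate of change (AU/degC)")
        ax.axvline(curve.temperatures[start], color="green", ls="--", lw=1)
        ax.axvline(curve.temperatures[min(start + w - 1, len(curve) - 1)],
                   color="green", ls="--", lw=1)
    if res.th_primary is not None:
        ax.axvline(res.th_primary, color="red", lw=1.5)
    ax.set_xlabel("temperature (degC)")
    ax.set_ylabel("fluorescence (AU)")
    ax.set_title(f"{curve.well_id}: {res.flag}"
                 + (f", Th = {res.th_primary:.1f} degC" if res.th_primary else ""))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _cell_colour(summary: WellSummary) -> str:
    if summary.category == CAT_NS:
        return "#ffffff"
    if summary.category == CAT_UNRELIABLE:
        return "#999999"
    if summary.category == CAT_TWO_STEP:
        return "#41ab5d"
    if summary.category == CAT_NEUTRAL:
        return "#f0f0f0"
    shade = (summary.shade_bin or 1) - 1
    return _BLUES[shade] if summary.category == CAT_INCREASE else _REDS[shade]


def render_heatmap(summaries: list[WellSummary], path) -> None:
    """8x12 plate grid coloured by ΔTh category, annotated with Th."""
    fig, ax = plt.subplots(figsize=(10, 6))
    by_well = {s.well_id: s for s in summaries}
    for ri, row in enumerate(_ROWS):
        for ci in range(12):
            well = f"{row}{ci + 1}"
            s = by_well.get(well)
            colour = _cell_colour(s) if s else "#ffffff"
            ax.add_patch(plt.Rectangle((ci, 7 - ri), 1, 1, facecolor=colour,
                                       edgecolor="black", lw=0.5))
            if s is not None:
                text = "N/S" if s.th_primary is None else f"{s.th_primary:.1f}"
                ax.text(ci + 0.5, 7 - ri + 0.5, text, ha="center", va="center",
                        fontsize=7)
    ax.set_xlim(0, 12)
    ax.set_ylim(0, 8)
    ax.set_xticks(np.arange(12) + 0.5, [str(i + 1) for i in range(12)])
    ax.set_yticks(np.arange(8) + 0.5, list(reversed(_ROWS)))
    ax.set_aspect("equal")
    ax.set_title("melting temperature per well (degC)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ph_profiles(profiles: dict[str, list[tuple[float, float]]], path) -> None:
    """Th versus temperature-corrected pH, one series per buffer system."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, series in sorted(profiles.items()):
        if not series:
            continue
        ph, th = zip(*series)
        ax.plot(ph, th, "o-", ms=4, label=label)
    ax.set_xlabel("pH at Th (temperature-corrected)")
    ax.set_ylabel("Th (degC)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_waterfall(entries: list[dict], path) -> None:
    """Overlaid melt curves ordered by concentration; shifted curves in blue."""
    fig, ax = plt.subplots(figsize=(7, 5))
    offset = 0.0
    for e in entries:
        curve: MeltCurve = e["curve"]
        colour = {"shifted": "#2171b5", "no_shift": "#9e6ebd"}.get(e["label"], "#bbbbbb")
        f = curve.fluorescence
        span = max(f.max() - f.min(), 1.0)
        ax.plot(curve.temperatures, (f - f.min()) / span + offset, color=colour, lw=1)
        ax.text(curve.temperatures[-1] + 0.5, offset + 0.2,
                f"{e['concentration_um']:g} uM", fontsize=6, va="bottom")
        offset += 0.35
    ax.set_xlabel("temperature (degC)")
    ax.set_ylabel("normalised fluorescence (offset per curve)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
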