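"""Melting-temperature calling for thermal shift assay (DSF/Thermofluor) curves.

A protein melt curve rises when an environment-sensitive dye binds the
hydrophobic core exposed during unfolding.  The melting temperature Th is
located numerically rather than by fitting a thermodynamic model:

1. A sliding window of increasing size (``window_min``..``window_max`` points)
   is regressed linearly against temperature.  A window is *eligible* when its
   slope is positive (unfolding raises fluorescence) and its Pearson
   correlation reaches ``r_min`` (default 0.996).  The largest eligible window
   size is retained and, within it, the steepest-slope position.
2. With that window size, a centred-window least-squares slope is computed at
   every data point: a noise-robust approximation of dF/dT.
3. A smoothing spline interpolates the rate series; local maxima of the
   interpolated rate on a dense grid are candidate melting temperatures.
   Up to two maxima are reported; curves without a clear transition are
   flagged NS (no signal), curves with more than two resolvable maxima are
   flagged UNRELIABLE.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import UnivariateSpline
from scipy.signal import find_peaks

from .errors import ValidationError

__all__ = [
    "MeltCurve",
    "WindowFit",
    "ThResult",
    "AnalysisConfig",
    "FLAG_OK",
    "FLAG_TWO_STEP",
    "FLAG_NS",
    "FLAG_UNRELIABLE",
    "fit_window",
    "select_denaturation_window",
    "rate_of_change",
    "smooth_interpolate",
    "call_th",
    "analyze_plate",
]

FLAG_OK = "OK"
FLAG_TWO_STEP = "TWO_STEP"
FLAG_NS = "NS"
FLAG_UNRELIABLE = "UNRELIABLE"

#: Smallest curve length accepted anywhere; equals the default minimum
#: sliding-window size.
MIN_CURVE_POINTS = 5


@dataclass(frozen=True)
class MeltCurve:
    """One well's fluorescence-versus-temperature series.

    Parameters
    ----------
    well_id
        Plate coordinate ("A1".."H12") or any free label.
    temperatures
        Strictly increasing temperatures in degrees Celsius.
    fluorescence
        Fluorescence in arbitrary units, same length as ``temperatures``.
    """

    well_id: str
    temperatures: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "fluorescence", f)
        if t.ndim != 1 or f.ndim != 1:
            raise ValidationError(f"{self.well_id}: series must be 1-D")
        if t.size != f.size:
            raise ValidationError(
                f"{self.well_id}: temperature and fluorescence lengths differ "
                f"({t.size} vs {f.size})"
            )
        if t.size < MIN_CURVE_POINTS:
            raise ValidationError(
                f"{self.well_id}: need at least {MIN_CURVE_POINTS} points, got {t.size}"
            )
        if not (np.isfinite(t).all() and np.isfinite(f).all()):
            raise ValidationError(f"{self.well_id}: non-finite values in curve")
        if not np.all(np.diff(t) > 0):
            # descending or duplicated temperatures: instrument ramps ascend
            raise ValidationError(
                f"{self.well_id}: temperatures must be strictly increasing"
            )

    def __len__(self) -> int:
        return int(self.temperatures.size)


@dataclass(frozen=True)
class WindowFit:
    """Linear regression of fluorescence on temperature over one window."""

    window_size: int
    start_index: int
    slope: float        # fluorescence units per degC (symbol a)
    correlation: float  # Pearson r in [-1, 1]


@dataclass(frozen=True)
class ThResult:
    """Called melting temperature(s) and quality flag for one well."""

    well_id: str
    th_primary: float | None
    th_secondary: float | None
    window_size: int | None
    peak_rate: float | None
    flag: str

    def __post_init__(self) -> None:
        if self.th_secondary is not None and self.th_primary is None:
            raise ValidationError("secondary Th without primary Th")
        if (self.flag == FLAG_NS) != (self.th_primary is None):
            raise ValidationError("flag NS iff no primary Th")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the Th-calling algorithm.

    ``r_min`` is the empirical correlation gate for the denaturation window;
    ``ns_noise_multiplier`` scales a MAD-based noise floor below which the
    tallest derivative peak is dismissed as no-signal.
    """

    window_min: int = 5
    window_max: int = 35
    r_min: float = 0.996
    dense_grid_step: float = 0.05
    prominence_fraction: float = 0.1
    min_peak_separation: float = 3.0
    ns_noise_multiplier: float = 3.0
    spline_smoothing_factor: float = 0.0

    def __post_init__(self) -> None:
        if not (3 <= self.window_min <= self.window_max):
            raise ValidationError("need 3 <= window_min <= window_max")
        if not (0.0 < self.r_min < 1.0):
            raise ValidationError("r_min must lie in (0, 1)")
        if self.dense_grid_step <= 0:
            raise ValidationError("dense_grid_step must be positive")


def _window_stats(t: np.ndarray, f: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised OLS slope and Pearson r for every length-``w`` window."""
    tw = sliding_window_view(t, w)
    fw = sliding_window_view(f, w)
    tm = tw.mean(axis=1, keepdims=True)
    fm = fw.mean(axis=1, keepdims=True)
    dt = tw - tm
    df = fw - fm
    sxx = (dt * dt).sum(axis=1)
    syy = (df * df).sum(axis=1)
    sxy = (dt * df).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / sxx, 0.0)
        denom = np.sqrt(sxx * syy)
        r = np.where(denom > 0, sxy / denom, 0.0)
    return slope, np.clip(r, -1.0, 1.0)


def fit_window(curve: MeltCurve, start_index: int, window_size: int) -> WindowFit:
    """Fit one sliding window by ordinary least squares.

    Returns the slope ``a`` and Pearson correlation ``r`` of fluorescence on
    temperature over ``window_size`` points starting at ``start_index``.
    A constant-fluorescence window has undefined correlation; it is defined
    as 0 so that it can never be selected.
    """
    n = len(curve)
    if window_size < 2:
        raise ValidationError("window_size must be >= 2")
    if start_index < 0 or start_index + window_size > n:
        raise IndexError(
            f"window [{start_index}, {start_index + window_size}) outside curve of {n} points"
        )
    t = curve.temperatures[start_index : start_index + window_size]
    f = curve.fluorescence[start_index : start_index + window_size]
    slope, r = _window_stats(t, f, window_size)
    return WindowFit(window_size=window_size, start_index=start_index,
                     slope=float(slope[0]), correlation=float(r[0]))


def select_denaturation_window(
    curve: MeltCurve, config: AnalysisConfig | None = None
) -> tuple[int, int] | None:
    """Choose the (window_size, start_index) of the denaturation window.

    Every window size in ``[window_min, window_max]`` is slid over the curve;
    a window is eligible when slope > 0 and r >= r_min.  The largest window
    size with any eligible position wins; within it the steepest slope wins,
    ties going to the lower start index.  Returns ``None`` when no window is
    eligible (no-signal curve).
    """
    config = config or AnalysisConfig()
    n = len(curve)
    if n < config.window_min:
        raise ValidationError(
            f"{curve.well_id}: curve of {n} points shorter than window_min={config.window_min}"
        )
    t, f = curve.temperatures, curve.fluorescence
    w_hi = min(config.window_max, n)
    for w in range(w_hi, config.window_min - 1, -1):
        slope, r = _window_stats(t, f, w)
        eligible = (slope > 0) & (r >= config.r_min)
        if eligible.any():
            slopes = np.where(eligible, slope, -np.inf)
            return w, int(np.argmax(slopes))  # argmax takes first on ties
    return None


def rate_of_change(
    curve: MeltCurve, window_size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Approximate dF/dT at every data point by a centred-window OLS slope.

    The window of ``window_size`` points is centred on each data point and
    truncated at the curve edges (never below 3 points).  Each rate is paired
    with its window's centre temperature (the mean of the window's
    temperatures): identical to the centre point for full odd-sized windows,
    and unbiased for even-sized or edge-truncated windows, where snapping to
    a data point would shift every derivative feature by up to half a step.

    Returns
    -------
    (temperatures, rates)
        Two arrays of the curve's length, temperatures non-decreasing.
    """
    n = len(curve)
    if window_size < 3:
        raise ValidationError("rate window must have at least 3 points")
    t, f = curve.temperatures, curve.fluorescence
    left = (window_size - 1) // 2
    right = window_size // 2
    temps = np.empty(n)
    rates = np.empty(n)
    for i in range(n):
        lo = max(0, i - left)
        hi = min(n, i + right + 1)
        if hi - lo < 3:  # only possible on very short curves
            lo, hi = max(0, min(lo, n - 3)), min(n, max(hi, 3))
        slope, _ = _window_stats(t[lo:hi], f[lo:hi], hi - lo)
        temps[i] = t[lo:hi].mean()
        rates[i] = slope[0]
    return temps, rates


def smooth_interpolate(
    rate_temperatures: np.ndarray,
    rates: np.ndarray,
    config: AnalysisConfig | None = None,
) -> UnivariateSpline:
    """Build a univariate smoothing spline over the rate-of-change series.

    With the default smoothing factor 0 the spline interpolates every point.
    The returned object is callable on any temperature in the series range.
    """
    config = config or AnalysisConfig()
    t = np.asarray(rate_temperatures, dtype=float)
    r = np.asarray(rates, dtype=float)
    if t.size < 4:
        raise ValidationError("need at least 4 rate points for a cubic spline")
    return UnivariateSpline(t, r, k=3, s=config.spline_smoothing_factor)


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def _ns_result(well_id: str) -> ThResult:
    return ThResult(well_id=well_id, th_primary=None, th_secondary=None,
                    window_size=None, peak_rate=None, flag=FLAG_NS)


def _detect_peaks(
    curve: MeltCurve, window_size: int, config: AnalysisConfig
) -> tuple[list[float], list[float]]:
    """Spline the rate series and return surviving peaks (temps, heights).

    Peaks shorter than ``prominence_fraction`` of the tallest are discarded,
    as are peaks within ``min_peak_separation`` degC of a taller one; a
    tallest peak below the MAD-based noise floor empties the list (NS).
    """
    rate_t, rates = rate_of_change(curve, window_size)
    spline = smooth_interpolate(rate_t, rates, config)
    dense_t = np.arange(rate_t[0], rate_t[-1] + config.dense_grid_step / 2,
                        config.dense_grid_step)
    dense_r = spline(dense_t)

    peak_idx, _ = find_peaks(dense_r)
    if peak_idx.size == 0:
        return [], []
    heights = dense_r[peak_idx]
    temps = dense_t[peak_idx]

    tallest = float(heights.max())
    noise_floor = config.ns_noise_multiplier * _mad(np.diff(rates))
    if tallest < noise_floor:
        return [], []

    # a surviving peak must clear both the relative-height cut and the
    # noise floor; noise bumps otherwise masquerade as extra transitions
    keep = (heights >= config.prominence_fraction * tallest) & \
        (heights >= noise_floor)
    temps, heights = temps[keep], heights[keep]
    # greedy non-maximum suppression: taller peaks absorb neighbours closer
    # than min_peak_separation; equal heights resolve to lower temperature
    order = np.lexsort((temps, -heights))
    kept_t: list[float] = []
    kept_h: list[float] = []
    for j in order:
        if all(abs(temps[j] - t0) >= config.min_peak_separation for t0 in kept_t):
            kept_t.append(float(temps[j]))
            kept_h.append(float(heights[j]))
    return kept_t, kept_h


def call_th(curve: MeltCurve, config: AnalysisConfig | None = None) -> ThResult:
    """Call up to two melting temperatures for one curve.

    Composes window selection, rate-of-change estimation and spline peak
    detection (see :func:`_detect_peaks` for the peak-acceptance rules).
    The tallest surviving peak is Th; a second gives flag TWO_STEP and more
    than two give UNRELIABLE (top two still reported).  Flag NS means no
    eligible window or a tallest peak indistinguishable from the rate
    series' own noise floor.

    When the tallest peak lies close enough to a grid edge that its rate
    windows were truncated, the window size is shrunk to the largest size
    whose windows are complete there and the peak search repeats.  Without
    this, the loss of smoothing towards the edge inflates nearby rates and
    drags the called Th of transitions ending near the final temperature
    away from the true midpoint.
    """
    config = config or AnalysisConfig()
    selection = select_denaturation_window(curve, config)
    if selection is None:
        return _ns_result(curve.well_id)
    window_size, _start = selection

    t0, t1 = curve.temperatures[0], curve.temperatures[-1]
    step = float(np.mean(np.diff(curve.temperatures)))
    while True:
        kept_t, kept_h = _detect_peaks(curve, window_size, config)
        if not kept_t:
            return _ns_result(curve.well_id)
        edge_pts = int(min(kept_t[0] - t0, t1 - kept_t[0]) / step)
        refined = min(window_size, max(config.window_min, 2 * edge_pts + 1))
        if refined == window_size:
            break
        window_size = refined

    if len(kept_t) == 1:
        flag = FLAG_OK
    elif len(kept_t) == 2:
        flag = FLAG_TWO_STEP
    else:
        flag = FLAG_UNRELIABLE
    return ThResult(
        well_id=curve.well_id,
        th_primary=kept_t[0],
        th_secondary=kept_t[1] if len(kept_t) >= 2 else None,
        window_size=window_size,
        peak_rate=kept_h[0],
        flag=flag,
    )


def analyze_plate(
    plate: Mapping[str, MeltCurve | None] | Iterable[MeltCurve],
    config: AnalysisConfig | None = None,
) -> dict[str, ThResult]:
    """Run :func:`call_th` on every well of a plate.

    Accepts a mapping well -> curve (``None`` marks an empty well, reported
    NS) or an iterable of curves keyed by their ``well_id``.  Duplicate well
    ids raise a validation error.  Deterministic given inputs and config.
    """
    config = config or AnalysisConfig()
    if isinstance(plate, Mapping):
        items = list(plate.items())
    else:
        items = [(c.well_id, c) for c in plate]
    seen: set[str] = set()
    for well, _ in items:
        if well in seen:
            raise ValidationError(f"duplicate well id {well!r}")
        seen.add(well)
    if not items:
        raise ValidationError("plate has no wells")
    results: dict[str, ThResult] = {}
    for well, curve in items:
        results[well] = _ns_result(well) if curve is None else call_th(curve, config)
    return results
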