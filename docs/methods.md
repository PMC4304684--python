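# Methods

## The Tₕ-calling algorithm

Thermofluor melt curves are heterogeneous: sloped native baselines, high
dye background, post-transition quenching as aggregates strip dye, double
transitions, and wells with no usable signal. Fitting a full thermodynamic
unfolding model to such data is fragile, so the melting temperature is
located numerically as the maximum of the fluorescence rate of change.

**Window selection.** For every window size *w* from `window_min` (5) to
`window_max` (35) points, every contiguous window of the curve is fitted by
ordinary least squares, giving a slope *a* and Pearson correlation *r*. A
window is *eligible* when *a* > 0 (unfolding raises fluorescence; the
post-peak quench must never be selected) and *r* ≥ `r_min` (0.996, an
empirical linearity gate). Among eligible windows the largest *w* wins —
larger windows are more noise-robust — and within that size the steepest
slope, ties resolving to the lower start index. Constant windows have
undefined correlation; it is defined as 0 so they are never eligible. If no
window is eligible the curve is declared no-signal. Note that the gate is
genuinely restrictive: a transition must present an approximately linear
rising flank above the noise. A half-amplitude transition at 1% noise sits
close to the r = 0.996 detection limit, and some noise realisations of such
curves are rejected — this is the intended behaviour of the gate, not a
failure mode.

**Rate of change.** With the selected size *w*, the derivative d*F*/d*T* is
approximated at every data point by the least-squares slope of the window
centred on that point, truncated at the curve edges (minimum 3 points).
Each slope is associated with its window's mean temperature: for a full
odd-sized window that is the centre point itself, while for even-sized and
edge-truncated windows the mean is the window's true centre — snapping to a
data point instead would shift every derivative feature by up to half a
grid step (a 0.5 °C bias on the standard 1 °C ramp).

**Peak calling.** A cubic smoothing spline (interpolating by default,
`spline_smoothing_factor` = 0) is evaluated on a dense grid
(`dense_grid_step` = 0.05 °C). Local maxima are ranked by height; a peak
survives if it reaches `prominence_fraction` (0.1) of the tallest peak
*and* a robust noise floor (`ns_noise_multiplier` = 3 × the median absolute
deviation of the rate series' first difference — an estimate of the rate
noise that is insensitive to the transition peak itself). Peaks within
`min_peak_separation` (3 °C) of a taller survivor are absorbed by it. One
survivor → flag `OK`; two → `TWO_STEP` with both temperatures reported;
more → `UNRELIABLE` (top two still reported). If the tallest peak misses
the noise floor, or no window was eligible, the flag is `NS` and no Tₕ is
reported.

**Edge refinement.** Smoothing with a *w*-point window attenuates the
derivative peak; near the ends of the temperature ramp the windows truncate,
the attenuation weakens, and rates close to the edge are inflated relative
to the interior. For a broad transition ending near the final temperature
this drags the spline argmax away from the true midpoint by more than a
degree. `call_th` therefore iterates: if the tallest peak lies where its
rate windows were truncated, the window size is shrunk to the largest size
that fits completely at that temperature and the peak search repeats (the
size never grows again, so the loop terminates). Interior peaks are
untouched. On noiseless two-state curves with Tm ∈ [35, 90] °C and van't
Hoff enthalpy ∈ [200, 600] kJ/mol sampled on the 24–95 °C, 1 °C ramp this
keeps every calling error ≤ 0.25 °C; at 1% noise errors stay below ~0.7 °C.

**Degenerate inputs.** Temperatures must be strictly increasing (descending
scans are rejected, not silently reversed — instrument ramps ascend), all
values finite, and curves at least `window_min` points long. Ties in peak
height resolve to the lower temperature.

## Screens, universal buffers and pH correction

The packaged `ph` and `salt` screens store **final** assay concentrations
(the wet-lab stocks are 2×, mixed 1:1 with protein-plus-dye;
`save_screen(..., stock2x=True)` emits the stock plate). The pH screen
deconvolutes buffer identity from pH: single buffers spanning pH 4.2–12.3,
and three universal buffers — A: succinate/phosphate/glycine, B:
citrate/HEPES/CHES, C: malonate/imidazole/borate, each conjugate pair at
200 mM (600 mM total) — titrated over the twelve acid:base mixing ratios
11:0, 10:1, …, 0:11. The measured pH of each buffer at each ratio is
shipped as data (`UNIVERSAL_BUFFER_PH`); the package never predicts pH from
composition. Two oddities of the source tables (a 5 mM entry inside the
GuHCl molar dilution series, and the formula "Na2NO3") are transcribed
verbatim and flagged in the fixture comments rather than silently
corrected.

A buffer's pKa drifts with temperature, so the pH a well actually had at
its melting temperature differs from the pH measured at 25 °C.
`corrected_ph` applies the linear correction pH(Tₕ) = pH₂₅ + (ΔpKa/°C) ×
(Tₕ − 25). ΔpKa/°C is user-supplied per condition; when absent it defaults
to 0 with a warning (amine buffers like Tris, at ≈ −0.028/°C, shift by more
than a pH unit over a typical melt).

## Plate analytics

The reference Tₕ is the **mean** of the primary Tₕ over the screen's
reference wells with an `OK` call (one reference well in the pH screen,
three water blanks in the salt screen). ΔTₕ > 0.5 °C (the configurable
`neutral_band`) classifies a well `INCREASE`, < −0.5 °C `DECREASE`,
otherwise `NEUTRAL`; `TWO_STEP`, `UNRELIABLE` and `NS` flags pass through
unchanged, and INCREASE/DECREASE wells carry an |ΔTₕ|-quartile shade bin
for heat-map rendering. Waterfall plots label a curve `shifted` when its
|ΔTₕ| exceeds a fixed threshold (default 1.0 °C) — a deliberate,
assumption-free stand-in for a significance test, since single-well screens
carry no replicate structure. Dose–response series normalise molar units to
µM (M × 10⁶, mM × 10³); percent and fold (×) species have no molar scale
and are excluded.

## Synthetic data

The generator emulates the standard two-state unfolding equilibrium: the
unfolded fraction is f(T) = 1/(1 + exp[(ΔH_vH/R)(1/T − 1/Tm)]) (T in
kelvin), which is ½ at Tm and sharpens with the van't Hoff enthalpy ΔH_vH.
Fluorescence superimposes a (optionally sloped) native baseline, a bright
unfolded plateau and an exponential quench beyond the point where the
transition is essentially complete (f > 0.99), reproducing the
rise-then-fall of real traces; variants give double transitions (weighted
sum of two f terms), high background, and flat no-signal wells. Defaults:
Tm 60 °C, ΔH_vH 400 kJ/mol (typical for a multimeric enzyme; it affects
transition width only), baselines 1 000 → 10 000 AU, and the 24–95 °C,
1 °C-per-step grid of a standard qPCR hold-per-degree ramp. Noise is
additive Gaussian for melt curves and multiplicative Gaussian for
isotherms; "1% noise" in the tests means 1% of the folded→unfolded
amplitude (90 AU) or 1% of each response, respectively. All generators
draw from an explicitly seeded `numpy.random.Generator`.

What the generator does **not** emulate: scan-rate-dependent (kinetic)
unfolding, aggregation nucleation, well-to-well optical crosstalk,
temperature-calibration error, or the correlated (non-white) noise of real
instruments. Passing tests therefore demonstrate the correctness of the
algorithms under the stated model, not instrument-grade robustness.

## Binding isotherms and layer mass

Equilibrium responses are fitted with Langmuir saturation models, one site
R(C) = Rmax·C/(K_d + C) or two independent sites summed, each site with its
own free Rmax. Parameters are fitted on a log scale (positivity is
structural, no active constraints), by Levenberg–Marquardt least squares.
The one-site fit starts from K_d at the half-maximal concentration and
Rmax at 1.1× the maximal response; the two-site fit is multistarted (8
seeded starts spread over the concentration range) because sites can swap
or collapse into local minima, and is reported ordered K_d1 ≤ K_d2. "Is a
second site justified?" is answered by the extra-sum-of-squares F-test on
the nested pair (2 extra parameters, α = 0.05), with small-sample-corrected
AICc reported alongside. Under the reference recovery conditions (K_d 15
and 99 µM, equal amplitudes, 1% noise, 14 log-spaced concentrations
0.5–1000 µM) the Cramér–Rao bound puts the standard deviation of the larger
constant at ≈ 16% — the fit attains that bound, so scatter of that order
between noise realisations is information-theoretic, not an optimiser
deficiency.

Adsorbed-layer bookkeeping starts from an already-resolved layer thickness
and refractive index (the optical inversion of the two waveguide
polarizations is instrument software, out of scope here). The de Feijter
relation converts the refractive-index excess over the running buffer into
protein density, density = (n_layer − n_buffer)/(dn/dc), with the standard
protein refractive-index increment dn/dc = 0.182 ml/g (configurable), and
areal mass = density × thickness; in g/cm³ × nm the conversion to ng/mm²
is exactly 1.

## Problem sizes in the test suite

The statistical suites use 100-curve sweeps for Tm recovery and no-signal
specificity, 50 curves for brute-force window-selection equivalence, and
100 seeds for isotherm recovery and model-selection power; these sizes give
stable pass/fail behaviour for the asserted thresholds while keeping the
full suite around a minute on one CPU.
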