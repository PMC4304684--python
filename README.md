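# meltshift

Analysis toolkit for **thermal shift assays** (TSA / Thermofluor /
differential scanning fluorimetry) and **equilibrium binding isotherms**
from surface biosensors such as dual polarization interferometry (DPI).

A thermal shift assay follows an environment-sensitive dye (e.g. SYPRO
Orange) while a protein solution is heated: as the protein unfolds, its
hydrophobic core becomes solvent-exposed, the dye binds and fluorescence
rises. The temperature of hydrophobic exposure, *T*ₕ — the midpoint of the
unfolding transition — shifts when a buffer, salt or ligand stabilises or
destabilises the protein, which makes 96-well screens of melting
temperatures a cheap, general probe of protein–ligand interactions and of
crystallisation-friendly buffer conditions.

`meltshift` provides:

* **Tₕ calling** (`meltshift.melt_core`): a numerical algorithm — no
  thermodynamic model fit — that finds the denaturation window by sliding
  linear regressions of increasing size (5–35 points) over the curve and
  keeping windows with slope *a* > 0 and Pearson *r* ≥ 0.996, estimates the
  rate of change d*F*/d*T* with centred windows of the selected size,
  interpolates it with a spline and reports up to two maxima as melting
  temperatures. Curves without a credible transition are flagged `NS` (no
  signal); double peaks give `TWO_STEP`; more than two, `UNRELIABLE`.
* **Screen definitions** (`meltshift.screens`): machine-readable 96-well pH
  and salt screens (single buffers pH 4.2–12.3, three universal
  three-component buffers titrated over twelve acid:base ratios, common
  salts, osmolytes and a divalent-metal block), plus the linear
  ΔpKa/°C temperature correction of buffer pH at *T*ₕ.
* **Plate analytics** (`meltshift.plate_analysis`): ΔTₕ against reference
  wells, heat-map categories, pH-stability profiles per buffer system,
  dose–response series and waterfall orderings for serial dilutions.
* **Synthetic data** (`meltshift.synthgen`): two-state van't Hoff melt
  curves (single/double transitions, high background, post-peak quench,
  flat no-signal), full plates and Langmuir isotherms, all seeded and
  bit-reproducible, so every stage is testable without instrument data.
* **Binding isotherms** (`meltshift.dpi_binding`): one-site
  *R*(C) = *R*max·C/(K_d + C) and two-site (sum of two such terms) fits by
  log-parameterised multistart least squares, an extra-sum-of-squares
  F-test to decide whether a second site is justified, and adsorbed-layer
  bookkeeping via the de Feijter relation
  (density = Δn / (dn/dc), areal mass = density × thickness).

## Worked example

Simulate a serial-dilution plate (each row a two-fold dilution of one
additive from 10 mM; row H an additive-free reference), call every well and
fit a two-site binding isotherm:

```sh
$ meltshift simulate --layout dilution_series --seed 7 --out demo/
$ meltshift analyze --plate demo/plate.csv --out demo/results.csv
wrote 96 wells to demo/results.csv
$ head -4 demo/results.csv
well,th1,th2,window_size,peak_rate,flag,delta_th,category
A1,67.90,,11,765.392250,OK,,NEUTRAL
A2,67.90,,11,759.491958,OK,,NEUTRAL
A3,67.80,,11,761.434980,OK,,NEUTRAL
```

Well A1 holds 10 mM of additive, enough to saturate its stabilising effect:
its called Tₕ of 67.9 °C sits ~8 °C above the 60 °C additive-free baseline
(`th1` is the primary melting temperature in °C, `window_size` the selected
regression window in points, `peak_rate` the derivative maximum in AU/°C).

Fitting a noisy two-site isotherm (true site dissociation constants 15 and
99 µM) and letting the F-test choose the model:

```sh
$ meltshift dpi-fit --in demo/iso.csv --model auto
{
  "one_site":  { "kd_um": 33.83, ... },
  "two_site":  { "kd1_um": 15.11, "kd2_um": 103.01, ... },
  "selection": { "chosen": "two_site", "f_statistic": 215.4,
                 "p_value": 6.0e-09, ... }
}
```

The single-site model averages the two sites into an apparent 33.8 µM
affinity; the nested F-test rejects it decisively (p ≈ 6×10⁻⁹) and the
two-site fit recovers both constants (15.1 and 103 µM) within the
uncertainty the 1% noise allows.

Other entry points: `meltshift screens --name ph --out ph.csv [--stock2x]`
exports the packaged screens (optionally as 2× wet-lab stocks), and
`meltshift analyze --builtin salt --heatmap plate.png --profiles prof.csv`
adds plate heat maps and pH profiles.

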