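# hicr — heat-induced Ca²⁺ release analysis

Malignant-hyperthermia mutations of the skeletal-muscle Ca²⁺-release
channel RyR1 make cells abnormally sensitive to heat: a local
temperature rise of only a degree or two can trigger an explosive
cytosolic Ca²⁺ burst from the ER store. Quantifying that sensitivity
requires an unusual measurement chain — an infrared laser delivers a
heat pulse whose amplitude ΔT falls off with distance from the focus, a
thermally quenched luminescent dye calibrates ΔT, and Ca²⁺-indicator
time series from many cells at many distances are reduced to a single
per-line number: **ΔT_th, the temperature rise at which 50% of cells
respond**.

`hicr` implements that chain for imaging labs and method developers:

* **thermometry** — Eu-TTA quench ratios
  `ΔF/F₀ = (F_heating − I_laser)/(F_before − I_back) − 1` converted to
  ΔT at the calibrated slopes (−2.7 %/°C at 24 °C, −4.1 %/°C at 36 °C),
  single-exponential photobleach correction, isotonic radial profiles,
  per-cell ΔT assignment;
* **burst metrics** — ΔF_max/F₀ in the 20 s after heating initiation
  (cytosolic), −ΔF_min/F₀ in the 2.4–10 s window (ER store), scatter
  subtraction, store normalisation, ER–cytosol correlation;
* **response statistics** — spontaneous fluctuations of unheated cells
  fitted with a Gaussian CDF `½[1 + erf((x−µ)/√(2σ²))]`, responder
  threshold ΔF_th = µ + 1.96σ, responder classification
  (ΔF_max/F₀ > ΔF_th), and ΔT_th from a floor-anchored logistic MLE
  `p(ΔT) = 0.025 + 0.975·logistic((ΔT−m)/w)` with bootstrap CI;
* **synthetic data** — a ground-truthed generator emulating the whole
  experiment (radial field with sub-100-ms rise, quenched thermometer
  traces, Bernoulli bursts logistic in ΔT, SERCA dip, ER-depletion
  minimum ~5 s post-pulse, bleaching, scatter, shot noise), used to
  validate the pipeline by parameter recovery.

See `docs/methods.md` for the model and the numerical choices.

## Worked example

Simulate a cohort of 1000 heated R164C-like cells (ΔT uniform on
0–6 °C, base temperature 36 °C) plus 100 unheated controls, then run
the full pipeline — sheet thermometry, ΔF_max/F₀, fluctuation
threshold, dose–response fit:

```python
from hicr.scenarios import recovery_config, run_recovery

cfg = recovery_config("R164C", 36.0, seed=1, n_cells=1000,
                      deltaT_range=(0.0, 6.0))
report, truth = run_recovery(cfg, n_boot=200)
```

Output:

```
fluctuation fit: mu=0.0616 sigma=0.0318 dF_th=0.1240 (n=100)
responders: 738/1000
dT_th = 1.39 degC  (95% CI 1.18-1.57), generative truth 1.4
```

The fluctuation model says unheated cells wander by ~6 ± 3% of
baseline, so only excursions above 12.4% count as responses; 738 of
1000 heated cells cross that bar, and the fitted 50% point recovers the
generative threshold (1.4 °C — a strongly heat-sensitized line) to
within 0.01 °C.

The same stages are available from the shell:

```bash
hicr simulate --seed 1 --mutant R164C --n-cells 300 --out sim/
hicr run --traces sim/traces.csv --rois sim/rois.csv --seed 1 --out out/
```

## Analysis scripts

`analysis/` holds the narrative drivers, each writing small tables to
`results/analysis/` (bulky raw cohorts go to `scratch/`):

1. `01_simulate_cohorts.py` — the ten line × temperature cohorts with
   their ground truth.
2. `02_temperature_calibration.py` — radial ΔT profiles at three laser
   powers (monotone decay, linear power scaling, ~10 °C at 10 µm for
   25.6 mW).
3. `03_burst_metrics.py` — per-line burst sizes and ER depletion at a
   fixed ~10 °C pulse, and their across-line correlation.
4. `04_dose_response.py` — ΔT_th for every line at both base
   temperatures, with bootstrap CIs and rank orders.

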