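# Methods

`hicr` quantifies heat-induced Ca²⁺ release (HICR) from single-cell
fluorescence recordings of optically applied heat pulses. A focused
infrared laser heats the medium locally for a few seconds; a
temperature-sensitive luminescent dye (Eu-TTA) on a cell-free dish
calibrates the temperature rise ΔT as a function of distance from the
focus, and cytosolic (fluo-4 / Cal-520) or ER-luminal (G-CEPIA1er)
Ca²⁺ indicators report the cellular response. The analysis produces,
per cell line and base temperature T₀, the heat-sensitivity threshold
ΔT_th — the temperature rise at which half the cells fire a Ca²⁺
burst.

All times are seconds from the start of the observation, distances in
µm, temperatures in °C (ΔT is a rise above T₀), intensities in camera
units.

## Thermometry

Eu-TTA luminescence is thermally quenched at a calibrated linear rate:
−2.7 %/°C at T₀ = 24 °C and −4.1 %/°C at T₀ = 36 °C. The quench ratio
of a sheet recording is

    ΔF/F₀ = (F_heating − I_laser) / (F_before − I_back) − 1,

where `F_heating` is the intensity at the end of the heating period
(mean of the final two laser-on frames, for robustness to single-frame
noise), `F_before` the intensity just before heating was initiated,
`I_back` the excitation-off (dark) background and `I_laser` the *total*
background during laser-on frames (dark + IR scatter — what a cell-free
ROI reads while the laser is on; with this convention the formula
isolates the dye signal exactly). ΔT = (ΔF/F₀) / slope(T₀). Lookup of
an uncalibrated T₀ fails loudly; muscle experiments at 23 °C are mapped
to the 24 °C slope by the caller, with a logged warning.

`F_before` is the single frame at, or immediately before, the pulse
onset, restricted to pre-laser frames: if the frame falling exactly on
the onset time was already acquired with the laser on, the last
laser-off frame before it is used. Without that restriction the
baseline absorbs scatter and the heating-associated intensity dip and
every downstream ratio is biased.

Photobleaching is corrected by a single-exponential fit
`F(t) = A·exp(−k t)` on the pre-stimulus segment (log-linear least
squares polished by nonlinear least squares; exact on noise-free
exponentials). The trace is divided by `exp(−k t)`; a non-positive
fitted rate leaves the trace unchanged, flagged. The fit is applied to
the background-subtracted dye signal, since the additive backgrounds do
not bleach.

A radial profile is built from sheet recordings at ≥ 3 distances:
per-distance ΔT values are regularised to be non-increasing in distance
(isotonic regression — physically, heat spreads out from a point
source) and each cell is assigned the ΔT at its own distance by linear
interpolation in log-distance, clamped at the measured range.

## Per-cell burst metrics

For cytosolic indicators, with F₀ = F_before − I_back:

* ΔF_max/F₀ — maximum of (F − F_before)/F₀ over the 20 s following
  heating initiation, after subtracting the IR-scatter excess
  (I_laser − I_back) from laser-on frames. No smoothing anywhere; all
  statistics are frame-wise. Windows are closed on both ends with
  half-frame timestamp tolerance.
* Spontaneous ΔF_max/F₀ — same statistic on unheated control cells,
  with F_before at 10 s and the maximum over 10–30 s, mirroring the
  light exposure of the heating experiments.

For the ER indicator, ΔF_min/F₀ is the minimum of (F − F_before)/F₀
between 2.4 s and 10 s after heating initiation (the early bound
excludes the thermal-quench epoch of the pulse itself), after bleach
correction; the depletion magnitude is −ΔF_min/F₀. Burst sizes can be
normalised by a line's resting ER Ca²⁺ level relative to wild type
(ΔF_max/F₀ ÷ store level). Across-line coupling between ER depletion
and cytosolic burst size is summarised by Pearson correlation of group
means.

## Responder threshold and ΔT_th

The spontaneous ΔF_max/F₀ values of unheated cells are fitted, by least
squares on the empirical CDF (plotting position i/n at the i-th sorted
value), with the Gaussian CDF

    F(x) = ½ [1 + erf((x − µ) / √(2σ²))],

and the responder threshold is ΔF_th = µ + 1.96σ: a heated cell
responds when its heat-pulse ΔF_max/F₀ strictly exceeds ΔF_th (ties are
non-responders). One pooled fluctuation model is used per cell line and
base temperature. Because the empirical CDF is fitted rather than
moments matched, σ can differ slightly from the sample SD.

ΔT_th is estimated from the per-cell (ΔT, responder) pairs by maximum
likelihood under a floor-anchored logistic,

    p(ΔT) = c + (1 − c) / (1 + exp(−(ΔT − m)/w)),   c = 0.025 fixed,

with ΔT_th = m, the 50% point of the heat-induced component. The floor
is not a free parameter: by construction ΔF_th sits at the 97.5th
percentile of the fitted fluctuation Gaussian, so ~2.5% of cells cross
it without a heat-induced burst. A plain two-parameter logistic absorbs
that floor by widening and is biased low — by ~0.3 °C asymptotically
when the sampled ΔT range extends well below the midpoint (the WT,
T₀ = 24 °C condition) — while a freely estimated floor is weakly
identified when the midpoint lies near the range edge. Anchoring the
floor at its construction value removes the bias without adding a
parameter. The 95% CI comes from a nonparametric bootstrap over cells
(default 1000 resamples, seeded). When the MLE degenerates (e.g.
complete separation), the estimate falls back to isotonic regression
of responder state on ΔT with linear interpolation of the 50% crossing,
flagged in the output. Binned response curves (equal-count quantile
bins, ≥ 8 cells per bin) are reported alongside for display.

Two-sample comparisons use the two-sided Mann–Whitney U test: the exact
permutation distribution (dynamic-programming recursion;
p = 2·min(P(U ≤ u), P(U ≥ u)), capped at 1) when both groups have ≤ 9
tie-free observations, otherwise the normal approximation with tie
correction.

## Synthetic data generator

The generator emulates the microheating experiment end to end and
carries its ground truth (per-cell ΔT, burst occurrence, amplitude), so
the pipeline can be validated by parameter recovery.

**Temperature field.** Separable, ΔT(r, t) = A(r)·g(t), with
A(r) = a·P/(r + r₀) (P laser power in mW; defaults a = 7.8125 °C·µm/mW,
r₀ = 10 µm put 10 °C at r = 10 µm for 25.6 mW, matching the measured
gradients and linear in power) and first-order rise/fall gating with
τ = 50 ms, consistent with the observed sub-100-ms onset. This is a
phenomenological stand-in, not a heat-conduction solution; its job is
monotone radial decay, power linearity and fast kinetics.

**Traces.** Every trace is dye·bleach + I_back + scatter·laser_on +
noise. Bleaching is exponential (default 0.001 s⁻¹); noise is a
Gaussian approximation of shot noise with SD scaling as √intensity
(default 1 a.u. at the 100 a.u. baseline; zero for exactness tests).
Thermometer-sheet ROIs average 16 pixels, so their noise is a quarter
of a single pixel's — the measured gradient curves are smooth. Cell
baselines are drawn per cell (100 ± 10 a.u.).

**Cytosolic cells.** A heat-induced burst occurs with probability
logistic((ΔT − ΔT_th,true)/w), the minimal smooth monotone law sharing
its form with the estimator; per-line generative midpoints are the
published per-line thresholds (36 °C: R164C 1.4, R164L 1.4, Y523S 4.3,
Q156K 4.9, WT 5.8; 24 °C: R164L 1.4, R164C 1.8, Y523S 3.8, Q156K 7.9,
WT 11.5), width 1 °C. Burst amplitude is truncated-normal (per-line
mean 1.2–2.5 ΔF/F₀ units, chosen so leakier lines with depleted stores
fire smaller bursts); onset follows the line's latency phenotype
(during heating, or just after recooling starts), with a grid-aligned
linear rise (~0.4 s) and exponential decay (4 s), so a noise-free burst
of amplitude a yields ΔF_max/F₀ = a exactly. A multiplicative SERCA
dip (2–10%) lowers the dye signal during the pulse. An optional
saturation factor interpolates the indicator's Ca²⁺ affinity between
its published 22 °C and 37 °C dissociation constants (520 / 190 nM);
it is off by default because the analysis operates on raw intensities.

**Spontaneous activity.** Every cytosolic cell shows recurring
mini-transients — one per 15-s block, ≥ 3 s apart — with a per-cell
amplitude |N(0.08, 0.025)| well above the frame-noise floor, plus rare
extra events (Poisson, 0.002 s⁻¹). This makes the across-cell
distribution of spontaneous ΔF_max/F₀ approximately Gaussian, the shape
the threshold procedure assumes and the shape reported for the real
fluctuation data. (An earlier iid-Poisson-event model produced an
extreme-value-skewed distribution whose 6–8% threshold-crossing rate is
not what the calibration implies.) Setting the line's spontaneous rate
to zero disables all spontaneous activity.

**ER cells.** Thermal quench of −2 %/°C during the pulse, then a
store-depletion dip of Gaussian shape whose minimum falls 5 s after
pulse cessation, with depth 0.1·amplitude/store level — deeper for
bigger bursts, shallower (relative to its own F₀) for fuller stores —
followed by recovery.

**Cohorts.** Heated cells at explicit distances or with ΔT drawn
uniformly over a configurable range (the cell is placed at the distance
producing that plateau ΔT); 100 unheated control cells; one cell-free
background ROI (scatter only); a thermometer sheet of 40 log-spaced
distances spanning the cells' range. Randomness is counter-based: cell
i draws from `default_rng([seed, i])`, so datasets are bit-reproducible
and growing a cohort never reshuffles earlier cells. An image mode
renders cohorts as 16-bit multi-page TIFFs of uniform disks whose ROI
means reproduce the traces to one quantisation step.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: optics (no PSF, no cell morphology,
uniform disks only), heat conduction (no transients beyond first-order
kinetics, no convection), indicator kinetics (no on/off rates, no
dye saturation unless enabled), mechanical artefacts (focus drift,
motion), and any within-line heterogeneity of heat sensitivity (a
single ΔT_th per line). Parameter recovery shows the estimator chain is
consistent under the stated statistical structure, not that the
structure is true of any particular experiment.

## Study conditions for validation

Recovery cohorts use 1000 heated cells (ΔT uniform over [0, 15] °C at
36 °C, [0, 20] °C at 24 °C — spanning each line's midpoint; laser power
25.6 / 51.2 mW accordingly) plus 100 unheated cells; the R164C cohort
narrows the range to [0, 6] °C. Rank-order replication across the five
36 °C lines uses 300 heated cells over [0, 9] °C, twenty seeded
replicates, and requires every strictly-ordered pair of generative
thresholds to be estimated in the right order (the R164C/R164L tie is
unconstrained). These sizes put the estimator's Monte-Carlo error well
inside the ±0.5 °C recovery band.

## Numerical choices and degenerate inputs

* Empirical-CDF fit: `scipy.optimize.curve_fit`, initialised at sample
  moments; zero-spread input returns σ = 0 with a warning.
* Floor-anchored MLE: Nelder-Mead on (m, log w), initialised from a
  plain `statsmodels` logistic fit; rejected (→ fallback) on
  non-convergence, non-positive slope, or a width exceeding 10× the
  sampled range. ΔT_th outside the sampled range is an error.
* Isotonic steps: `sklearn.isotonic`; ties in the profile average
  duplicated distances first.
* Quantile binning deduplicates bin edges; all-identical ΔT is an
  error.
* Exact U distribution is cached per (n₁, n₂); ties or n > 9 switch to
  the asymptotic path.
* Excluded cells (dead baseline, incomplete windows) are dropped and
  logged with machine-readable reasons; a cohort without unheated cells
  requires an explicit ΔF_th.

## Limitations

The floor anchor assumes the fluctuation fit is well calibrated; if the
real spontaneous distribution is heavily skewed the residual floor will
differ from 2.5% and ΔT_th inherits a small bias. ΔT assignment
interpolates a static end-of-pulse profile; experiments where the
gradient drifts between sheet calibration and cell recording are not
modelled. The two published quench slopes restrict thermometry to
T₀ ∈ {24, 36} °C unless user slopes are supplied.
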