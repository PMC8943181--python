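# Methods

This note records the models, conventions and design choices behind
`orsmoke`, and what the synthetic-data tests do and do not establish about
real operating-room data.

## Measurement model and processing

A record is a multichannel concentration time series (ppb by volume, 1 s
grid) bracketed by protocol windows: a pre-operation instrument blank, a
standard-gas calibration window, the operation segment, and a
post-operation blank. Processing assumes

* an additive instrument/ambient background that is stationary across the
  record (so the pre-operation blank mean estimates it), and
* a per-channel multiplicative instrument sensitivity that is stable within
  one operation (single-point calibration; drift within an operation is not
  modelled).

`subtract_blank` removes the channel-wise blank-pre mean from every sample.
Negative results are retained: clipping at zero would bias means and totals
upward. `calibrate` multiplies each channel by
`standard / mean(calibration segment)`; channels without a standard are
left unchanged and flagged. Summaries (mean, max, argmax time) are computed
over the operation segment only — the blanks and calibration describe the
instrument, not the exposure. Argmax ties break to the earliest sample,
which makes the argmax-time statistic deterministic on flat or quantized
signals; the argmax-time fraction divides by the operation-segment length,
so it lies in `[0, 1)` on the sampling grid.

### Compound registry

The packaged panel transcribes a 32-row table of harmful VOCs observed at
surgeon level without smoke evacuation: name, CAS number(s), hazard
classes, OSHA/NIOSH permissible exposure limits, and reference
average/maximum concentrations. Conventions:

* Rows naming several isobaric compounds are one record (PTR-MS cannot
  separate isobars); the molecular formula and weight are those of the
  first-listed compound. Formulas are supplied by the package from the
  compound identities — uncontroversial chemistry needed for the
  ppb-to-mass bridge.
* Limits printed without an agency attribution are stored in the OSHA
  column; the governing limit is the minimum of those present, so the slot
  choice has no numeric effect.
* The methanol and ethanol limit cells are printed on a doubtful unit
  scale in the source (conventional NIOSH limits for both are in ppm).
  They are transcribed verbatim in ppb and flagged `limit_suspect`; the
  exceedance screen evaluates but quarantines them in a suspect-limit
  section instead of guessing a rescale.
* The panel's average column sums to 272.70 ppb, matching its printed
  total (272.69) to last-digit rounding. The maximum column sums to
  9991.01 ppb while the printed maximum total is 8991; the two cannot be
  reconciled from the table alone (the printed figure may be the maximum
  of the summed time series rather than a column sum), so reports carry
  both values with an explicit note.

Exceedance uses a strict inequality (`max > limit`) against the most
stringent limit; compounds with no limit are "unassessed" and never
flagged.

## Exposure arithmetic

`Vm = R·T/P` with R = 8.314462618 L·kPa/(mol·K); at the 298.15 K /
101.325 kPa defaults Vm = 24.465 L/mol (the industrial-hygiene convention
rounds this to 24.45; the difference is 0.07 % and both sit inside the
tolerances used here). Then `µg/m³ = ppb × MW / Vm` and the per-operation
dose is `ppb × 10⁻⁹ × V̇·D/Vm × MW × 10⁶` µg with minute ventilation
V̇ = 5 L/min and duration D = 120 min by default. Doses are linear in
concentration, ventilation and duration, and invariant across (T, P) pairs
with equal molar volume.

Uptake divides the inhale-minus-exhale mean difference by the inhaled
mean; instrument noise can push the raw ratio outside `[0, 1]`, so the
fraction is clipped with a flag rather than silently. The fraction is
undefined when the inhaled mean is non-positive (the absolute difference is
still reported). Cigarette equivalence divides the dose by a packaged
per-cigarette emitted mass (acetaldehyde 2000 µg, 1,3-butadiene 130 µg);
compounds without a reference return no equivalence.

## Synthetic OR-air generator

The generator provides ground truth, not realism in every detail. One
operation is simulated as

* cautery activations: homogeneous Poisson, default 1 activation/min;
* per-activation amplitudes: log-normal per compound, default mean
  30 ppb with coefficient of variation 1 (heavy-tailed maxima, matching
  the orders-of-magnitude spread between average and maximum panel
  concentrations);
* clearance: each plume decays as `exp(−k t)` with k = 0.05 s⁻¹
  (≈ 20 s time constant, a stand-in for a laminar-flow OR; no spatial
  airflow modelling);
* factor effects are multiplicative on emission amplitude: smoke-evacuation
  attenuation 0.5 (the halving assumed by the study-design power
  calculation), room-air dilution 0.8, open-surgery factor 1.3 (chosen to
  match the reported direction and rough size of location and approach
  effects on maxima);
* background (anesthetic gases, instrument background) is constant across
  all segments; the calibration window adds a known standard
  (default 100 ppb); the instrument multiplies truth by a per-channel
  sensitivity and adds white noise (default sd 0.5 ppb).

`config_from_registry` scales emission means so the stationary plume mean
`λ·Ā/k` tracks the panel's average column, and treats the anesthetic
carrier gases (desflurane, sevoflurane) as pure background.

Blocked randomization assigns smoke-evacuation use 1:1 within blocks of 4;
a trailing partial block is a truncated balanced block. Breath pairs are
constant-level series with exhale expectation `inhale × (1 − uptake)` and
independent noise.

What the generator does **not** emulate: particulates and aerosols,
spatially varying airflow, instrument drift within an operation,
autocorrelated baseline wander, ion fragmentation and isobaric
interference, or between-surgeon behavioural variation. Passing recovery
and calibration tests therefore establishes that the estimators are
correct under the stated generative model, not that real OR data satisfy
that model.

## Statistics

* **Two-group comparisons** use Welch's two-sided t-test. The reported
  group standard deviations in this setting are clearly unequal, and Welch
  is the safe default when variances differ; p-values are reported raw
  (no multiplicity correction), with the number of tests recorded by the
  pipeline.
* **Effect decomposition** regresses a response on an intercept plus one
  0/1 indicator per factor (`with_ses`, `open`, `surgeon_level`). Coding
  both levels of a factor as separate indicators alongside an intercept
  would be rank deficient and leave coefficients non-identifiable, so one
  indicator per factor is used; a rank check raises an error naming
  collinear columns. Reported are per-factor effects in ppb, the multiple
  correlation R, and the residual sd.
* **Max-time analysis** ranks channels per operation by maximum
  concentration, keeps the top K (default 100; all channels when fewer),
  pools their argmax-time fractions and applies a one-sample
  Kolmogorov–Smirnov test against the uniform distribution on `[0, 1]` —
  the only distribution-free formalization of "no systematic timing
  pattern".
* **Sample size** for a two-sided two-sample t-test defaults to the
  classical normal-approximation formula
  `n = 2·((z₁₋α/₂ + z_power)/d)²`, rounded up, with a floor of 2 — the
  form used by common clinical power calculators; at d = 1.22, α = 0.05,
  power 0.90 it gives 15 per group. An `exact` method searching the
  noncentral-t power curve is also provided; near rounding boundaries it
  can require one more subject per group (16 at the same inputs, where
  the exact power of n = 15 is 0.897). Tests cross-check the exact method
  against an independent power library and a brute-force Monte-Carlo
  power curve.

## Study sizes used by the test suite

Monte-Carlo checks run at desk scale: operations of 240 s (≈ 4 expected
cautery activations) for calibration checks and mixed-design recovery
(200 replicates × 100 operations), and 600 s (≈ 10 activations) for the
power study at 15 operations per arm. The 600 s choice matters: the
standardized smoke-evacuation effect grows with the number of activations
averaged per operation, and at 240 s it sits almost exactly at the d ≈ 1.2
design boundary where a ≥ 90 % rejection check is a coin flip; 600 s
operations put the realized effect near d ≈ 1.7, which is also the more
faithful scaled stand-in for 2 h surgeries with their hundreds of
activations. Type-I calibration uses 500 replicates under the no-effect
generator and under uniform argmax draws, with the nominal 0.05 level
required to within ±0.02. All replicate seeds derive from one fixed base
seed.

## Known limitations

* Single-point calibration and stationary background: slow instrument
  drift within an operation aliases into concentration estimates.
* The exceedance screen is per-compound; it ignores mixture effects and
  compounds with no assigned limit, and inherits the suspect-limit
  ambiguity documented above.
* Dose assumes tidal breathing of well-mixed air at the inlet point;
  no respiratory deposition or toxicokinetic modelling.
* The uptake estimator compares means of paired series; it does not model
  breath-phase segmentation within a mixed inhale/exhale record.
* Group statistics treat operations as independent; within-day or
  within-team correlation is not modelled.
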