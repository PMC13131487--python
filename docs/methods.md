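# Methods

This note documents the models, rules and numerical choices implemented in
`nociscreen`, and what the synthetic-data generators do and do not emulate.

## Calcium-imaging excitability classifier

**Assay model.** Cultured DRG neurons expressing a genetically encoded
calcium indicator are depolarized by repeated 25 mM KCl pulses (15 s pulse,
5 min onset-to-onset spacing, a 15 s lead-in before the first pulse). The
evoked calcium transient is used as a surrogate for excitability. Trials 0
and 1 are drug-free baselines; the candidate agonist is perfused for the
5 min preceding pulse 2 and during that pulse; any later pulses monitor
washout.

**Scoring.** Per trial, excitability is *e* = max ΔF/F over the response
window. The raw-fluorescence baseline F₀ is not prescribed by the assay
description, so it is defined here per trial as the mean F over the 10 s
immediately preceding each pulse onset (configurable via
`StimulusProtocol.f0_window_s`). A per-trial F₀ makes the score robust to
slow baseline drift over the ~25 min session and makes every downstream
quantity invariant to detector gain. The response window defaults to
`pulse_duration + 15 s` from onset — long enough to capture the transient
peak, short enough not to reach the next trial's F₀ window; windows are
half-open `[onset, onset + window)` and overlapping response windows are
rejected at protocol construction.

**Rules.** Baseline QC: include a cell iff |*e*₀ − *e*₁| / mean(*e*₀, *e*₁)
< 0.15, strictly. The denominator is the two-trial mean (symmetric in trial
order); normalizing by the first trial is available as an option. A
non-positive mean fails QC without raising. Drug effect: with baseline
*b* = (*e*₀+*e*₁)/2 > 0 and *r* = *e*<sub>drug</sub>/*b*, the label is
inhibited iff *r* < 0.85 and enhanced iff *r* > 1.15, both strict — a drug
trial at exactly 85% of baseline is unchanged. Cells with non-positive F₀ or
non-positive baseline are excluded with a reason code
(`degenerate_baseline`, `baseline_qc`, `nonpositive_baseline`), never
silently dropped, and the count identity `inhibited + enhanced + unchanged +
excluded = total` holds by construction.

**Strata.** Soma diameter partitions cells into small (< 25 μm), medium
(25–35 μm, both ends inclusive) and large (> 35 μm). Missing diameters map
to `unknown` and never exclude a cell from unstratified summaries;
non-positive diameters are rejected as measurement errors.

**Washout.** The mean excitability of post-drug trials relative to baseline
is reported per cell but feeds no classification: whether washout
non-recovery should gate the drug call is left open by the assay
description, so it is deliberately report-only here.

**Aggregation.** Fractions are over QC-passing cells. Population summaries
are computed pooled across cells; because whether percentages should be
averaged per coverslip/animal first is not specified, `summarize_population`
accepts any subset of classifications, so both aggregations are one list
comprehension away.

## Expression restriction screen

A gene is *restricted* iff its summary value is ≥ `on_threshold` in at least
one CGRP⁺ subtype and < `off_threshold` in every LTMR and proprioceptor
subtype. Two separate thresholds reflect that "expressed in" and "not
expressed in" are asymmetric judgments; both default to 0.1 in the units of
the input summary and must be read as explicit configuration, since no
numeric definition of "expressed" is prescribed — with `off == on` and a
binary matrix the screen reduces to exact set logic. Subtypes of class
`other` (TrpM8⁺, MrgprD⁺, Sst⁺ …) neither qualify nor disqualify a gene;
`strict_other=True` adds them to the exclusion classes. Duplicate gene ids
are rejected at load, results are invariant to row/column permutation, and
raising the on-threshold can only shrink the restricted set. `breadth`
counts the CGRP⁺ subtypes expressing a restricted gene (1 = exclusive to a
single subtype).

## cAMP signaling summaries

Wells are normalized to their own pre-compound baseline (all samples at
t < 0, isoproterenol at t = 0), which cancels per-well detector gain and
reporter load. The response summary is the **peak** luminescence over
5–20 min post-isoproterenol by default — robust to slow reporter kinetics —
with the window mean as an option; which form a given plate reader's export
favors is an open choice, so both are exposed.

Dose-response tables report per-dose mean ± SD of normalized responses
sorted ascending (vehicle dose 0 included) plus a monotone-trend descriptor
from the sign of the Spearman rank correlation between dose and per-dose
mean. An optional 4-parameter-logistic refinement
(`fit_four_param_logistic`, scipy `curve_fit` over positive doses) estimates
the IC50.

The constitutive index is the ratio of mean normalized receptor response to
mean normalized vector response under matched stimulation; it is 1 for
identical groups and inverts under group swap. The qualitative call uses a
fixed effect-size margin δ = 0.2 (Gi-like < 0.8, Gs-like > 1.2): the
original calls rested on significance tests across replicates, but
hypothesis testing is out of scope here, so a margin with reported replicate
dispersion stands in. Note one modelling consequence of per-well baseline
normalization: a receptor that only elevates basal cAMP would normalize to
1, so the generators plant constitutive coupling as a multiplicative change
of the iso-stimulated fold response (scale < 1 Gi-like, > 1 Gs-like),
which is also how the index detects it.

## Behavior rules

* **von Frey**: the 50% withdrawal threshold is the lowest filament force
  with ≥ 5 positive responses out of 10; if no filament qualifies the animal
  is above-range (`None`).
* **Dynamic brush**: per-trial score = max grade (integers 0–3); session
  score = mean over trials; allodynic iff score ≥ 1.5, inclusive.
* **Pinprick**: a trial is valid iff the pin-to-skin contact channel
  strictly exceeds 1.5 V after the button press; stimulus onset is the first
  such sample; movement onset is the first accelerometer sample ≥ 0.15 V
  ("reached", hence inclusive) at or after stimulus onset; magnitude is the
  trapezoidal AUC of the accelerometer over 0.4 s from stimulus onset, on
  the recorded sampling grid, computed even when no movement onset occurs.
* **Paw luminance**: per-frame log₁₀(ipsi/contra). The log base is not
  prescribed; base 10 is used and stated. Frames with either paw at zero
  luminance are masked and excluded from the mean of log-ratios. Because the
  assay's text and its figure conventions suggest different forms, both the
  mean of per-frame log-ratios and the ratio of session means are emitted.
  A session is 30 min at 25 fps = 45,000 frames.
* **Locomotion split**: a frame is locomoting when the 0.5 s
  moving-average-smoothed centroid speed is ≥ 2 cm/s — a conventional rodent
  open-field cutoff, configurable; property tests validate the split against
  planted state labels rather than trusting the default.
* **Preference / events**: preference is the fraction of frames on the
  target side (the two sides sum to 1). Event summaries count annotated
  nocifensive events within the observation window; with zero events the
  latency is censored at the window length and flagged as such, since no
  convention is prescribed.

## oEPSC drug-effect metrics

Amplitudes are stored as magnitudes (inward-current sign handled upstream)
so all ratios are positive. Sweeps are normalized to the mean over the
10 min pre-drug baseline `[drug_on − 600 s, drug_on)`; normalization is
idempotent and gain-invariant, and all windows are defined relative to drug
onset, so a global time shift changes nothing. The drug effect is
`post_mean / pre_mean` with pre `[drug_on − 120 s, drug_on)` and post
`[drug_on + 480 s, drug_on + 600 s)` (the 2 min at 8–10 min after
application, just before washout). Window membership is half-open — a sweep
exactly at drug onset belongs to the drug period. Stability QC compares
every monitored resistance sample to the **first** sample and excludes the
recording iff any deviation strictly exceeds 20% (exactly 20% passes); a
range/mean variant is available. QC failure flags the effect fields as NaN
rather than dropping the recording's normalized series.

## Synthetic-data generators

All generators consume one root seed through `numpy.random.SeedSequence`;
independent child streams are spawned in a fixed documented order, so equal
configurations give bit-identical output.

**Calcium populations.** Traces are
`F₀·(1 + drift·t/60) + F₀·a·exp(−(t−onset)/τ)` per pulse (instantaneous
rise, single-exponential decay — the simplest shape with a well-defined
max), plus i.i.d. Gaussian noise on raw fluorescence. Defaults are the
reference screening conditions used throughout the tests: 500 cells,
responder fraction 0.4, drug-trial amplitude multiplier 0.5 for responders,
noise sd 1% of baseline F, drift 1%/min, τ = 8 s, per-cell peak ΔF/F ~
N(2.0, 0.5) floored at 0.2. τ and the amplitude scale are nominal values
for a fast genetically encoded indicator under sustained KCl
depolarization — the source cultures' kinetics are unreported — and are
fully configurable. Diameters come from a truncated-normal mixture over
small/medium/large strata (weights 0.45/0.35/0.20; means 20/30/40 μm, sd
2.5–3); the ground-truth stratum is derived from the drawn diameter with the
same rule the classifier uses. The generator plants no size-dependence of
drug response and no per-trial amplitude jitter beyond noise, so passing
recovery tests demonstrate the classifier's correctness under the stated
noise model, not robustness to bleaching, movement artifacts or
indicator saturation.

**Expression matrices.** Planted genes get high values (uniform in
[max(on, 0.5), 2]) in a random non-empty subset of CGRP⁺ subtypes and
sub-threshold values in all exclusion subtypes; half of the remaining genes
are decoys expressed in both a CGRP⁺ and an LTMR subtype; the rest are
background below every threshold. Dropout zeroes entries at random but each
planted gene keeps one on-entry and each decoy its violating LTMR entry, so
the planted set is exactly recoverable by construction at any dropout level —
the generator tests the screen's logic, not its behavior under missingness
of the guarantee entries themselves.

**Plate wells, luminance sessions, pinprick trials, oEPSC series.** Each
plants a single effect size (response scale, ipsilateral luminance factor,
contact/accelerometer profile, suppression factor) under simple Gaussian or
lognormal noise, sized to the standard designs (6 replicate wells for
constitutive activity, 3 for dose-response; 30 min × 25 fps sessions; 30 s
sweep spacing with 10 min baseline and 10 min drug). They emulate the
statistical structure the estimators consume, not instrument physics
(no photon counting, no detector saturation, no pose-estimation errors).

## Problem sizes

Tests and the acceptance sweeps run at the reference conditions above
(populations of ≤500 cells at 1 Hz sampling, 20 seeds for parameter
recovery, 10 seeds for screen recovery, rule boundaries on grids of
301–4001 points), which keeps the full suite under a minute while leaving
every estimate's Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The screen cannot reproduce any specific published gene list; it
  implements the restriction logic, which is only as good as the expression
  summaries and thresholds supplied.
* The calcium classifier assumes the trace timebase covers every F₀ and
  response window; partial recordings raise rather than being imputed.
* Coupling calls from the constitutive index use a fixed margin, not
  inference; with few replicates the reported dispersion should temper any
  call.
* Statistical hypothesis testing, dose-response significance, ROI
  segmentation, motion correction and pose estimation are out of scope; the
  package consumes their outputs as tables.
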