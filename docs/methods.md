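# Methods

This note documents the models, operational definitions, parameter choices
and numerical details behind `cardiophys`, including what the synthetic
generators do and do not emulate.

## Signals and units

All traces are uniformly sampled `SampledSignal` objects; time is seconds
internally and intervals are converted to milliseconds only when reported,
matching how murine electrophysiology tables are printed. Voltage is mV;
plethysmography flow units are treated as arbitrary throughout — every
respiratory rule in the package is a ratio, so no flow calibration is
needed. The on-disk format is a `time_s,value` CSV with a JSON sidecar
carrying sampling rate, units and channel label; ABF import is optional and
degrades to a capability error when no reader backend is installed.

## ECG delineation

The target signal is anesthetized mouse lead II at ≥ 1 kHz, acquired
band-limited to roughly 10 Hz – 1 kHz. Definitions, each a config knob on
`ECGConfig`:

* **R peaks** — local maxima of a zero-phase 10–300 Hz band-passed trace,
  refractory-spaced ≥ 40 ms, kept when taller than 40 % of the 90th
  percentile of candidate peak heights. The quantile reference tolerates
  both records where waves fill most of the cycle (short RR) and a minority
  of oversized artefact deflections; polarity is auto-detected from the
  dominant extremum sign.
* **Breathing-interference rejection** — each beat is scored by the RMS of
  the 100–500 Hz band over its window (QRS ± 15 ms blanked). A beat is
  clean when its score is below 3 × the record's median moving RMS in that
  band *and* below 5 % of the R amplitude; the absolute cap is what lets a
  globally contaminated record be rejected rather than renormalized away.
  Analysis uses the earliest run of 5 consecutive clean complexes.
* **QRS onset/end** — the last point before (first after) the maximal
  absolute derivative of the band-passed complex at which that derivative
  falls below 10 % of its beat maximum, sub-sample interpolated.
* **Baseline** — median over a 10 ms window ending 5 ms before QRS onset.
* **QT end** — first return of the lightly smoothed trace (3 ms moving
  average), after the T peak, to within 10 % of the T height above
  baseline. A "return to near baseline after the T peak" has no unique
  textbook definition in mice; the 10 % fraction is this package's
  documented choice and is configurable.
* **J wave** — maximal deflection between QRS end and the T search window,
  reported only above a 0.05 mV floor, measured on a 1 ms-smoothed copy so
  the narrow lobe is not attenuated.
* **P wave** — best effort; PR is reported missing when no P deflection
  exceeds 2 × the baseline noise SD (plus a 0.02 mV absolute floor).

Animal-level summaries average the 5 selected complexes; both QT
corrections are computed per complex and then averaged (for the linear
correction the two orders are identical by linearity; for the square-root
correction the per-beat-then-average order is the package's convention).

Rate corrections: `qtc_mitchell` = QT/√(RR/100) and `qtc_mccauley` =
QT + 0.3173·(170 − RR), both leaving QT unchanged at their reference RR
(100 and 170 ms).

## Action-potential morphology

Per-stimulus windows run from 50 ms before each stimulus to the next
stimulus; a window is captured when the potential crosses 0 mV. Features:

* resting potential: mean over the 40 ms ending 2 ms before the stimulus;
* overshoot and peak time: argmax of a 0.3 ms-smoothed copy refined by a
  local quartic fit over ±1 ms (the quartic term absorbs the asymmetry
  between upstroke and early decay; only an interior local maximum is
  accepted). The peak is the APD clock zero — APD10 values of well under a
  millisecond in murine tables are only possible when APD is clocked from
  the peak rather than the stimulus;
* V_max: maximum of a 5-point Savitzky–Golay first derivative between
  0.5 ms post-stimulus and the peak (the mask excludes the injection
  artefact from the search but not from the peak search);
* APD_x: first sustained above-to-below crossing of
  `overshoot − x/100 · amplitude`, searched sequentially in x (which
  enforces APD monotonicity by construction) with linear interpolation.
  Crossings at x ≥ 60 are refined by a local quadratic least-squares fit
  (window 0.35 × the provisional APD, clipped where the trace leaves the
  level ± 0.12 amplitude band), and the 90 % crossing additionally by a
  local exponential-decay fit `c + A e^(−t/τ)` — the terminal murine
  repolarization is mono-exponential on this scale, and the fitted-curve
  crossing extracts far more precision from a shallow slope than any
  first-crossing rule. Both refinements fall back to the unrefined estimate
  when a fit fails or wanders.

BVR uses the adopted short-term-variability normalization
`Σ|ΔAPD90| / (n_pairs √2)` over the first 10–15 consecutive APs, with
missing-APD pairs excluded. The printed form of the source equation is not
recoverable (it is typeset as an image), so the denominator convention —
consecutive-pair count, √2 normalization — is stated here explicitly;
alternative conventions differ by a constant factor.

## Respiration

Breaths are delimited by zero crossings of the mean-centred flow smoothed
with a 20 ms moving average; lobes with area under 5 % of the median lobe
area are merged into their neighbour (hysteresis against noise-split
breaths). Expiration is the positive lobe by default, with a polarity flag.
The running expiration-time average is recomputed at 60 s ticks over the
trailing 60 s window and held between ticks ("taken every minute"); a
continuously sliding variant is available behind `sliding_average`. The
average is undefined during the first minute, excludes the breath under
test by construction (only completed breaths in the trailing window enter),
and carries forward over empty windows. A breath is an apnoea when its
expiration time strictly exceeds 4 × the running average; events are
restricted to the analysis window (default 60 min) after the adaptation
period (default 20 min). Everything is scale-invariant: multiplying all
expiration times by a constant changes no detection.

## Statistics

Thin, typed wrappers over scipy.stats: mean ± SEM (SD with n−1
denominator), Student and Welch unpaired t-tests with an `auto` mode that
picks Welch when a two-sided F-test of variance equality rejects at 0.05
(a concrete stand-in for "equal or unequal variances as appropriate"),
paired t-test, Mann–Whitney (exact enumeration when n1+n2 ≤ 12 and
tie-free, otherwise tie-corrected normal approximation with continuity
correction), and Pearson correlation with the two-sided t-based p-value.
All p-values are two-sided. Degenerate zero-variance comparisons return
p = 1 (equal means) or p = 0 (unequal) by convention.

## Synthetic generators

The generators exist to give every analysis stage a signal with exactly
known ground truth; they are morphological templates, not biophysical
(ionic-current) models.

**ECG** — each complex is a sum of compactly supported raised-cosine
lobes (P, a single QRS lobe, optional J, T). Compact support makes nominal
onsets exact: QRS spans r ± QRS/2, P starts at QRS onset − PR, and the T
lobe is positioned so its post-peak 10 %-of-height point lands exactly at
QRS onset + QT (for a Hann lobe that point is at 0.89758 of the lobe
width). Beat-to-beat RR jitter is Gaussian (default CV 2 %, a conservative
configurable choice; within-animal interval dispersion is not reported in
the tables the presets target). Breathing-interference bursts are
band-limited 100–500 Hz noise epochs — the morphology the clean-beat
selector rejects. Defaults target the wild-type group means (RR 154.4,
PR 46.1, QRS 12.3, QT 53.3 ms); the `rtt` preset targets the
*Mecp2*-heterozygous means. What the generator does **not** emulate:
baseline wander, electrode motion artefacts, T-P fusion at high rates, or
arrhythmic beats — so passing recovery tests demonstrate correctness of the
measurement definitions, not robustness to every in-vivo nuisance.

**AP trains** — rest, a trapezoidal-velocity upstroke that integrates
exactly to the target amplitude with its plateau at exactly the target
V_max, a parabolic peak cap whose curvature matches the early decay (so the
synthetic overshoot is a smooth, measurable maximum, as in a real rounded
AP peak), and a two-exponential repolarization
`f(t) = w e^(−t/τ1) + (1−w) e^(−t/τ2)` running in warped time
`g(t) = t²/(t+c)` (c = 6 ms) so the decay leaves the peak with zero slope.
The time constants are solved by root-finding so the 50 % and 90 %
crossings land exactly on the APD50/APD90 targets; the fast-phase weight
starts at w = 0.5 — which places the 90 % crossing on its steepest
attainable course and incidentally lands template APD25 near the published
wild-type value — and is raised automatically for target pairs the even
split cannot reach. Past 95 % repolarization the tail is accelerated
(τ = 25 ms) so the membrane is at rest well before the next stimulus.
Ground-truth APD_x is computed by root-finding on the noiseless analytic
template — the same independent oracle the tests use. Beat-to-beat
variability perturbs the APD90 target per beat (Gaussian). Presets target
the published per-cell group means; the per-beat SD is chosen as
BVR·√(π/2), the value for which an i.i.d. Gaussian APD90 series converges
to the target BVR.

**Respiratory flow** — half-sine inspiration/expiration lobes with the
expiration fraction of the period configurable; expired volume balances
inspired volume, so a scheduled apnoea is a long shallow expiratory lobe
and the record mean stays at zero (a net-flow offset would bias every zero
crossing). Scheduled apnoeas stretch one breath's expiration to
factor × the nominal expiration time; the truth table lists every breath
and event.

**Cohorts** — per-animal (ECG, respiration) and per-cell (AP) true
parameters are drawn from genotype-labelled normal distributions with
SD reconstructed as SEM·√n from the published group tables — an
approximation of the unreported dispersion — lightly truncated to satisfy
the generators' structural invariants (e.g. PR < QT < RR, APD90 ≥ 7·APD50,
amplitude ≥ 60 mV); the truncations bind far from the group means. QT and
RR are drawn independently, which over-disperses corrected QTc relative to
the published QTc SEMs (in real animals QT co-varies with RR; the
correction removes exactly that shared variance) — a known limitation
discussed below. Apnoea schedule distributions (similar counts in both
genotypes, longer pauses in the disease group) are package-chosen synthetic
values: the published count/length group values appear only graphically.
All randomness flows from one seed through spawned child streams, so every
cohort is reproducible bit-for-bit.

## Problem sizes used by the validation suite

The acceptance tests run 50 synthetic ECG animals (RR 120–180 ms, QT 45–65
ms, 0.01 mV noise), 100 synthetic APs (APD90 80–200 ms, 0.5 mV RMS noise),
10⁵-sample BVR Monte-Carlo convergence, two 70-minute plethysmography
traces with 7–10 scheduled apnoeas, 10,000 null simulations per statistical
test at n = 25 per group, and 100 replicate cohorts at the published group
sizes (12/15 ECG animals, 24/18 AP cells). Cohort respiration recordings
default to a 20-minute analysis window in `CohortSpec` (the rule is
window-length invariant; the full 20 + 60 min protocol remains the
analysis-side default).

## Known limitations

* The QT-end and T-detection rules are reproducible operational choices,
  not a uniquely published criterion; different fractions shift absolute QT
  by a few ms (the corrections' group *differences* are much less
  sensitive).
* The equal-split two-exponential template ties APD10–APD75 to the drawn
  APD50/APD90, so their cohort dispersions do not follow the published
  per-row SEMs; only APD50 and APD90 are targeted moments.
* Independent QT/RR draws inflate QTc dispersion relative to the published
  QTc SEMs. Together with the SEM·√n dispersion reconstruction this caps
  the replication probability of any single cohort's full significance
  pattern well below one — re-running the published design is itself a
  noisy experiment; the suite's cohort-pattern check quantifies exactly
  this.
* BVR magnitudes depend on the adopted normalization convention; compare
  BVR across analyses only under the same convention.
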