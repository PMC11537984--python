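# Methods

## Vessel diametry from line profiles

A fluorescence intensity profile across a vessel is modelled as a Gaussian
`b + A·exp(−(x−µ)²/(2σ²))`, fitted by nonlinear least squares
(Levenberg–Marquardt via trust-region reflective with bounds A ≥ 0,
σ > 0). Initialisation is deterministic and data-driven: b ← min intensity,
A ← range, µ ← argmax, σ ← half the half-maximum crossing width. The
diameter is the width of the fitted curve at a stated fraction of the
amplitude *above baseline*: FWHM (fraction ½) for mural labels that sit on
the vessel wall, FWQM (fraction ¼) for intravascular dye whose profile
shoulders extend further; measuring at fractions of amplitude above
baseline rather than of the absolute maximum keeps a baseline offset from
corrupting the width. For a Gaussian these widths are closed-form,
2σ√(2 ln(1/f)), so FWQM/FWHM = √2 identically and the diameter is invariant
to intensity offset and gain.

A fit with r² below the quality threshold (default 0.90; the threshold is
a free parameter since "fits poorly" has no canonical definition) routes to
a fallback that mimics manual measurement: smooth with a 3-sample moving
average, take a robust baseline (10th percentile), and measure the
outermost linear-interpolated crossings at the same fractional level. The
outermost (edge-to-edge) convention matters for the typical failure mode —
dye accumulated at both vessel walls produces a double-peaked profile whose
vessel spans both peaks. A profile with no supra-baseline region raises a
no-vessel error rather than returning a width.

Pericyte coverage profiles average label intensity in fifteen 1-µm bins of
distance from the soma centre; an empty bin is reported as missing (NaN),
never as zero.

## Calcium transients

Traces are normalised by the mean of a designated baseline window (F/F₀;
idempotent). A transient is a contiguous supra-threshold excursion whose
peak exceeds the baseline mean by more than `threshold_sd` (default 3)
times the baseline noise SD. Two estimation choices make the 3×SD rule
behave well on active cells:

- **Noise SD** defaults to a robust estimator — the median absolute
  deviation of first differences of the baseline segment, scaled by
  1.4826/√2 — because transients falling inside the baseline window
  inflate a plain standard deviation several-fold at high event rates
  while barely moving the difference-MAD. `noise_estimator="std"` restores
  the plain estimator.
- **Baseline mean** defaults to the window median; when the window is
  visibly activity-skewed (median exceeds the 10th percentile by more than
  twice the noise SD, which cannot happen for Gaussian noise alone) the
  mean is taken as the 10th percentile plus its Gaussian offset 1.28·SD —
  the percentile-baselining convention standard in ΔF/F pipelines.

Runs separated by less than `merge_gap_s` (default 1 s, two samples at the
2 Hz acquisition typical for these transients) are merged so noise does not
split single events. Merged runs are then split wherever the elevation
above baseline exceeds its predicted exponential decay by more than the
residual noise allows: the per-sample decay ratio ρ is estimated from the
trace itself (median ratio of consecutive elevations over samples more than
5 SD above baseline; ρ = 1, i.e. a plain jump criterion, when fewer than 10
such samples exist), and a cut is placed where
`elev[k] − ρ·elev[k−1] > threshold_sd·√(1+ρ²)·SD`. This separates
transients riding on each other's decay without requiring a decay time
constant. Resolution limit: a new transient is reliably separated from an
ongoing one when its rise exceeds roughly 8× the noise SD; at exactly 6×SD
with heavy overlap (≳4 events/30 s at τ = 2 s, 2 Hz) rate recovery
degrades, because a 6·SD rise must be discriminated against ~1.3·SD
residual noise. Two simultaneous events within one acquisition sample are
indistinguishable by construction.

Rates are reported per 30 s (`n·30/duration`); the mean amplitude of an
empty event list is NaN. Event detection is invariant to affine intensity
rescaling applied before normalisation. No detrending is applied by default
(stable preparations show no photobleaching decay at these settings).

Time-to-half-peak of slow drug-response timecourses: baseline = mean before
the intervention onset, plateau = mean of the final 20% of the record,
t_half = first crossing of the midpoint by the 5-sample moving-averaged
trace after onset, linearly interpolated and clamped at 0.

## Vascular-resistance model

The cerebral vascular bed is reduced to two series resistances: arterioles
with fraction `f_art` = 0.43 of healthy total resistance and capillaries
with `f_cap` = 0.57. Each obeys Poiseuille scaling (resistance ∝ 1/d⁴);
blood viscosity changes, pulsatility and network topology are outside the
model. Pericyte somata are spaced s = 144 µm apart along capillaries, and
diameter changes driven by pericytes are confined to a rectangular window
of length L_c centred on each soma — the minimal closed-form surrogate for
the measured spatial profile of constriction, which is largest at somata
and decays within a few tens of µm. Capillary resistance per pericyte unit
is L_c/d_soma⁴ + (s−L_c)/d_off⁴, normalised to the healthy uniform unit.

L_c defaults to 50 µm, the value at which the stated disease-and-drug
scenario (21% baseline constriction at somata; 16.9% capillary dilation in
the window and 17.8% arteriole dilation) yields a 51% flow increase; the
calibration is reproducible with `calibrate_window_length` (monotonicity
check plus bisection to 0.01 µm). Venules are omitted (the resistance split
names only arterioles and capillaries), the 43/57 split is taken as the
healthy baseline, drug dilation is applied only inside the soma window
(off-window dilation is exposed as `cap_off_factor`), and the model is
agnostic to whether input factors come from outer or lumen diameters —
callers supply whatever fractional changes they measured.

## Stall spatial statistics

With pericyte somata uniformly spaced s apart and blocks at random
positions, block-to-nearest-soma distance is uniform on [0, s/2]:
CDF = min(2d/s, 1), mean s/4. Distances beyond s/2 are geometrically
inconsistent with the stated spacing, so they are flagged and excluded with
a warning, never clipped. The one-sample Kolmogorov–Smirnov test computes
D as the sup-norm over sample points (both one-sided gaps) and the p-value
from the asymptotic Kolmogorov distribution evaluated at
`(√n + 0.12 + 0.11/√n)·D`, the standard small-sample correction. Distances
are assumed measured along the vessel axis, matching the null's geometry.
Stall durations at 2 Hz sampling are (last frame − first frame + 1)/2 s;
summaries report per-cell-class means, medians and pairwise fold ratios.

## Microglial surveillance

S(t) is the cardinality of the union of the binarised masks up to frame t
(S(0) = cell area at t 0; nondecreasing; bounded by the frame size). The
motility index divides S(t) by the per-frame cell area; because the
normalising area can also be read as the maximum-intensity-projection area,
both variants are emitted. Masks are inputs — binarisation belongs to the
upstream imaging pipeline — but an Otsu binariser is provided for
convenience.

## Perfusion and permeability

Patency = 100 × (patent segment length)/(total length) over any metadata
filter; the plaque-proximity filter defaults to 65 µm. Extravasation =
per-region extravascular intensity relative to the first acquired frame
(gain-invariant by construction), with optional depth strata at <40 µm and
40–126 µm below the cortical surface. Whether extravascular regions should
exclude a dilation buffer around vessels is left to the caller's region
definitions.

## Synthetic data: what it emulates and what it does not

Generators produce every input class with ground truth attached, seeded and
bit-reproducible. Defaults encode the measured study conditions: 3.7-fold
(somata) and 2.6-fold (processes) transient-rate elevation in disease; 21%
soma constriction (healthy soma diameter 6.9 µm); one pericyte per 144 µm;
5.2% vs 0.47% of capillary segments blocked; 87% of blocks within three
branch orders of the ascending venule; neutrophil stalls 5.4-fold longer
than monocyte stalls. Where no value is printed anywhere, defaults were
chosen once as realistic for this preparation and are configurable:
healthy somatic transient rate 0.5/30 s and process rate 1.0/30 s; trace
baseline F₀ = 100 a.u. with noise SD 5 a.u. (SNR 20 line profiles); decay
τ = 2 s; monocyte mean stall 5 s (neutrophil 27 s); transient amplitude
10× noise SD; sampling 2 Hz over 300 s with a 60 s baseline window.

Noise is Gaussian by default — photomultiplier noise at typical two-photon
intensities is near-Gaussian — with a Poisson option. Transient events are
Poisson-timed over the full record and snapped to the sampling grid, so the
first sample of each event carries the full rise; same-sample events merge.
The clustered-stall law is an exponential truncated to [0, s/2], the
simplest one-parameter soma-attraction model. Drug-response timecourses are
logistic with a flat pre-onset baseline; the logistic midpoint is the
ground-truth half-peak time. Microglial cells are random-walking,
radius-jittered disks.

Not emulated: optical point-spread functions, scattering, motion artifacts,
photobleaching, blood-cell rheology, vessel curvature, correlated noise,
or cell morphology beyond a disk. Passing recovery tests on these inputs
demonstrates correctness of the estimators under their stated noise model,
not robustness to every artifact of real recordings.

## Numerical choices and degenerate inputs

- Gaussian fits: flat or peakless profiles return an explicit failure
  (success = False, r² = 0), never NaN; r² is clipped to [0, 1].
- Transient detection on a constant trace returns no events (the threshold
  degenerates to "strictly above the baseline mean").
- Bisection tolerance for window calibration: 0.01 µm, with a 17-point
  monotonicity pre-check and an explicit achievable-range error.
- KS test requires ≥ 5 usable distances; all-out-of-range data error out.
- Percentage computations error on empty denominators and name the filter
  that emptied them.
- The pipeline driver derives all stage seeds from one root seed via a
  single generator, so identical configurations give byte-identical
  outputs; provenance records the config (minus the output path) and
  package versions.

## Problem sizes in the shipped tests

Statistical calibrations run at sizes chosen to keep sampling error well
inside the asserted bands: 1000 seeded profiles for σ recovery (median
error ≈ 1.5% at SNR 20), 200 traces per rate point for detector rate
recovery (slope 0.98), 400 pure-noise traces for the false-positive floor
(≈ 0.15 events/30 s), 2000/500 datasets of n = 119 for KS type-I error
(≈ 0.051) and power (1.00), 100 mask stacks against the exact pixel-union
oracle.

## Known limitations

- The rectangular constriction window is a surrogate; with measured spatial
  constriction profiles the capillary integral should use them directly.
- The resistance model ignores viscosity–diameter coupling, so it
  understates flow gains from dilation of narrow capillaries.
- The transient detector's overlap resolution degrades near the 6×SD
  amplitude floor (see above); amplitudes there are also biased low by
  peak-noise selection.
- The KS p-value is asymptotic (with small-n correction), adequate for
  n ≳ 30; exact small-n p-values are not implemented.
- Motility normalisation by per-frame area makes the index sensitive to
  frame-to-frame segmentation area jitter; the projection-area variant is
  stabler but less local.
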