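# Methods

This note records the analysis model implemented by `lickwave`, the
conventions chosen where the procedure admits more than one reasonable
reading, and what the synthetic-data generator does and does not emulate.

## Signal model and correction

A session is two simultaneously sampled fluorescence channels: the 465 nm
sensor channel and the 405 nm isosbestic control, which shares
photobleaching and motion artifacts with the sensor channel but is
insensitive to ligand. The correction assumes the relation

    F465(t) ≈ a · F405(t) + b + signal(t)

over the whole session, estimates `(a, b)` by ordinary least squares, and
forms ΔF/F = (F465 − F̂)/F̂ with F̂ = a·F405 + b. Fitting over the whole
session (not per-event) reflects the assumption that bleach and motion
are session-scale phenomena. An optional `fit_mask` restricts the fit to
baseline samples: event-locked sensor transients are variance the control
does not share, and excluding peri-event windows removes the small bias
they put on the control gain. On noise-free simulated sessions the masked
fit makes the correction an exact inverse of the forward model (the test
suite checks max error < 1e-6 ΔF/F); the unmasked default matches common
practice and is adequate whenever events occupy a minority of the
session.

The corrected trace is low-pass filtered with a zero-phase
(forward–backward) 2nd-order Butterworth filter, default cutoff 1.67 Hz.
The cutoff is tied to the significance criterion: 1.67 Hz corresponds to
a 0.6 s period, the span of the 6-bin consecutive threshold below.
Division is guarded — if the fitted control is ≤ 0 anywhere the
correction aborts, naming the first offending sample — and a constant
control channel is rejected as degenerate.

The corrected trace is averaged into 0.1 s bins (bin *k* = mean of
samples in `[k·0.1, (k+1)·0.1)`, trailing partial bin dropped). Every
downstream statistic lives on this grid, so any sampling rate ≥ 20 Hz is
supported.

The separate in vitro ΔF/F₀ helper uses F₀ = mean of the 10 samples
immediately before ligand addition; it exists because sensor
characterisation uses a different baseline convention than the in vivo
pipeline.

## Lick bouts and behavior

A bout is a maximal cluster of licks whose consecutive gaps are all
< 10 s, kept if it has ≥ 3 licks. The inter-bout gap is measured from the
last lick of one cluster to the first lick of the next (an end-to-start
convention; the alternative start-to-start reading would merge long bouts
with their successors). Clusters of 1–2 licks are not bouts but still
count toward session lick totals. Bout length is last lick minus first
lick; no terminal inter-lick interval is appended. Within-bout lick rate
is reported as the reciprocal of the median within-bout inter-lick
interval pooled over the session — a convention, made explicit because a
"lick frequency" statistic admits several definitions.

The condition comparison uses a classical one-way within-subjects ANOVA
(F = MS_condition / MS_condition×subject, df = (k−1, (k−1)(n−1))) on the
complete, balanced mouse × condition table; missing cells are an error
rather than an imputation. The implementation is checked against a
hand-computed sums-of-squares decomposition and against
`statsmodels.AnovaRM`.

## Peri-event snips

Each bout maps onto a fixed 230-bin layout: 50 baseline bins (5 s before
the first lick), 60 bins for the first 6 s of licking, 20 bins for the
last 2 s of licking, and 100 post bins (10 s after the last lick).
Restricting the lick period to its first and last segments puts bouts of
unequal duration on one comparable grid. Bouts shorter than the analysis
threshold (8 s when comparing regions, 4 s when comparing conditions,
where short bouts are common) are excluded as `excluded_short`; windows
that would extend beyond the recording are `excluded_edge` (an
implementation-level status: recordings begin and end somewhere).

For bouts between the threshold and 8 s the first-6-s zone has fewer than
60 source bins. Default behavior linearly time-warps the available bins
onto the 60-bin grid (the last-2-s zone is always literal); such snips
carry a `warped` flag. An alternative `overlap` mode resamples
nearest-neighbor bins with duplication instead. Warping preserves the
within-lick shape at the cost of a stretched time axis; either way the
fixed layout is what makes bin-wise averaging across bouts well defined.

Snips are z-scored against their own 5 s baseline (sample SD, ddof = 1);
a constant baseline is degenerate (`excluded_zero_sd`). The artifact test
then discards a bout if any |z[i+1] − z[i]| strictly exceeds 12. The
threshold is applied in baseline-SD units of the binned, normalized snip:
a jump of 12 baseline SDs between adjacent 0.1 s bins is far outside the
passband of the 1.67 Hz filter and can only be a residual artifact,
whereas raw-ΔF/F units would make the threshold depend on sensor
brightness. A jump of exactly 12 passes (strictly-greater rule, kept
explicit in a boundary test). Statuses partition the bout list, so
`included + Σ excluded_by_reason = n_bouts` always holds.

## Bootstrap waveform statistics

The pooled included snips of a group (all bouts of a region × condition,
across mice and sessions) are resampled with replacement 1000 times; each
resample's bin-wise mean yields, per bin, the 2.5th and 97.5th
percentiles as a 95% CI around the plain mean. Percentile intervals were
chosen over a normal approximation because they need no distributional
assumption and behave sensibly at small pools; the choice is recorded in
the result object and configurable. One index matrix is drawn per call
and reused across bins, so the CI is coherent in time; snips are put in a
canonical (lexicographic) order before resampling, making the result a
function of the snip multiset rather than its ordering. All randomness
flows through a single seeded generator; identical seeds give
bit-identical results.

A *true fluctuation* is a maximal run of ≥ 6 consecutive bins whose CI
excludes zero (strict inequalities: a CI touching zero counts as
including it). Six bins = 0.6 s = one period of the low-pass filter, so a
run must outlast the filter's correlation time. Two groups differ where
their CIs are disjoint for ≥ 6 consecutive bins; the criterion is
symmetric in the two groups.

Run boundaries are converted to seconds against the anchor their bins
carry: bins up to the end of the first-6-s zone are timed from bout
start, later bins from bout end (bins in the last-2-s zone have no
well-defined time from bout start, since bout durations differ). The
derived readouts are: suppression onset (start of the first below-zero
run beginning at or after bout start), suppression offset (end of the
last below-zero run extending past bout end) and rebound onset (start of
the first above-zero run after bout end); absent phenomena are reported
as missing, not zero. Epoch AUCs are trapezoidal integrals of the
z-scored snip over the first-6-s zone, the last-2-s zone, and the two 5 s
halves of the post window (so a constant z = 1 over a 50-bin epoch gives
4.9 z·s, the trapezoid of 50 points at 0.1 s spacing).

### Calibration properties

On flat Gaussian snips the per-bin percentile CI covers the true mean at
close to the nominal 95% (the suite asserts 95 ± 3 percentage points at
n = 50 snips and 2000 resamples; percentile intervals run slightly
conservative-narrow at these pool sizes). The *family-wise* false-positive
rate of the run criterion on null cohorts is a different quantity: the
low-pass filter correlates neighboring bins at exactly the 6-bin scale,
so chance runs are far more likely than an independent-bins calculation
suggests. The suite therefore asserts only the monotone property — raising
the consecutive threshold can only remove chance runs — and the
acceptance script reports the measured null-cohort rate alongside the
other outputs rather than asserting a level for it. Users comparing many
groups should treat the 6-bin criterion as descriptive, not as a
multiplicity-corrected test.

## Synthetic data generator

The generator is the package's ground-truth instrument, not a fixture.
It emulates:

* **Lick trains** — lognormal bout durations (default mean 10 s, SD 3 s),
  gamma inter-lick intervals around a 7 Hz within-bout rate (shape 8,
  CV ≈ 0.35; 7 Hz is the conventional rodent lick rate — the rate is a
  parameter, not a claim), and inter-bout gaps of at least 10 s plus a
  random Dirichlet split of the session's slack. Defaults place 30 bouts
  in a 30 min session. Because gaps are ≥ 10 s and bouts have ≥ 3 licks,
  segmentation recovers the generated bouts exactly (tested as a
  round-trip).
* **Photometry** — `F465 = B(t)·(1 + k(t)) + M(t) + ε` and
  `F405 = g·B(t) + M(t) + ε'`, with `B` a shared double-exponential
  bleach over a constant plateau (default amplitudes 0.5/0.2 of plateau,
  taus 900/120 s), `M` sparse biexponential motion transients added
  identically to both channels (so control correction can remove them),
  and white channel noise. `k(t)` is the event-locked kernel in ΔF/F
  (1% ΔF/F per kernel unit); the 405 channel carries no kernel.
* **Response kernels** — exponential relaxation to a suppression depth
  after an onset delay; after the bout either a fast recovery plus an
  alpha-shaped rebound (`rebound` mode) or a very slow recovery with no
  rebound (`sustained` mode). The two presets mirror the qualitative
  region difference the pipeline is meant to resolve: the PVH preset
  suppresses from 1.5 s after lick onset and rebounds a few seconds after
  the bout; the VMH preset suppresses from 0.2 s and stays below baseline
  beyond the 10 s post window. Responses are truncated 25 s after bout
  end and overlapping responses add.
* **Noise calibration** — the default channel noise (SD 0.035 in raw
  units) was set, once, so that one kernel unit is approximately one
  baseline SD of the corrected, filtered, binned trace; kernel depths are
  therefore nominal z units. The realized per-snip z depends on the
  baseline-SD estimate from 50 correlated bins and typically runs
  somewhat larger than nominal.

It does **not** emulate: hemodynamic or pH confounds, sensor kinetics
(the kernel is the *net* response, not a binding model), wavelength-
dependent motion (motion is perfectly shared, the favourable case for
isosbestic correction), non-Gaussian noise, lick-rate modulation within a
bout, or session-to-session sensor expression differences beyond the
seed. Passing tests therefore show the *analysis* is correct and well
calibrated under a realistic forward model — not that the correction
would remove pathological artifacts real recordings can contain.

## Problem sizes and numerics

Simulated validation cohorts run at 50 Hz sampling (any fs ≥ 20 Hz is
supported; 100 Hz is the generator default) with 200-bout sessions for
the recovery and discrimination checks, 50 cohorts for onset recovery and
20 replicates for the rebound-vs-sustained discrimination — sizes chosen
so the whole suite runs on a laptop in a couple of minutes while leaving
the assertions comfortable margins. Bin-index arithmetic uses
floor/ceiling with a 1e-9 guard against float round-off; time-warped
snips use linear interpolation; CSV output writes shortest-round-trip
floats and is re-read with round-trip parsing, so both on-disk dialects
(HDF5 and CSV directory) are bit-lossless. Duplicate or out-of-order lick
timestamps are sorted/deduplicated at read time with a logged warning,
never silently.

## Known limitations

* The cited correction family is under-specified in the literature; the
  implemented estimator (whole-session OLS of the control, ratio form,
  zero-phase low-pass) is one member, tagged in the output
  (`method_tag`), and the interface deliberately admits alternatives
  (e.g. spectral-domain subtraction) without touching downstream stages.
* Onset/offset readouts inherit the bootstrap's granularity (0.1 s bins)
  and the zero-phase filter's symmetric smearing (~±0.1–0.2 s at high
  SNR).
* The AUC epochs are exported descriptively; no inferential statistics
  are attached to them.
* Proprietary acquisition formats are not parsed; sessions enter via the
  HDF5/CSV container.
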