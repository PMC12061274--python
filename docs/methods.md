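# Methods

This note documents the models, defaults and design decisions behind
`socialfp`, and what the synthetic data do and do not establish.

## Behavioral model and metrics

A session presents two stimuli for 300 s; an automated tracker reports,
per stimulus, half-open contact intervals `[start, end)` in seconds on a
0-based session clock, quantized to the video frame grid (15 fps).

**Bout merging.** Contacts of the same stimulus separated by a gap
strictly shorter than 0.5 s are fused into one bout. The comparison is
strict: a gap of exactly 0.5 s does not merge. A bout's *duration* is its
merged span (gaps included); the summed raw contact is kept separately as
*contact time*. Duration is what the length categories use.

**Categories.** short `[0, 6)` s, mid `[6, 19]` s, long `(19, ∞)` s. The
mid bin is closed on both sides; 6 s and 19 s are assigned to it by
elimination, since the outer categories are defined by strict
inequalities. Long bouts are the category most associated with genuine
social engagement.

**Binning and preference.** Investigation time is accumulated in 60 s
bins; a bout spanning a bin edge contributes its overlap to each bin
(time is additive), while bout *counts* attribute each bout to its onset
minute once (counts are not). The preference score is the per-minute
difference in investigation time between the two stimuli, so it lies in
[−60, +60] s.

**Transitions.** Merged bouts of both stimuli are interleaved
chronologically; every bout whose stimulus differs from the previous
bout's marks a transition at its onset. Using merged bouts (not raw
contacts) keeps sub-gap micro-contacts from inflating the count. Rates
are raw counts per 60 s bin; the bin width is reported alongside so a
caller can normalize. Switch intervals are `next.start − prev.end` for
consecutive bout pairs with differing stimuli; their histogram is
reported as counts and percentages (undefined, and flagged, when the
animal never switched).

## Photometry model and processing

**Detrending.** The isosbestic 405 nm channel is calcium-independent but
shares bleaching and motion with the 465 nm signal. A single affine OLS
fit over the whole session, `c = a·F405 + b`, estimates the nuisance
component; `dF/F = (F465 − c)/c`. Windowed or robust fits are out of
scope. A fitted control that touches zero anywhere, or a constant 405
regressor, is an error rather than a silent division hazard.

**Event alignment.** Behavioral event times map onto the photometry
clock by `t' = scale·t + offset`; events landing outside the recorded
trace are dropped and counted. The generator can inject a configurable
offset so this step is exercised end to end.

**Peri-event matrix.** For each onset, dF/F samples are averaged into
0.1 s bins over `[−2, +5)` s (70 bins, left-closed, bin-center
abscissae). Resampling is by within-bin averaging, which is anti-aliased
by construction, not decimation. Events whose window exceeds the trace
are excluded and logged.

**z-scoring.** Each row is normalized against its own 2 s pre-onset
baseline: `z = (x − mean)/sd`, sd with the n−1 denominator, computed per
bout rather than on a concatenated session baseline — the reading
consistent with a per-event pre-period. Rows with baseline sd below 1e-9
carry no noise estimate and are excluded from averages rather than
clipped. The 2 s baseline matches the typical time an animal needs to
move between compartments.

**Overlap handling.** Two flags qualify events: (a) another
*same-stimulus* onset inside the baseline (flagged, kept by default —
repeated responses of the same type average meaningfully); (b) any
*other-stimulus* onset inside the full −2…+5 s span (excluded from
averages by default). The second rule matters: in dense sessions a
food-aligned window frequently contains the onset of the next social
bout, and since transient amplitude differs by stimulus and genotype,
keeping such events leaks the social response into the food summary and
can manufacture spurious genotype differences where none exist. Both
rules are configuration switches.

**AUC.** The per-animal summary is the trapezoidal integral of the
event-averaged z-trace over `[0, +5]` s (configurable), using bin centers
as abscissae with constant extension to the interval endpoints, so a
constant trace of height h integrates to exactly 5h.

**QC.** Baseline stability is the absolute Theil–Sen slope of dF/F over
the pre-stimulus period (≥ 60 s required), threshold 0.01 dF/F per
minute; the slope is computed on a decimated grid (≤ ~600 points) since
the estimator is quadratic in sample count. SNR is the 95th percentile of
|dF/F − median| divided by the median absolute deviation, threshold 3: a
trace with genuine transients has a heavy positive tail relative to its
noise floor, while pure noise sits near 2.9 and fails — mirroring the
practice of excluding animals with no detectable response.

## Statistics

Parametric ANOVA is deliberately replaced by distribution-free
permutation machinery, so the package's claims are about its own pipeline
rather than any particular software's F-tests. The group statistic is
|Δmean| for two groups and the variance of group means for three or more;
the null is label permutation. Paired ON/OFF designs use sign-flips of
the within-animal differences, two-sided on |mean|. p-values use add-one
smoothing, `p = (1 + #exceedances)/(n_perm + 1)`, with `n_perm = 10,000`
by default and the seed always recorded. Tie handling differs by test:
the group test counts strict exceedances (the permutation that re-creates
the observed split does not count against it), the sign-flip test counts
ties (the identity flip always reproduces the observed statistic, giving
the exact-enumeration floor of ~2/2ⁿ for n pairs). Both conventions keep
the type-I error at the nominal level for continuous data, which the test
suite verifies by simulation. Dispersion is reported as SEM (sd/√n),
undefined for single-animal groups.

## Synthetic-data generator

The generator exists so that every pipeline stage has a ground truth to
be tested against. It emulates the *statistical structure* the analysis
assumes, not the physics of the rig.

**Bout process.** An alternating-renewal process per session: candidate
onsets are drawn per minute from a Poisson process at the profile rate
divided by the expected free-time fraction, candidates arriving while the
animal is occupied are discarded, so the realized bout rate approximates
the nominal rate while the two stimuli never overlap. Durations are
log-normal (shape σ = 0.5) with the profile's mean; a 0.6 s refractory
period separates bouts so that generated bouts survive analysis-side
merging one-to-one. A schedule whose expected occupancy exceeds 60 s per
minute is rejected as infeasible. Output is quantized to the 15 fps frame
grid. The log-normal is a modeling choice (bout durations are
heavy-tailed — a >19 s category exists), not an empirical fit.

**Genotype profiles (defaults).** WT: social bout rate 6/min in minute 1
collapsing to the empty-compartment level (1.5/min, 8 s bouts) from
minute 2 — within-session habituation, with minutes 2–5 symmetric between
the stimuli so the expected late-session preference is zero. KO: sustained
5/min, 9 s social bouts for all five minutes and little empty
investigation. HET: intermediate, with partial habituation. Transient
amplitudes (peak dF/F): social 2.0 / 0.5 / 0.0 for WT / HET / KO; food
1.0 for every genotype; between-animal amplitude sd 0.3, truncated at
zero. These encode the qualitative pattern the pipeline must recover —
graded social hypoactivity with genotype, intact food responses — and are
all overridable.

**Photometry.** `F465 = B·e^(−t/τ)·(1 + Σ amp·K(t − onset)) + m(t) + ε`,
`F405 = 0.8·(B·e^(−t/τ) + m(t)) + ε'`, with baseline B = 100 a.u.,
bleaching τ = 1800 s, white noise sd 1 a.u. per channel, and m(t) a
shared Gaussian process low-passed at 1 Hz with sd 2 a.u. — exactly the
nuisance structure the isosbestic regression removes. The transient
kernel K is a difference of exponentials (rise 0.2 s, decay 1.0 s),
peak-normalized so that `amp` is the peak fractional change; transients
enter multiplicatively on the bleached baseline, making dF/F recover
`amp` directly. Sampling is 100 Hz (ample for 0.1 s bins); 60 s of
stimulus-free recording precede t = 0 for the QC stage. Each session's
draws derive from a single seed via `SeedSequence` spawning, so cohorts
are pure functions of (profiles, config, seed).

**What the synthetic data are not.** No pose or pixel simulation; no
hemodynamic or photobleaching nonlinearity beyond the single exponential;
motion is stationary Gaussian, not impulsive; transient amplitude is
constant within an animal-session rather than bout-to-bout variable;
optogenetic sessions are represented as behavior-profile switches, not
simulated physiology. Passing recovery tests therefore shows the pipeline
is correct and unbiased *under these assumptions*; it cannot certify
performance on artifacts the generator does not model (e.g. fiber
decoupling, non-shared motion, state-dependent baselines).

## Problem sizes in the verification suite

The test suite checks oracle equivalence on 1,000 random frame-quantized
sessions, z-score self-normalization on 10,000 random events, artifact
rejection on 100 zero-amplitude sessions, amplitude-ordering and
food-null recovery on 100 cohorts of 10 animals per genotype, behavioral
phenotype recovery on 100 cohorts of 20 animals per group, and test
validity on 1,000 null simulations per test. `scripts/acceptance.py`
recomputes the same quantities at 30 cohorts / 500 null simulations and
one full-size pipeline cohort (WT 10, HET 12, KO 9) — sizes chosen to
give stable Monte-Carlo estimates while keeping a full rerun in the
minutes range on one core.

## Known limitations

* The realized bout rate tracks the nominal rate through a mean-field
  free-time correction; near saturation (total occupancy approaching
  60 s/min) the thinning approximation degrades and realized rates fall
  short of nominal.
* Per-bout amplitudes within an animal are identical; real transients
  vary bout-to-bout and adapt.
* The affine detrend assumes channel gains are constant over the session;
  slow gain drift that differs between channels would leak into dF/F.
* Permutation p-values are Monte-Carlo estimates with resolution
  `1/(n_perm + 1)`; exact enumeration is not implemented.
* QC thresholds (0.01 dF/F·min⁻¹ drift, SNR 3) are heuristics calibrated
  to the generator's noise model, not to any particular rig.
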