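# Methods

`nemoresponse` quantifies stimulus-evoked neural activity and motor output in
*C. elegans* CO₂-response experiments: ratiometric calcium imaging of
identified neurons (BAG and its postsynaptic interneurons), centroid tracking
of freely moving animals during gas pulses, and population chemotaxis assays.
This note records the models, the parameters that matter, and the design
choices made where the experimental literature leaves the procedure open.

## Stimulus protocols

A recording is a contiguous sequence of gas segments — air pre-pulse,
stimulus pulse, post-stimulus air — sampled at a fixed frame rate.  The
standard behavioral protocol is a 20-s air pulse followed by a 60-s CO₂ pulse
(2.5% CO₂, 21% O₂, balance N₂) and a 40-s recovery period; imaging uses the
same timing with 15% CO₂.  An air control replaces the CO₂ pulse with air at
identical clock times, so every stimulus-anchored window has a matched
control window.  Acquisition rates default to 5 fps (behavior) and 2 fps
(imaging); both are configurable, as the true acquisition parameters of any
given rig vary.  All analysis windows are half-open `[start_s, end_s)`
against frame timestamps.

## Ratiometric calcium analysis

For a FRET indicator (donor CFP, acceptor YFP; e.g. yellow cameleon YC3.60)
the ratio `R(t) = acceptor/donor` cancels any gain or bleaching factor common
to both channels.  Responses are expressed as

    %ΔR/R₀(t) = 100 · (R(t) − R₀) / R₀

with `R₀` the mean ratio over the baseline window (default: the pre-pulse air
period minus its first 2 s, left configurable because preparations need a
settling time of rig-dependent length).  The response window defaults to
pulse onset through 30 s past offset, wide enough to capture responses that
begin only after the pulse ends (post-pulse inhibition, as seen in dauer
RIG).  No bleach-correction fit is applied to `R₀` by default; shared
bleaching cancels in the ratio and differential bleaching is left to the
user's preprocessing.

Per-animal responses are summarised by the maximum and minimum of %ΔR/R₀
over the response window.  Classification into excitatory / inhibitory /
silent uses an empirical null: the sample SD (n−1) of a per-animal statistic
computed on air-control animals.  A response is non-silent when its magnitude
exceeds `k` (default 3) times that SD; the dominant sign decides the class,
with exact magnitude ties classified excitatory (a deterministic, documented
rule; probability zero under continuous noise).  The air-control statistic
is the *signed window extremum* of %ΔR/R₀ by default — this matches testing
"the absolute value of the response" against the null — with `max` and `min`
variants available in configuration since the field's conventions differ
between labs.  A zero-SD null (identical controls) triggers a
`DegenerateNullWarning` and makes every nonzero response non-silent.

Cohort summaries are framewise mean ± SEM traces (SD/√n, n−1 convention) and
per-animal heatmaps ordered by agglomerative clustering of the %ΔR/R₀
vectors (Euclidean distance, average linkage, optimal leaf ordering; all
configurable).  Hierarchical-clustering row order is deterministic for fixed
input.

## Locomotion analysis

Centroid tracks `(t, x, y)` are reduced to per-interval speed and heading;
the speed sample of the displacement from frame *i* to *i+1* is timestamped
at the later frame.  Instantaneous speed is optionally smoothed with a 1-s
centered moving average (truncated at the edges).

State segmentation uses three states.  Intervals whose raw speed falls below
`pause_speed_mm_s` (default 0.02 mm/s) are pauses.  Moving intervals start
as forward; when the instantaneous heading departs from a smoothed reference
heading by more than `reversal_angle_deg` (default 120°), the direction
state toggles forward↔reverse and the reference resets to the new heading.
Within a bout the reference follows heading drift with an exponential moving
average (time constant 1 s), so gradual path curvature does not trigger
reversals.  Bouts shorter than `min_bout_s` (default 0.6 s) merge into the
longer neighbor to suppress jitter flicker.  These are centroid-level
heuristics — a tracker with body-posture information can resolve head/tail
directly — and every threshold is exposed in configuration.  The initial
moving state is assumed forward.

Windowed metrics follow the standard stimulus-locked comparisons: mean speed
during the first 20 s of the pulse and during a 20-s window starting 30 s
after onset; forward/reverse/pause time ratios over the pulse window (the
pause fraction is computed as the complement of the other two, so the three
ratios sum to exactly 1 in floating point); straight-line distance between
the first and last positions in a window; and distance traveled in reverse
(summed displacement over reverse-labeled intervals).  All metrics are
invariant to rigid rotation and translation of plate coordinates.

## Chemotaxis and statistics

The chemotaxis index is `(n_test − n_control)/(n_test + n_control)`, the
standard two-region assay index; worms scored at the origin are excluded
from the denominator by default with a switch to include them.  The
comparison harness wraps established routines — Welch's t, Mann–Whitney
(exact for small tie-free samples), Kruskal–Wallis, one-way ANOVA with
Dunnett's posttest, two-way factorial ANOVA with Šidák-adjusted
pooled-variance cell contrasts, and Fisher's exact test — behind a typed
plan interface; tests are chosen explicitly per metric in configuration
rather than by automatic normality switching.  Dunn's rank posttest after
Kruskal–Wallis is implemented directly (standard tie-corrected z statistics,
Bonferroni-family adjustment) because no installed library provides it.
All p-values are two-sided; adjusted p-values are never smaller than raw.

## Synthetic data generator

The generator exists so that every stage of the analysis can be exercised
against known ground truth, at the scale of the experiments it emulates
(cohorts of ~13–20 animals per condition, 16–18 assay plates).

**Calcium.**  The noise-free ratio is `R₀ · (1 + s·a·k(t))` with sign `s`
(+1 excitatory, −1 inhibitory), amplitude `a` (% / 100), and a kernel `k`
that rises linearly over 3 s and decays exponentially with τ = 10 s from
the response start (pulse onset + latency, or pulse offset + latency for
post-offset responses).  The paper-adjacent trace shapes motivate the bump
form, but any smooth bump would do for testing the analysis; rise and decay
are configurable.  Both channels carry independent multiplicative Gaussian
noise (default SD 1% of signal) and a shared exponential bleach (default
off) that cancels in the ratio.  Cohorts draw classes i.i.d. from a
specified mix and amplitudes from a configurable distribution (default
uniform 10–30%).

**Locomotion.**  States follow a forward/reverse/pause Markov jump process
with separate per-second rate matrices for the baseline and stimulus epochs.
Jumps are realized at frame boundaries with per-frame exit probability
`min(1, λ·dt)`: this Euler discretization keeps the mean dwell time exactly
`1/λ` and the stationary occupancy exactly that of the continuous-time rate
matrix, while making per-frame ground-truth labels exact (rates faster than
the frame rate saturate at one jump per frame).  The stimulus epoch spans
the CO₂ segment, optionally truncated after `stimulus_adaptation_s` to
emulate rapid behavioral adaptation (the adult-like preset slows for only
the first 20 s of the pulse) and optionally extended by a carry-over after
offset (default 0 s).  Position integrates per-state speed along a heading
that diffuses (default 0.3 rad²/s) on moving frames; reversal frames
translate along heading + π.  Two presets encode the qualitative life-stage
contrast: `dauer_like` (strong pause-entry rates for the whole pulse,
baseline speed 0.10 mm/s) and `adult_like` (transient reversal/pause
elevation for 20 s, baseline speed 0.15 mm/s).  Trajectories carry
`n_frames + 1` position samples so an N-second track covers N seconds of
motion.

**Chemotaxis.**  Each worm lands on the stimulus side with probability
`p_test`, giving binomial plate counts.

**Randomness.**  Every simulator takes one root seed; cohort members get
independent child streams spawned deterministically from (root seed, animal
index) via `numpy.random.SeedSequence`, so identical seeds give bit-identical
outputs and cohort size changes do not reshuffle earlier animals.

What the generator does *not* emulate: body posture (no skeletons or
eigenworms), omega turns, gas-diffusion dynamics, receptor kinetics,
multi-worm interactions, tracking artifacts such as dropped frames or
collisions, and slow non-stationary drift in fluorescence other than
exponential bleaching.  Passing recovery tests therefore demonstrates that
the analysis correctly inverts this generative model at realistic noise
levels — not that it is robust to every artifact of real rigs.

## Numerical choices and edge cases

* Sample SD and SEM use the n−1 convention throughout.
* Windows are validated against the recording and the pulse; empty windows
  and windows overlapping the pulse (for baselines) raise
  `InvalidArgumentError`; non-positive fluorescence raises `DataError`.
* The three time ratios partition exactly: pause = 1 − (forward + reverse)
  after rounding, so the left-to-right sum is exactly 1.0.
* Classification thresholds nest in `k`, so the non-silent fraction is
  monotone non-increasing in `k` by construction.
* Heatmap ordering of two traces returns the identity permutation.

## Calibration test designs

The suite verifies that every statistical path holds its nominal 5% type-I
error within 3 binomial SEs over 10⁴ null replicates.  Null designs use
moderate-to-large samples where the tests' exact/asymptotic distributions are
effectively continuous: n = 15/group (Welch, Kruskal–Wallis), n = 30/group
(Mann–Whitney), n = 10/group (ANOVA paths), and 2×2 tables with row totals
of 50,000 at p = 0.5 for Fisher's exact test — the conditional exact test is
conservative at small counts because its p-value lattice is coarse, and the
deficit shrinks like the reciprocal root of the table total.

## Problem sizes

Default test and demo problem sizes mirror the emulated experiments
(n = 16 animals/group imaging, 18/group behavior, 17 plates) with larger
cohorts where a check is statistical: 200 animals for classification
recovery, 50 animals per point for the pause-rate sweep, 10⁴ empirical vs
10⁵ oracle draws for null-rate calibration, and 100 seeded replicates at
n = 20/group for the life-stage speed pattern.

## Known limitations

* Direction inference from centroids alone cannot distinguish a true
  reversal from a sharp omega turn; the 120° heading criterion conflates
  them by design.
* The empirical null assumes air-control animals share the noise structure
  of stimulus recordings; systematic differences (e.g. valve artifacts)
  would bias the 3-SD threshold.
* The two-way ANOVA treats early/late window speeds of the same animal as
  independent observations, as in the standard figure-style analysis it
  reproduces; a mixed model would be more efficient but is out of scope.
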