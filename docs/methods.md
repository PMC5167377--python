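# Methods

`erpstates` implements the analysis chain used to study dual-task
interference on word production with ERPs: preprocessing and epoching for
stimulus- and response-aligned data, mass-univariate waveform statistics
with a spatio-temporal extent criterion, and topographic microstate
analysis with cross-validated model-order selection and randomization
inference on map timing. This note documents the models, the numerical
choices, and what the synthetic data do and do not emulate.

## Data model and conventions

Amplitudes are microvolts, times milliseconds, everywhere outside the file
readers. Stimulus-aligned epochs span −100..+500 ms around picture onset;
response-aligned epochs span a fixed 500 ms window ending 100 ms before
each trial's vocal onset (relative axis −600..−100 ms). Only correct,
non-filler trials enter averages, and a trial must survive artifact
rejection in *both* alignments to be used in either. Subject averages
require a minimum trial count (default 31); grand averages are unweighted
means over subjects and carry the mean production latency of their
contributors.

## Preprocessing

* **Filter**: 0.2–30 Hz Butterworth of order 2, applied forward–backward
  (`scipy.signal.sosfiltfilt`), hence zero-phase. A single pass of a
  2nd-order Butterworth rolls off at −12 dB/octave; the two-pass
  application squares the magnitude response, so the effective roll-off is
  −24 dB/octave. We implement the named filter (2nd order, zero phase) and
  note the doubling here rather than halving the order.
* **Average reference**: per-sample channel mean subtracted; residual
  channel means are at numerical precision (≪ 1 nV).
* **Artifact rejection**: an epoch is rejected when any sample on any
  channel *strictly exceeds* ±100 μV; a sample at exactly the threshold is
  kept (literal reading of an exceedance criterion). Manual inspection
  cannot be reproduced algorithmically; an exclusion list in the trial log
  (the mask) plays that role.
* **Overlap trimming**: a response-aligned sample at relative time τ sits
  at mean-RT + τ post picture onset. Samples whose whole period lies
  before the stimulus-aligned window end (500 ms) duplicate signal already
  analyzed there and are removed from the response-aligned grand average;
  the first kept sample straddles the cutoff. Trimming uses the
  condition's grand-mean latency; per-subject trimming exists behind a
  flag but the grand-average rule is the default because the overlap is a
  property of the condition's mean timing.

## Mass-univariate waveform statistics

A one-way repeated-measures ANOVA (factor task: ST/pDT/aDT) is computed at
every electrode × sample on subject averages, vectorized over the whole
grid; with k levels and n subjects the F statistic has (k−1, (k−1)(n−1))
degrees of freedom. No sphericity correction is applied by default;
Greenhouse–Geisser is available (`correction="gg"`) and its epsilon matches
`pingouin.rm_anova` to machine precision (cross-checked in the tests).
Planned pairwise contrasts are two-sided paired t tests; on two conditions
F = t² holds exactly. Degenerate grid points (no variance) report F = 0,
p = 1.

Multiple comparisons are handled by an extent criterion rather than a
p-value correction: suprathreshold points (p ≤ α, default 0.01) are joined
into connected components, where two points connect if they share a sample
and their electrodes are montage-adjacent, or share an electrode at
consecutive samples. A component is retained when its **maximum
simultaneous electrode extent** is ≥ 5 and its **time span** is ≥ 20 ms.
The two criteria combine per connected component because that is how
cluster-extent criteria are defined in the ERP literature this practice
descends from; no cluster-mass permutation correction is added, since the
criterion is purely extent-based.

Adjacency is never given by the recording itself, so the montage builds it:
the default is the Delaunay triangulation of the electrodes on an
azimuthal-equidistant projection of the fitted scalp sphere, with the
projection pole taken from the electrode cloud (making the graph invariant
to global rotation and scaling); a fixed-radius rule is available.

The recordings are sampled at 512 Hz, so the statistical grid step is
1.953 ms; the effective step is recorded in outputs rather than resampling
to a nominal 2 ms.

## Microstate analysis

A topography is the vector of potentials across electrodes at one sample;
its global field power (GFP) is the spatial standard deviation. Template
maps are zero-mean (average reference) with unit GFP. Spatial correlation
is the Pearson correlation of two topographies across electrodes;
polarity-sensitive comparison is the default (event-related mode: a map
and its inversion are different states), with a polarity-ignoring mode
(|r|) behind a flag.

**Segmentation (modified k-means).** All condition grand averages of an
alignment are segmented jointly into k shared templates. Each restart
seeds the templates from k random samples and alternates (i) labeling each
sample with its best-correlating template and (ii) re-estimating each
template from its members — the GFP-weighted mean direction in
polarity-sensitive mode, the principal spatial component in
polarity-ignoring mode (where the alternation is exact coordinate ascent
on GEV). The best of n_init restarts (default 50) is kept; runs are
deterministic given a seed. Quality is scored by global explained
variance,

    GEV = Σ_t (GFP_t · r_{t,label(t)})² / Σ_t GFP_t² ∈ [0, 1].

Restart seeding draws from the data's own samples; on tiny adversarial
instances (~0.4% of random 4-electrode × 6-sample Gaussian draws) no such
seed lies in the globally optimal basin and the best restart can sit just
below the enumerated optimum — irrelevant at real problem sizes but
visible to an exhaustive oracle.

**Label smoothing.** Temporally isolated, weakly fitting labels are
removed by penalized relabeling: each sample's score for template j is its
spatial correlation plus `penalty` × (number of same-labeled samples
within ±window/2), with synchronous updates, ties kept by the incumbent,
and a 100-iteration cap (defaults window 10 samples, penalty 3). This is
deliberately a *local* scheme, as in the smoothing literature it follows:
its fixed points are single-flip optima of the implied Potts-style
objective and preserve segment boundaries, whereas the *global* optimum of
that objective at these parameter scales is degenerate (a uniform labeling
— merging two runs gains a fixed 2·penalty·O(window²) while per-sample fit
losses are bounded by 2). The test suite therefore verifies the fixed
point is a single-flip optimum by exhaustive enumeration, not that it
matches a global optimizer.

**Model-order selection.** The number of maps is chosen by repeated
split-half cross-validation over subjects (default 50 splits of 8 train /
8 test, k = 1..20): segment the training grand averages at each k, label
the training samples (with smoothing), and correlate each *test* sample
with the template its training label points to; the criterion is that
correlation averaged over samples, conditions and splits, and the selected
k maximizes it (ties to the smaller k). The superficially simpler
criterion — each test sample's best-matching template — is recorded as a
diagnostic but cannot drive selection: a larger dictionary can only raise
a best match, so that quantity is monotone in k. The label-transfer
criterion drops beyond the supported order because extra templates capture
training noise that the test data do not reproduce.

**Fitting and map statistics.** Fitting labels every sample of a grand
average with its best-correlating template (then optional smoothing),
within a configurable window — stimulus-aligned fits start at 190 ms
post-onset by default, matching the first window of waveform effects. Per
map and condition: duration = (count of labeled samples) × sample period,
summed over possibly discontiguous runs; onset = start of the first
labeled sample; offset = end of the last labeled sample; plus mean spatial
correlation and GEV share. A map never winning a sample has duration 0 and
undefined onset/offset, and is flagged.

**Randomization inference.** For a contrast of conditions, each subject's
ERPs are randomly reassigned to the condition slots, grand averages are
rebuilt, templates are re-fitted, and the statistic (duration, onset or
offset of one map) recomputed; the default 5000 permutations, seeded.
Two-condition contrasts use the absolute difference (two-sided); the
three-condition omnibus uses the range (max − min) of the statistic, a
choice documented here because the aggregation is genuinely open.
p = (#{null ≥ observed} + 1)/(n_perm + 1). Statistics for the final map of
a window are suppressed by default, because its duration is constrained by
the preceding map and the end of the signal; permutations in which the
tested map is never expressed are dropped for onset/offset, and the result
is flagged invalid if that happens in more than half of them. Smoothing is
off inside the permutation loop by default (it multiplies the cost of each
of thousands of refits and barely moves grand-average labelings);
it can be switched on.

**Template-set correlation.** The full k_a × k_b matrix of spatial
correlations plus a greedy one-to-one matching by descending correlation,
used to identify response-aligned maps with stimulus-aligned ones.

## Synthetic data

The generator emulates the study's structure: 17 subjects × 3 tasks (with
tones or syllables as distractors), 128 electrodes at 512 Hz, 72 trials
per condition, stimulus- and response-aligned epochs, right-skewed naming
latencies (log-normal; medians 817/844/887 ms for ST/pDT/aDT, shape 0.13,
matching the reported latency table for tones), an auditory evoked
component peaking 100 ms after the distractor onset at SOA +300 ms in
dual-task conditions only, and per-condition map-duration schedules whose
defaults mirror the reported effects (the lexical-window map longer under
higher attentional demand stimulus-aligned; the late response-locked map
longer in the active dual task).

Signal model per trial: a sequence of zero-mean unit-GFP dipolar template
maps (rejection-sampled to pairwise |r| ≤ 0.6) following the schedule with
±10% per-trial duration jitter, scaled by a smooth positive GFP envelope
(~5 μV), plus spatially correlated Gaussian noise (exponential covariance
over electrode distance, length scale half the head radius) scaled to a
target SNR defined as planted-signal GFP over noise GFP. The
stimulus-locked schedule anchors at −100 ms; the response-locked schedule
ends at vocal onset −100 ms and takes precedence where they overlap, which
reproduces the observed high correlation between late stimulus-aligned and
response-aligned maps.

Between-subject stage-timing variability is modeled by log-normal
per-segment duration multipliers (σ = 0.20, renormalized to the window),
set from the between-subject coefficient of variation of naming latencies
in this paradigm (13–20% across the latency table's cells). This term is
what gives the map-duration statistic a non-degenerate permutation null:
with all subjects sharing boundaries, grand-average durations barely move
under label permutation and a calibration study cannot resolve the nominal
level. `simulate_subject_erps` generates subject averages directly (SNR at
the subject-average level, where group analyses operate); it draws each
subject's boundaries sharply rather than modeling the within-subject blend
ramp that trial averaging would produce — grand averages still blend
across subjects, which is the feature that matters for the group-level
statistics.

What passing tests on these data do **not** show: robustness to ocular or
muscle artifacts (not simulated; the rejection stage is tested separately),
to volume-conducted correlated *signal* (noise is signal-independent), to
boundary blends inside single-subject averages, or to montage digitization
errors.

## Problem sizes in the acceptance checks

The acceptance suite runs the full machinery at sizes chosen to finish in
a few minutes on one CPU, as a deliberate scaling of the study's
dimensions: 32 electrodes (montage geometry and adjacency behave
identically), 256–512 Hz, 12–16 subjects, 4 planted maps, 199 permutations
per test with 200–500 simulated datasets for power and calibration, and
cross-validation with 10 splits of 6/6 subjects over k = 1..8. Model-order
recovery is assessed with stage timing shared across subjects: with
realistic between-subject timing spread the grand average genuinely
contains boundary-blend topographies, the supported model order exceeds
the per-subject planted k, and cross-validation correctly prefers more
maps — a property of grand-average microstate analysis worth knowing, not
a failure of selection. Calibration and power use the full generator
(timing spread included), since between-subject variability is exactly
what the randomization test permutes.

## Known limitations

* The epoch container is package-specific (HDF5 with explicit time-axis
  metadata); no interchange format covers response-locked epochs.
* BDF support writes 24-bit files with one-second records and integer
  sampling rates; EDF is read but not written.
* The repeated-measures ANOVA treats subjects as a random factor via the
  classical sum-of-squares decomposition; unbalanced designs are handled
  by excluding subjects with missing cells, not by mixed models.
* Duration statistics live on the sample lattice; with very low
  between-subject variability their permutation distributions are coarse
  and the randomization test becomes conservative.
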