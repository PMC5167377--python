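# erpstates

ERP waveform statistics and topographic microstate analysis for dual-task
word-production EEG.

When people name pictures while doing a second task, their naming slows
down — but *which* word-planning stage pays the cost? High-density ERPs
can answer this if the analysis separates amplitude effects from timing
effects: periods of quasi-stable scalp topography (**microstates**)
correspond to processing stages, and a stage under attentional load shows
up as a *longer* microstate, not a different one. `erpstates` is a tested,
reusable implementation of that analysis chain for researchers working
with stimulus-aligned and response-aligned (vocal-onset-locked) epochs:

* **Preprocessing** — 0.2–30 Hz zero-phase Butterworth, average reference,
  ±100 μV epoch rejection, joint stimulus/response trial masks, subject and
  grand averages, and removal of the response-aligned segment that
  overlaps the stimulus-aligned analysis window.
* **Mass-univariate statistics** — repeated-measures ANOVA (tasks
  ST/pDT/aDT) at every electrode × time point with planned pairwise
  contrasts, corrected by a spatio-temporal extent criterion: keep only
  effects spanning ≥ 5 montage-adjacent electrodes and ≥ 20 ms at α = 0.01.
* **Microstates** — modified k-means segmentation of grand averages scored
  by global explained variance, GEV = Σₜ(GFPₜ·r₍ₜ₎)²/ΣₜGFPₜ²; penalized
  label smoothing; split-half cross-validation over subjects to choose the
  number of maps; template fitting yielding per-map duration/onset/offset;
  and randomization tests that permute condition labels within subjects to
  get p-values for timing differences.
* **Synthetic data** — a generator that plants known microstate sequences,
  naming latencies and an auditory evoked component (SOA +300 ms) in
  multi-subject EEG, emitting full ground truth so every stage is testable
  without any recordings.
* **Pipeline & CLI** — `erpstates run --workdir out/` executes
  simulate → preprocess → waveform-stats → crossval → segment → fit →
  randtest → report from one YAML config, deterministically per seed.

## Worked example

`examples/03_microstate_segmentation.py` simulates 12 subjects with four
planted topographies at subject-average SNR 2, selects the model order by
cross-validation, and fits the chosen templates:

```
 k  mean_test_corr  mean_test_maxcorr
 1          0.4765             0.4765
 2          0.6785             0.6785
 3          0.8720             0.8720
 4          0.9798             0.9798
 5          0.9796             0.9799
 6          0.9792             0.9801
 ...
selected k = 4 (planted 4)
training GEV at k=4: 0.982
condition map  duration_ms  onset_ms  offset_ms  mean_corr  gev_share
       ST   1        152.3    -101.6       50.8        1.0        0.2
       ST   2        152.3      50.8      203.1        1.0        0.3
       ST   3        148.4     203.1      351.6        1.0        0.2
       ST   4        148.4     351.6      500.0        1.0        0.3
```

The selection criterion (`mean_test_corr`, training labels transferred to
held-out subjects) peaks at the planted k = 4, while the naive best-match
correlation (`mean_test_maxcorr`) keeps creeping upward with k — which is
why it cannot drive selection. The fitted durations recover the planted
150 ms schedule to within one sample, and each map's onset/offset bracket
its period of dominance.

`examples/04_randomization_test.py` plants an 80 ms duration difference on
one map and tests it by within-subject label permutation:

```
duration of map 2: ST 150 ms, aDT 234 ms
observed difference -84 ms (null mean 1.5 +/- 44.9 ms)
two-sided p = 0.0200 (999 permutations)
```

The other examples cover preprocessing/trimming, the cluster-filtered
waveform ANOVA, and the full pipeline (whose report prints per-condition
mean latencies, the cluster table, the selected k, map statistics and
randomization p-values).

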