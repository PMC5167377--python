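"""Microstate segmentation with cross-validated model-order selection.

Simulates subject ERPs with 4 planted maps, selects the number of maps by
split-half cross-validation, segments the grand average, and prints the
selected k, the GEV, and per-map duration/onset/offset per condition.
"""

import numpy as np

from erpstates.containers import GrandAverage
from erpstates.microstate import cross_validate_k, fit_templates, kmeans_segment
from erpstates.simulate import SimulationConfig, simulate_subject_erps

cfg = SimulationConfig(
    n_subjects=12, tasks=("ST",), n_electrodes=32, sfreq=256.0,
    k_templates=4, corr_cap=0.6,
    stim_schedule={"ST": [(0, 150), (1, 150), (2, 150), (3, 150)]},
    resp_schedule={"ST": [(3, 250), (2, 250)]},
    rt_median_ms={"ST": 1100.0}, auditory=None, snr=2.0, seed=2,
)
erps, truth = simulate_subject_erps(cfg, subject_jitter=False)

cv = cross_validate_k(
    erps, k_range=range(1, 9), n_splits=10, train_n=6, test_n=6,
    n_init=8, seed=0, smooth={"window": 10, "penalty": 3.0},
)
print(cv.to_frame().round(4).to_string(index=False))
print(f"selected k = {cv.selected_k} (planted {cfg.k_templates})")

ga = GrandAverage(
    condition="ST", alignment="stimulus", sfreq=cfg.sfreq,
    data=np.mean([e.data for e in erps], axis=0), times=erps[0].times,
    subjects=[e.subject for e in erps],
)
templates, gev = kmeans_segment(ga, cv.selected_k, n_init=50, seed=0)
print(f"training GEV at k={cv.selected_k}: {gev:.3f}")
_, stats = fit_templates(templates, ga, smooth={"window": 10, "penalty": 3.0})
print(stats.round(1).to_string(index=False))
# duration = total labeled time per map; onset/offset bracket each map's
# period of dominance; GEV share is its contribution to explained variance.
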