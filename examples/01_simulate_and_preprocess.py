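"""Simulate a small dual-task ERP dataset and preprocess it.

Builds 6 subjects x 3 tasks of epoched EEG with planted microstate
structure, applies the standard chain (average reference, +/-100 uV
rejection, joint stimulus/response trial masks, subject averages, grand
averages, overlap trimming) and prints the per-condition mean naming
latency and the trimmed response-aligned span.
"""

import numpy as np

from erpstates.preprocess import (
    average_epochs,
    grand_average,
    harmonize_masks,
    reject_artifacts,
    rereference_average,
    trim_overlap,
)
from erpstates.simulate import SimulationConfig, simulate_dataset

cfg = SimulationConfig(
    n_subjects=6, n_electrodes=32, trials_per_condition=12, seed=1
)
ds = simulate_dataset(cfg)
print(f"simulated {len(ds.epochs)} epoch sets, {len(ds.logs)} trials")

by_key = {(e.subject, e.condition, e.alignment): e for e in ds.epochs}
erps = []
for (subject, condition, alignment), ep in sorted(by_key.items()):
    if alignment != "stimulus":
        continue
    resp = by_key[(subject, condition, "response")]
    pair = []
    for e in (ep, resp):
        e.data = rereference_average(e.data)
        pair.append(reject_artifacts(e, 100.0))
    stim_e, resp_e = harmonize_masks(*pair)
    erps += [average_epochs(stim_e, min_epochs=8), average_epochs(resp_e, min_epochs=8)]

for condition in cfg.tasks:
    stim = [e for e in erps if e.condition == condition and e.alignment == "stimulus"]
    resp = [e for e in erps if e.condition == condition and e.alignment == "response"]
    ga_stim = grand_average(stim)
    ga_resp = trim_overlap(grand_average(resp))
    print(
        f"{condition}: mean RT {ga_stim.mean_rt_ms:6.0f} ms, "
        f"response window kept {ga_resp.times[0]:.0f}..{ga_resp.times[-1]:.0f} ms "
        f"(trimmed {ga_resp.trimmed_span_ms})"
    )
# Mean RTs rise with attentional demand (ST < pDT < aDT); the trimmed span
# is the part of the response-aligned average that would duplicate signal
# already analyzed in the 0..500 ms stimulus-aligned window.
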