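"""Filtering, re-referencing, artifact rejection, epoching and averaging.

The processing chain mirrors standard ERP practice for overt word
production: 0.2–30 Hz zero-phase Butterworth bandpass, average reference,
±100 μV amplitude rejection, stimulus-aligned (-100..+500 ms) and
response-aligned (500 ms ending 100 ms before vocal onset) epochs, subject
averages with a minimum trial count, grand averages, and removal of the
portion of the response-aligned grand average that overlaps the
stimulus-aligned analysis window given the condition's mean latency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace

import numpy as np
from scipy import signal

from .containers import (
    RESP_WINDOW_MS,
    STIM_WINDOW_MS,
    EpochSet,
    GrandAverage,
    Recording,
    SubjectERP,
    TrialLog,
)

logger = logging.getLogger(__name__)

DEFAULT_BAND_HZ = (0.2, 30.0)
DEFAULT_FILTER_ORDER = 2
DEFAULT_REJECT_UV = 100.0
DEFAULT_MIN_EPOCHS = 31


def bandpass(
    data: np.ndarray,
    sfreq: float,
    low: float = DEFAULT_BAND_HZ[0],
    high: float = DEFAULT_BAND_HZ[1],
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth bandpass along the last axis.

    The filter is designed at the given order; applying it in both
    directions doubles the effective roll-off and removes phase delay.
    """
    nyq = sfreq / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band edges must satisfy 0 < {low} < {high} < {nyq}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=sfreq, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def rereference_average(data: np.ndarray) -> np.ndarray:
    """Re-reference to the common average: subtract the channel mean per sample.

    Accepts ``(..., electrodes, samples)``; the electrode axis is ``-2``.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[-2] < 2:
        raise ValueError("average reference needs at least 2 channels")
    return data - data.mean(axis=-2, keepdims=True)


def reject_artifacts(epochs: EpochSet, threshold: float = DEFAULT_REJECT_UV) -> EpochSet:
    """Mask out epochs whose amplitude strictly exceeds ``±threshold`` μV.

    A sample at exactly the threshold is kept (the criterion is exceedance).
    The returned mask is the AND of the existing mask and the amplitude
    criterion, so rejection composes with prior exclusions.
    """
    if threshold <= 0:
        raise ValueError("rejection threshold must be positive")
    bad = np.any(np.abs(epochs.data) > threshold, axis=(1, 2))
    return replace(epochs, mask=epochs.mask & ~bad)


def _window_samples(sfreq: float, start_ms: float, stop_ms: float) -> np.ndarray:
    """Sample offsets (relative to the alignment point) covering [start, stop)."""
    dt = 1000.0 / sfreq
    n = int(round((stop_ms - start_ms) / dt))
    return np.arange(n) + int(round(start_ms / dt))


def make_epochs(
    raw: Recording,
    onsets: np.ndarray,
    trials: list[TrialLog],
    alignment: str,
    stim_window_ms: tuple[float, float] = STIM_WINDOW_MS,
) -> EpochSet:
    """Cut epochs around picture onsets (stimulus) or vocal onsets (response).

    Parameters
    ----------
    onsets
        Picture-onset sample indices, one per trial log entry.
    trials
        Behavioral records; only correct, non-filler trials are epoched.
        Response alignment additionally requires each trial's latency.
    alignment
        ``"stimulus"`` — window ``stim_window_ms`` around picture onset;
        ``"response"`` — 500 ms ending 100 ms before vocal onset.

    Trials whose window would exceed the recording bounds are dropped with a
    log entry.  Error and filler trials are excluded up front.
    """
    onsets = np.asarray(onsets, dtype=int)
    if len(onsets) != len(trials):
        raise ValueError("one onset per trial log entry required")
    dt = 1000.0 / raw.sfreq
    if alignment == "stimulus":
        offs = _window_samples(raw.sfreq, *stim_window_ms)
    elif alignment == "response":
        offs = _window_samples(raw.sfreq, *RESP_WINDOW_MS)
    else:
        raise ValueError(f"unknown alignment {alignment!r}")

    subject = trials[0].subject if trials else "unknown"
    condition = trials[0].condition if trials else "ST"
    segs, lats = [], []
    for onset, tr in zip(onsets, trials):
        if not tr.correct or tr.filler:
            continue
        if alignment == "response":
            anchor = onset + int(round(tr.rt_ms / dt))
        else:
            anchor = onset
        idx = anchor + offs
        if idx[0] < 0 or idx[-1] >= raw.n_samples:
            logger.warning(
                "trial %s/%d: %s window [%d, %d] outside recording; dropped",
                tr.subject, tr.trial, alignment, idx[0], idx[-1],
            )
            continue
        segs.append(raw.data[:, idx])
        lats.append(tr.rt_ms)
    n_e = raw.montage.n_electrodes
    n_s = len(offs)
    data = np.stack(segs) if segs else np.empty((0, n_e, n_s))
    return EpochSet(
        subject=subject,
        condition=condition,
        alignment=alignment,
        sfreq=raw.sfreq,
        data=data,
        times=offs * dt,
        latencies=np.array(lats, dtype=float),
        mask=np.ones(len(segs), dtype=bool),
    )


def harmonize_masks(stim: EpochSet, resp: EpochSet) -> tuple[EpochSet, EpochSet]:
    """Keep only trials surviving rejection in BOTH alignments.

    Subject averages use the intersection so stimulus- and response-aligned
    ERPs are built from the same trials.
    """
    if stim.n_trials != resp.n_trials:
        raise ValueError("stimulus/response epoch sets must cover the same trials")
    joint = stim.mask & resp.mask
    return replace(stim, mask=joint), replace(resp, mask=joint)


def average_epochs(epochs: EpochSet, min_epochs: int = DEFAULT_MIN_EPOCHS) -> SubjectERP:
    """Average retained trials into a single-subject ERP.

    Raises if fewer than ``min_epochs`` trials survive — underpowered
    averages are excluded from group analysis, mirroring the per-subject
    inclusion threshold.
    """
    n = epochs.n_kept
    if n < min_epochs:
        raise ValueError(
            f"subject {epochs.subject} {epochs.condition}/{epochs.alignment}: "
            f"only {n} epochs survive (minimum {min_epochs})"
        )
    kept_rts = epochs.latencies[epochs.mask]
    return SubjectERP(
        subject=epochs.subject,
        condition=epochs.condition,
        alignment=epochs.alignment,
        sfreq=epochs.sfreq,
        data=epochs.kept().mean(axis=0),
        times=epochs.times.copy(),
        n_epochs=n,
        mean_rt_ms=float(np.mean(kept_rts)) if len(kept_rts) else None,
    )


def grand_average(erps: list[SubjectERP]) -> GrandAverage:
    """Unweighted across-subject mean of per-subject averages."""
    if len(erps) < 2:
        raise ValueError("grand average needs at least 2 subjects")
    first = erps[0]
    for e in erps[1:]:
        if e.condition != first.condition or e.alignment != first.alignment:
            raise ValueError("all subject ERPs must share condition and alignment")
        if e.sfreq != first.sfreq or not np.array_equal(e.times, first.times):
            raise ValueError("heterogeneous time axes")
        if e.data.shape != first.data.shape:
            raise ValueError("heterogeneous data shapes")
    stack = np.stack([e.data for e in erps])
    rts = [e.mean_rt_ms for e in erps if e.mean_rt_ms is not None]
    return GrandAverage(
        condition=first.condition,
        alignment=first.alignment,
        sfreq=first.sfreq,
        data=stack.mean(axis=0),
        times=first.times.copy(),
        subjects=[e.subject for e in erps],
        mean_rt_ms=float(np.mean(rts)) if rts else None,
    )


def trim_overlap(resp: GrandAverage, stim_window_end_ms: float = STIM_WINDOW_MS[1]) -> GrandAverage:
    """Drop the head of a response-aligned grand average that overlaps the
    stimulus-aligned window.

    A response-aligned sample at relative time ``tau`` (ms before/after vocal
    onset) sits at ``mean_rt + tau`` ms post picture onset; samples with
    ``mean_rt + tau < stim_window_end_ms`` repeat signal already analyzed
    stimulus-aligned and are removed.  The trimmed span (in the response-
    aligned axis) is recorded on the result.
    """
    if resp.alignment != "response":
        raise ValueError("trim_overlap applies to response-aligned grand averages")
    if resp.mean_rt_ms is None:
        raise ValueError("mean production latency required for overlap trimming")
    cutoff = stim_window_end_ms - resp.mean_rt_ms  # in the response-aligned axis
    # a sample is removed when its whole period lies inside the overlap
    dt = 1000.0 / resp.sfreq
    overlap = resp.times + dt <= cutoff + 1e-9
    n_cut = int(overlap.sum())
    if n_cut == 0:
        return replace(resp, trimmed_span_ms=None)
    if n_cut >= len(resp.times):
        raise ValueError(
            f"overlap trimming would remove the whole response-aligned window "
            f"(mean RT {resp.mean_rt_ms:.0f} ms)"
        )
    if n_cut >= len(resp.times) - max(1, int(round(resp.sfreq * 0.005))):
        warnings.warn(
            f"overlap trimming leaves only {len(resp.times) - n_cut} samples",
            stacklevel=2,
        )
    span = (float(resp.times[0]), float(resp.times[n_cut - 1] + 1000.0 / resp.sfreq))
    return replace(
        resp,
        data=resp.data[:, ~overlap],
        times=resp.times[~overlap],
        trimmed_span_ms=span,
    )
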