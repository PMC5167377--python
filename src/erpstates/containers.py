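"""In-memory containers shared across the pipeline.

Conventions fixed package-wide: amplitudes in microvolts, times in
milliseconds, sampling rate in Hz.  Stimulus-aligned epochs span
-100..+500 ms around picture onset; response-aligned epochs span a 500 ms
window ending 100 ms before vocal onset (fixed relative axis -600..-100 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import Montage

#: canonical task labels: single task, passive dual-task, active dual-task
TASKS = ("ST", "pDT", "aDT")
DISTRACTORS = ("tones", "syllables", "none")
ALIGNMENTS = ("stimulus", "response")

STIM_WINDOW_MS = (-100.0, 500.0)
RESP_WINDOW_MS = (-600.0, -100.0)  # relative to vocal onset


@dataclass
class Recording:
    """Continuous multi-channel recording in microvolts."""

    data: np.ndarray  # channels x samples, μV
    sfreq: float
    montage: Montage

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be channels x samples")
        if self.data.shape[0] != self.montage.n_electrodes:
            raise ValueError(
                f"{self.data.shape[0]} channels but montage has "
                f"{self.montage.n_electrodes} electrodes"
            )
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class TrialLog:
    """One behavioral record: condition, vocal-onset latency, accuracy."""

    subject: str
    trial: int
    condition: str  # ST | pDT | aDT
    distractor: str  # tones | syllables | none
    rt_ms: float | None  # vocal-onset latency; None for error trials
    correct: bool
    filler: bool = False

    def __post_init__(self) -> None:
        if self.condition not in TASKS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.distractor not in DISTRACTORS:
            raise ValueError(f"unknown distractor {self.distractor!r}")
        if self.correct and self.rt_ms is None:
            raise ValueError("correct trial must have a vocal-onset latency")
        if not self.correct and self.rt_ms is not None:
            raise ValueError("error trial must not carry a latency")


@dataclass
class EpochSet:
    """Per-subject trial tensor for one condition and alignment.

    ``data`` is trials x electrodes x samples (μV).  ``times`` is the shared
    time axis in ms relative to the alignment point.  ``latencies`` holds the
    per-trial vocal-onset latency (ms post picture onset).  ``mask`` marks
    trials retained for averaging (True = keep).
    """

    subject: str
    condition: str
    alignment: str
    sfreq: float
    data: np.ndarray
    times: np.ndarray
    latencies: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.latencies = np.asarray(self.latencies, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.alignment not in ALIGNMENTS:
            raise ValueError(f"alignment must be one of {ALIGNMENTS}")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x electrodes x samples")
        if self.times.shape != (self.data.shape[2],):
            raise ValueError("time axis length must match sample count")
        n = self.data.shape[0]
        if self.mask.shape != (n,) or self.latencies.shape != (n,):
            raise ValueError("mask/latencies length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.mask.sum())

    def kept(self) -> np.ndarray:
        return self.data[self.mask]


@dataclass
class SubjectERP:
    """Single-subject average for one condition and alignment."""

    subject: str
    condition: str
    alignment: str
    sfreq: float
    data: np.ndarray  # electrodes x samples, μV
    times: np.ndarray  # ms
    n_epochs: int
    mean_rt_ms: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("average must be electrodes x samples")
        if self.times.shape != (self.data.shape[1],):
            raise ValueError("time axis length must match sample count")


@dataclass
class GrandAverage:
    """Across-subject mean ERP for one condition and alignment."""

    condition: str
    alignment: str
    sfreq: float
    data: np.ndarray  # electrodes x samples, μV
    times: np.ndarray  # ms
    subjects: list[str]
    mean_rt_ms: float | None = None
    trimmed_span_ms: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("grand average must be electrodes x samples")
        if self.times.shape != (self.data.shape[1],):
            raise ValueError("time axis length must match sample count")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)
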