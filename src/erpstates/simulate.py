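"""Synthetic multi-subject ERP data with planted microstate structure.

The generator emulates the structure of a dual-task picture-naming study:
BioSemi-style montage (default 128 electrodes, 512 Hz), three tasks
(single task ST, passive dual-task pDT, active dual-task aDT), 72 trials
per condition, stimulus-aligned epochs (-100..+500 ms), response-aligned
epochs (500 ms ending 100 ms before vocal onset), right-skewed naming
latencies, an auditory evoked component 300 ms after picture onset (the
distractor SOA) in dual-task conditions, and condition-dependent map
duration schedules.  Every simulation emits its full ground truth (planted
templates, label timelines, per-trial latencies) so recovery can be tested
without any real recordings.

Signal model per trial: a sequence of zero-mean unit-GFP template maps
following the condition's duration schedule (per-trial jitter ±10%),
scaled by a smooth positive GFP envelope, plus the auditory component in
dual-task conditions, plus spatially correlated Gaussian noise scaled to a
target SNR (planted-signal GFP over noise GFP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .containers import (
    RESP_WINDOW_MS,
    STIM_WINDOW_MS,
    EpochSet,
    SubjectERP,
    TrialLog,
)
from .microstate import MicrostateTemplates, gfp
from .montage import Montage, build_adjacency

SOA_MS = 300.0  # distractor onset relative to picture onset

#: duration schedules in ms per map index; stimulus epochs span 600 ms,
#: response epochs 500 ms.  The map-4 slot carries the planted dual-task
#: effect stimulus-aligned (longer under higher attentional demand), the
#: last response-locked slot carries the response-aligned effect.
DEFAULT_STIM_SCHEDULE = {
    "ST": [(0, 100), (1, 140), (2, 100), (3, 46), (4, 110), (5, 104)],
    "pDT": [(0, 100), (1, 140), (2, 100), (3, 64), (4, 110), (5, 86)],
    "aDT": [(0, 100), (1, 140), (2, 100), (3, 124), (4, 70), (5, 66)],
}
DEFAULT_RESP_SCHEDULE = {
    "ST": [(4, 204), (5, 174), (6, 122)],
    "pDT": [(4, 170), (5, 172), (6, 158)],
    "aDT": [(4, 140), (5, 132), (6, 228)],
}
DEFAULT_RT_MEDIAN_MS = {"ST": 817.0, "pDT": 844.0, "aDT": 887.0}


@dataclass
class AuditoryComponent:
    """Evoked response to the auditory distractor (dual-task only)."""

    latency_ms: float = 100.0  # peak relative to distractor onset
    amplitude_uv: float = 3.0
    width_ms: float = 25.0  # Gaussian SD of the time course


@dataclass
class SimulationConfig:
    n_subjects: int = 17
    tasks: tuple[str, ...] = ("ST", "pDT", "aDT")
    distractor: str = "tones"
    n_electrodes: int = 128
    sfreq: float = 512.0
    montage_seed: int = 0
    k_templates: int = 7
    corr_cap: float = 0.6
    stim_schedule: dict = field(default_factory=lambda: dict(DEFAULT_STIM_SCHEDULE))
    resp_schedule: dict = field(default_factory=lambda: dict(DEFAULT_RESP_SCHEDULE))
    rt_median_ms: dict = field(default_factory=lambda: dict(DEFAULT_RT_MEDIAN_MS))
    rt_sigma: float = 0.13  # log-normal shape; SD/mean ~ 13% as in naming data
    rt_subject_sigma: float = 0.05
    auditory: AuditoryComponent | None = field(default_factory=AuditoryComponent)
    snr: float = 2.0
    noise_length_scale: float = 0.5  # fraction of head radius
    signal_gfp_uv: float = 5.0
    trials_per_condition: int = 72
    n_fillers: int = 18
    jitter_frac: float = 0.10
    #: between-subject stage-timing variability: per-segment log-normal
    #: duration multipliers exp(N(0, sigma)), renormalized to the window.
    #: Matches the 13-20% between-subject coefficient of variation of
    #: naming latencies in this paradigm.
    subject_timing_sigma: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("SNR must be positive")
        stim_len = STIM_WINDOW_MS[1] - STIM_WINDOW_MS[0]
        resp_len = RESP_WINDOW_MS[1] - RESP_WINDOW_MS[0]
        for task in self.tasks:
            if abs(sum(d for _, d in self.stim_schedule[task]) - stim_len) > 1e-6:
                raise ValueError(f"{task}: stimulus schedule must sum to {stim_len} ms")
            if abs(sum(d for _, d in self.resp_schedule[task]) - resp_len) > 1e-6:
                raise ValueError(f"{task}: response schedule must sum to {resp_len} ms")
            top = max(
                m for m, _ in self.stim_schedule[task] + self.resp_schedule[task]
            )
            if top >= self.k_templates:
                raise ValueError(
                    f"{task}: schedule references map {top} but only "
                    f"{self.k_templates} templates are planted"
                )


# ---------------------------------------------------------------------------
# montage and templates


def make_montage(n_electrodes: int = 128, seed: int = 0, radius: float = 1.0) -> Montage:
    """Fibonacci-spiral electrode layout on the upper two thirds of a sphere."""
    golden = (1 + 5**0.5) / 2
    i = np.arange(n_electrodes)
    # z from just above the equatorial rim to near the vertex
    z = np.linspace(-0.45, 0.985, n_electrodes)
    phi = 2 * np.pi * i / golden
    rho = np.sqrt(1 - z**2)
    pos = radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    labels = [f"E{j + 1}" for j in range(n_electrodes)]
    return build_adjacency(Montage(labels=labels, positions=pos))


def _dipolar_map(montage: Montage, rng: np.random.Generator) -> np.ndarray:
    """Smooth dipole-like scalp pattern: potential of a random interior dipole."""
    radius = float(np.linalg.norm(montage.positions, axis=1).mean())
    src = rng.normal(size=3)
    src = src / np.linalg.norm(src) * rng.uniform(0.2, 0.7) * radius
    moment = rng.normal(size=3)
    moment /= np.linalg.norm(moment)
    d = montage.positions - src
    dist = np.linalg.norm(d, axis=1)
    v = (d @ moment) / dist**3
    v = v - v.mean()
    g = v.std()
    if g == 0:
        raise ValueError("degenerate dipolar map")
    return v / g


def make_templates(
    k: int,
    montage: Montage,
    corr_cap: float = 0.6,
    seed: int | None = None,
    max_attempts: int = 2000,
) -> MicrostateTemplates:
    """Rejection-sample k dipolar maps with pairwise |r| below ``corr_cap``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    maps: list[np.ndarray] = []
    attempts = 0
    while len(maps) < k:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not draw {k} maps with pairwise |r| <= {corr_cap} "
                f"in {max_attempts} attempts"
            )
        attempts += 1
        cand = _dipolar_map(montage, rng)
        n = np.linalg.norm(cand)
        ok = all(
            abs(cand @ m / (n * np.linalg.norm(m))) <= corr_cap for m in maps
        )
        if ok:
            maps.append(cand)
    return MicrostateTemplates(
        maps=np.stack(maps),
        ids=[str(i + 1) for i in range(k)],
        provenance=f"synthetic dipolar maps (seed={seed})",
    )


# ---------------------------------------------------------------------------
# label timelines


def _jitter_schedule(
    schedule: list[tuple[int, float]], jitter: float, rng: np.random.Generator
) -> list[tuple[int, float]]:
    """Uniform ±jitter per-segment duration jitter, renormalized."""
    durs = np.array([d for _, d in schedule], dtype=float)
    if jitter > 0:
        durs = durs * rng.uniform(1 - jitter, 1 + jitter, size=len(durs))
        durs *= sum(d for _, d in schedule) / durs.sum()
    return [(m, float(d)) for (m, _), d in zip(schedule, durs)]


def _subject_schedule(
    schedule: list[tuple[int, float]], sigma: float, rng: np.random.Generator
) -> list[tuple[int, float]]:
    """Between-subject timing: log-normal per-segment multipliers, renormalized."""
    durs = np.array([d for _, d in schedule], dtype=float)
    if sigma > 0:
        durs = durs * np.exp(rng.normal(0.0, sigma, size=len(durs)))
        durs *= sum(d for _, d in schedule) / durs.sum()
    return [(m, float(d)) for (m, _), d in zip(schedule, durs)]


def _lookup(schedule: list[tuple[int, float]], t: np.ndarray, start: float) -> np.ndarray:
    """Map times (ms) onto schedule segments anchored at ``start``."""
    edges = np.concatenate([[0.0], np.cumsum([d for _, d in schedule])]) + start
    ids = np.array([m for m, _ in schedule])
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(ids) - 1)
    return ids[idx]


def trial_label_timeline(
    t_ms: np.ndarray,
    rt_ms: float,
    stim_schedule: list[tuple[int, float]],
    resp_schedule: list[tuple[int, float]],
) -> np.ndarray:
    """Planted map index at absolute times ``t_ms`` (post picture onset).

    The stimulus-locked schedule is anchored at -100 ms; the response-locked
    schedule ends at vocal onset - 100 ms and takes precedence where the two
    overlap (articulation-locked processes dominate late signal).  Any gap
    between the schedules is filled by extending the last stimulus-locked map.
    """
    resp_total = sum(d for _, d in resp_schedule)
    resp_start = rt_ms - 100.0 - resp_total
    labels = _lookup(stim_schedule, t_ms, STIM_WINDOW_MS[0])
    gap = (t_ms >= STIM_WINDOW_MS[1]) & (t_ms < resp_start)
    labels[gap] = stim_schedule[-1][0]
    in_resp = t_ms >= resp_start
    labels[in_resp] = _lookup(resp_schedule, t_ms[in_resp], resp_start)
    return labels


def _envelope(t_ms: np.ndarray) -> np.ndarray:
    """Smooth positive GFP envelope (soft peaks, never near zero)."""
    return 1.0 + 0.4 * np.sin(np.pi * (t_ms + 100.0) / 350.0) ** 2


def _noise_chol(montage: Montage, length_scale: float) -> np.ndarray:
    pos = montage.positions
    radius = float(np.linalg.norm(pos, axis=1).mean())
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    K = np.exp(-d / (length_scale * radius))
    return np.linalg.cholesky(K + 1e-8 * np.eye(len(pos)))


def _scaled_noise(
    shape_samples: int,
    chol: np.ndarray,
    target_gfp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    z = rng.standard_normal((chol.shape[0], shape_samples))
    n = chol @ z
    n = n - n.mean(axis=0, keepdims=True)
    scale = gfp(n).mean()
    return n * (target_gfp / scale) if scale > 0 else n


# ---------------------------------------------------------------------------
# dataset-level generators


@dataclass
class GroundTruth:
    """Everything the analysis is expected to recover."""

    templates: MicrostateTemplates
    montage: Montage
    auditory_map: np.ndarray | None
    stim_schedule: dict
    resp_schedule: dict
    rt_ms: dict  # (subject, condition) -> per-trial RTs or subject mean
    stim_labels: dict  # condition -> planted label array on the stimulus grid
    resp_labels: dict  # condition -> planted label array on the response grid
    durations_ms: dict  # (condition, alignment, map index) -> planted duration


def _grid(window_ms: tuple[float, float], sfreq: float) -> np.ndarray:
    dt = 1000.0 / sfreq
    n = int(round((window_ms[1] - window_ms[0]) / dt))
    return (np.arange(n) + int(round(window_ms[0] / dt))) * dt


def _planted_labels(cfg: SimulationConfig) -> tuple[dict, dict, dict]:
    """Noise-free, jitter-free label grids and the implied durations."""
    stim_t = _grid(STIM_WINDOW_MS, cfg.sfreq)
    resp_rel = _grid(RESP_WINDOW_MS, cfg.sfreq)
    dt = 1000.0 / cfg.sfreq
    stim_labels, resp_labels, durations = {}, {}, {}
    for task in cfg.tasks:
        rt = cfg.rt_median_ms[task]
        stim_labels[task] = trial_label_timeline(
            stim_t, rt, cfg.stim_schedule[task], cfg.resp_schedule[task]
        )
        resp_labels[task] = trial_label_timeline(
            resp_rel + rt, rt, cfg.stim_schedule[task], cfg.resp_schedule[task]
        )
        for align, lab in (("stimulus", stim_labels[task]), ("response", resp_labels[task])):
            for m in range(cfg.k_templates):
                durations[(task, align, m)] = float(np.sum(lab == m) * dt)
    return stim_labels, resp_labels, durations


def _signal_for_times(
    t_abs: np.ndarray,
    rt: float,
    task: str,
    cfg: SimulationConfig,
    templates: MicrostateTemplates,
    aud_map: np.ndarray | None,
    stim_sched: list[tuple[int, float]],
    resp_sched: list[tuple[int, float]],
) -> np.ndarray:
    labels = trial_label_timeline(t_abs, rt, stim_sched, resp_sched)
    sig = templates.maps[labels].T * (_envelope(t_abs) * cfg.signal_gfp_uv)
    if cfg.auditory is not None and aud_map is not None and task in ("pDT", "aDT"):
        peak = SOA_MS + cfg.auditory.latency_ms
        tc = cfg.auditory.amplitude_uv * np.exp(
            -0.5 * ((t_abs - peak) / cfg.auditory.width_ms) ** 2
        )
        sig = sig + aud_map[:, None] * tc
    return sig


@dataclass
class SimulatedDataset:
    epochs: list[EpochSet]
    logs: list[TrialLog]
    montage: Montage
    truth: GroundTruth


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Simulate epoched EEG for every subject, condition and alignment.

    Per trial: planted map sequence (jittered durations), GFP envelope,
    auditory component at SOA + latency for dual-task conditions, spatially
    correlated noise at the configured single-trial SNR, and a log-normal
    naming latency that anchors the response-aligned epoch.
    """
    rng = np.random.default_rng(cfg.seed)
    montage = make_montage(cfg.n_electrodes, cfg.montage_seed)
    templates = make_templates(
        cfg.k_templates, montage, cfg.corr_cap, seed=int(rng.integers(2**31 - 1))
    )
    aud_map = (
        _dipolar_map(montage, rng) if cfg.auditory is not None else None
    )
    chol = _noise_chol(montage, cfg.noise_length_scale)
    stim_t = _grid(STIM_WINDOW_MS, cfg.sfreq)
    resp_rel = _grid(RESP_WINDOW_MS, cfg.sfreq)

    stim_labels, resp_labels, durations = _planted_labels(cfg)
    epochs: list[EpochSet] = []
    logs: list[TrialLog] = []
    rts_truth: dict = {}
    mean_env_gfp = float((_envelope(stim_t) * cfg.signal_gfp_uv).mean())
    noise_gfp = mean_env_gfp / cfg.snr

    for s_i in range(cfg.n_subjects):
        subject = f"S{s_i + 1:02d}"
        subj_rt_factor = math.exp(rng.normal(0.0, cfg.rt_subject_sigma))
        for task in cfg.tasks:
            n_tr = cfg.trials_per_condition
            rts = cfg.rt_median_ms[task] * subj_rt_factor * np.exp(
                rng.normal(0.0, cfg.rt_sigma, size=n_tr)
            )
            rts_truth[(subject, task)] = rts
            stim_data = np.empty((n_tr, cfg.n_electrodes, len(stim_t)))
            resp_data = np.empty((n_tr, cfg.n_electrodes, len(resp_rel)))
            subj_ssched = _subject_schedule(
                cfg.stim_schedule[task], cfg.subject_timing_sigma, rng
            )
            subj_rsched = _subject_schedule(
                cfg.resp_schedule[task], cfg.subject_timing_sigma, rng
            )
            for tr in range(n_tr):
                ssched = _jitter_schedule(subj_ssched, cfg.jitter_frac, rng)
                rsched = _jitter_schedule(subj_rsched, cfg.jitter_frac, rng)
                rt = float(rts[tr])
                s_sig = _signal_for_times(
                    stim_t, rt, task, cfg, templates, aud_map, ssched, rsched
                )
                r_sig = _signal_for_times(
                    resp_rel + rt, rt, task, cfg, templates, aud_map, ssched, rsched
                )
                stim_data[tr] = s_sig + _scaled_noise(len(stim_t), chol, noise_gfp, rng)
                resp_data[tr] = r_sig + _scaled_noise(len(resp_rel), chol, noise_gfp, rng)
                logs.append(
                    TrialLog(
                        subject=subject,
                        trial=tr + 1,
                        condition=task,
                        distractor=cfg.distractor if task != "ST" else "none",
                        rt_ms=rt,
                        correct=True,
                    )
                )
            common = dict(subject=subject, condition=task, sfreq=cfg.sfreq,
                          latencies=rts, mask=np.ones(n_tr, dtype=bool))
            epochs.append(EpochSet(alignment="stimulus", data=stim_data,
                                   times=stim_t, **common))
            epochs.append(EpochSet(alignment="response", data=resp_data,
                                   times=resp_rel, **common))
    truth = GroundTruth(
        templates=templates,
        montage=montage,
        auditory_map=aud_map,
        stim_schedule=dict(cfg.stim_schedule),
        resp_schedule=dict(cfg.resp_schedule),
        rt_ms=rts_truth,
        stim_labels=stim_labels,
        resp_labels=resp_labels,
        durations_ms=durations,
    )
    return SimulatedDataset(epochs=epochs, logs=logs, montage=montage, truth=truth)


def simulate_subject_erps(
    cfg: SimulationConfig,
    alignment: str = "stimulus",
    subject_jitter: bool = True,
) -> tuple[list[SubjectERP], GroundTruth]:
    """Simulate single-subject average ERPs directly (no per-trial loop).

    The SNR here applies at the subject-average level — the natural scale
    for group analyses (cross-validation, randomization inference), where
    trial-level noise has already been averaged down.  Per-subject segment
    durations carry log-normal multipliers (``subject_timing_sigma``),
    modeling between-subject variability in processing-stage timing — the
    same variability that makes grand-average microstate boundaries soft;
    boundary blending within a subject's average is not modeled (see the
    methods note).
    """
    rng = np.random.default_rng(cfg.seed)
    montage = make_montage(cfg.n_electrodes, cfg.montage_seed)
    templates = make_templates(
        cfg.k_templates, montage, cfg.corr_cap, seed=int(rng.integers(2**31 - 1))
    )
    aud_map = _dipolar_map(montage, rng) if cfg.auditory is not None else None
    chol = _noise_chol(montage, cfg.noise_length_scale)
    window = STIM_WINDOW_MS if alignment == "stimulus" else RESP_WINDOW_MS
    t_rel = _grid(window, cfg.sfreq)
    stim_labels, resp_labels, durations = _planted_labels(cfg)
    mean_env_gfp = float((_envelope(t_rel if alignment == "stimulus" else t_rel + 800)
                          * cfg.signal_gfp_uv).mean())
    noise_gfp = mean_env_gfp / cfg.snr

    erps: list[SubjectERP] = []
    rts_truth: dict = {}
    sigma = cfg.subject_timing_sigma if subject_jitter else 0.0
    for s_i in range(cfg.n_subjects):
        subject = f"S{s_i + 1:02d}"
        subj_rt_factor = math.exp(rng.normal(0.0, cfg.rt_subject_sigma))
        for task in cfg.tasks:
            rt = cfg.rt_median_ms[task] * subj_rt_factor
            rts_truth[(subject, task)] = rt
            ssched = _subject_schedule(cfg.stim_schedule[task], sigma, rng)
            rsched = _subject_schedule(cfg.resp_schedule[task], sigma, rng)
            t_abs = t_rel if alignment == "stimulus" else t_rel + rt
            sig = _signal_for_times(
                t_abs, rt, task, cfg, templates, aud_map, ssched, rsched
            )
            noise = _scaled_noise(len(t_rel), chol, noise_gfp, rng) if cfg.snr < math.inf else 0.0
            erps.append(
                SubjectERP(
                    subject=subject,
                    condition=task,
                    alignment=alignment,
                    sfreq=cfg.sfreq,
                    data=sig + noise,
                    times=t_rel,
                    n_epochs=cfg.trials_per_condition,
                    mean_rt_ms=rt,
                )
            )
    truth = GroundTruth(
        templates=templates,
        montage=montage,
        auditory_map=aud_map,
        stim_schedule=dict(cfg.stim_schedule),
        resp_schedule=dict(cfg.resp_schedule),
        rt_ms=rts_truth,
        stim_labels=stim_labels,
        resp_labels=resp_labels,
        durations_ms=durations,
    )
    return erps, truth


def null_schedules(cfg: SimulationConfig) -> SimulationConfig:
    """Copy of *cfg* with identical schedules and RT model for every task —
    i.e. no planted condition effect (for calibration studies)."""
    from dataclasses import replace

    base_s = cfg.stim_schedule[cfg.tasks[0]]
    base_r = cfg.resp_schedule[cfg.tasks[0]]
    base_rt = cfg.rt_median_ms[cfg.tasks[0]]
    return replace(
        cfg,
        stim_schedule={t: list(base_s) for t in cfg.tasks},
        resp_schedule={t: list(base_r) for t in cfg.tasks},
        rt_median_ms={t: base_rt for t in cfg.tasks},
    )
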