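"""Staged analysis pipeline: simulate → preprocess → waveform-stats →
segment/crossval/fit/randtest → report.

Stages communicate only through files in a working directory (HDF5 epoch
container, CSV tables, NPZ template sets), so each stage can be re-run or
tested in isolation.  A single :class:`RunConfig` carries every stage
parameter plus one global seed; identical config and seed give identical
numeric outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from . import io as eio
from . import mass_univariate as mu
from . import microstate as ms
from . import preprocess as pp
from . import simulate as sim
from .containers import STIM_WINDOW_MS, GrandAverage


class _Params(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateParams(_Params):
    n_subjects: int = 17
    tasks: tuple[str, ...] = ("ST", "pDT", "aDT")
    distractor: str = "tones"
    n_electrodes: int = 128
    sfreq: float = 512.0
    k_templates: int = 7
    corr_cap: float = 0.6
    snr: float = 2.0
    signal_gfp_uv: float = 5.0
    trials_per_condition: int = 72
    jitter_frac: float = 0.10
    rt_sigma: float = 0.13
    rt_subject_sigma: float = 0.05
    subject_timing_sigma: float = 0.20
    auditory_amplitude_uv: float = 3.0
    null_effect: bool = False


class PreprocessParams(_Params):
    apply_filter: bool = True
    band_low_hz: float = 0.2
    band_high_hz: float = 30.0
    filter_order: int = 2
    reject_uv: float = 100.0
    min_epochs: int = 31
    trim_overlap: bool = True
    stim_window_end_ms: float = STIM_WINDOW_MS[1]


class WaveformStatsParams(_Params):
    alpha: float = 0.01
    min_elec: int = 5
    min_ms: float = 20.0
    correction: str | None = None
    pairwise: bool = True


class CrossvalParams(_Params):
    k_min: int = 1
    k_max: int = 20
    n_splits: int = 50
    train_n: int = 8
    test_n: int = 8
    n_init: int = 10
    polarity: str = "sensitive"
    smooth: bool = True
    smooth_window: int = 10
    smooth_penalty: float = 3.0


class SegmentParams(_Params):
    # None -> take the cross-validated selection (stimulus-aligned CV)
    k_stimulus: int | None = None
    k_response: int | None = None
    n_init: int = 50
    polarity: str = "sensitive"


class FitParams(_Params):
    fit_window_start_ms: float | None = 190.0  # stimulus-aligned fits
    smooth: bool = True
    smooth_window: int = 10
    smooth_penalty: float = 3.0


class RandtestParams(_Params):
    n_perm: int = 5000
    statistics: tuple[str, ...] = ("duration", "offset")
    suppress_last_map: bool = True
    pairwise: bool = True


class RunConfig(_Params):
    seed: int = 0
    simulate: SimulateParams = SimulateParams()
    preprocess: PreprocessParams = PreprocessParams()
    waveform_stats: WaveformStatsParams = WaveformStatsParams()
    crossval: CrossvalParams = CrossvalParams()
    segment: SegmentParams = SegmentParams()
    fit: FitParams = FitParams()
    randtest: RandtestParams = RandtestParams()

    @model_validator(mode="after")
    def _check_split_sizes(self):
        if self.crossval.train_n + self.crossval.test_n > self.simulate.n_subjects:
            raise ValueError(
                "crossval train_n+test_n exceeds the number of subjects"
            )
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)


ALL_STAGES = (
    "simulate", "preprocess", "waveform-stats", "crossval",
    "segment", "fit", "randtest", "report",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage_seed(config: RunConfig, stage: str) -> int:
    # distinct, reproducible per-stage seeds below 2**31
    return int(
        np.random.SeedSequence([config.seed, ALL_STAGES.index(stage)]).generate_state(1)[0]
        % (2**31 - 1)
    )


def _simulation_config(config: RunConfig) -> sim.SimulationConfig:
    p = config.simulate
    aud = (
        sim.AuditoryComponent(amplitude_uv=p.auditory_amplitude_uv)
        if p.auditory_amplitude_uv > 0
        else None
    )
    cfg = sim.SimulationConfig(
        n_subjects=p.n_subjects,
        tasks=p.tasks,
        distractor=p.distractor,
        n_electrodes=p.n_electrodes,
        sfreq=p.sfreq,
        k_templates=p.k_templates,
        corr_cap=p.corr_cap,
        snr=p.snr,
        signal_gfp_uv=p.signal_gfp_uv,
        trials_per_condition=p.trials_per_condition,
        jitter_frac=p.jitter_frac,
        rt_sigma=p.rt_sigma,
        rt_subject_sigma=p.rt_subject_sigma,
        subject_timing_sigma=p.subject_timing_sigma,
        auditory=aud,
        seed=_stage_seed(config, "simulate"),
    )
    if p.null_effect:
        cfg = sim.null_schedules(cfg)
    return cfg


def stage_simulate(config: RunConfig, workdir: Path) -> None:
    cfg = _simulation_config(config)
    ds = sim.simulate_dataset(cfg)
    eio.save_epochs(workdir / "epochs.h5", ds.epochs, mode="w")
    eio.write_trial_log(workdir / "trials.csv", ds.logs)
    from .montage import write_montage

    write_montage(workdir / "montage.txt", ds.montage)
    # ground truth sidecar: written for recovery checks, never read by stages
    np.savez(
        workdir / "ground_truth.npz",
        template_maps=ds.truth.templates.maps,
        stim_labels=np.stack([ds.truth.stim_labels[t] for t in cfg.tasks]),
        resp_labels=np.stack([ds.truth.resp_labels[t] for t in cfg.tasks]),
        tasks=np.array(cfg.tasks),
        durations=json.dumps(
            {f"{t}|{a}|{m}": v for (t, a, m), v in ds.truth.durations_ms.items()}
        ),
    )


def stage_preprocess(config: RunConfig, workdir: Path) -> None:
    p = config.preprocess
    epochs = eio.load_epochs(workdir / "epochs.h5")
    by_key = {(e.subject, e.condition, e.alignment): e for e in epochs}
    erps = []
    for (subject, condition, alignment), ep in sorted(by_key.items()):
        if alignment != "stimulus":
            continue
        resp = by_key.get((subject, condition, "response"))
        if resp is None:
            raise ValueError(f"missing response epochs for {subject}/{condition}")
        pair = []
        for e in (ep, resp):
            data = e.data
            if p.apply_filter:
                data = pp.bandpass(
                    data, e.sfreq, p.band_low_hz, p.band_high_hz, p.filter_order
                )
            data = pp.rereference_average(data)
            e = type(e)(
                subject=e.subject, condition=e.condition, alignment=e.alignment,
                sfreq=e.sfreq, data=data, times=e.times,
                latencies=e.latencies, mask=e.mask,
            )
            pair.append(pp.reject_artifacts(e, p.reject_uv))
        stim_e, resp_e = pp.harmonize_masks(*pair)
        erps.append(pp.average_epochs(stim_e, p.min_epochs))
        erps.append(pp.average_epochs(resp_e, p.min_epochs))
    eio.save_subject_erps(workdir / "derived.h5", erps, mode="w")

    gas: list[GrandAverage] = []
    conditions = sorted({e.condition for e in erps})
    for condition in conditions:
        for alignment in ("stimulus", "response"):
            group = [
                e for e in erps
                if e.condition == condition and e.alignment == alignment
            ]
            ga = pp.grand_average(group)
            if alignment == "response" and p.trim_overlap:
                ga = pp.trim_overlap(ga, p.stim_window_end_ms)
            gas.append(ga)
    eio.save_grand_averages(workdir / "derived.h5", gas)
    rt_rows = [
        {"condition": c, "mean_rt_ms": g.mean_rt_ms, "n_subjects": g.n_subjects}
        for c in conditions
        for g in gas
        if g.condition == c and g.alignment == "stimulus"
    ]
    pd.DataFrame(rt_rows).to_csv(workdir / "mean_rt.csv", index=False)


def stage_waveform_stats(config: RunConfig, workdir: Path) -> None:
    p = config.waveform_stats
    from .montage import read_montage

    montage = read_montage(workdir / "montage.txt")
    from .montage import build_adjacency

    montage = build_adjacency(montage)
    erps = eio.load_subject_erps(workdir / "derived.h5")
    conditions = sorted({e.condition for e in erps})
    frames = []
    for alignment in ("stimulus", "response"):
        sub = [e for e in erps if e.alignment == alignment]
        stat = mu.pointwise_anova(sub, conditions, correction=p.correction)
        clusters = mu.spatiotemporal_filter(
            stat, montage, p.alpha, p.min_elec, p.min_ms
        )
        df = clusters.to_frame(montage.labels)
        df.insert(0, "contrast", "x".join(conditions))
        df.insert(0, "alignment", alignment)
        frames.append(df)
        if p.pairwise:
            for i in range(len(conditions)):
                for jj in range(i + 1, len(conditions)):
                    pair = (conditions[i], conditions[jj])
                    pstat = mu.planned_pairwise(sub, pair)
                    pcl = mu.spatiotemporal_filter(
                        pstat, montage, p.alpha, p.min_elec, p.min_ms
                    )
                    df = pcl.to_frame(montage.labels)
                    df.insert(0, "contrast", f"{pair[0]}-{pair[1]}")
                    df.insert(0, "alignment", alignment)
                    frames.append(df)
    nonempty = [f for f in frames if len(f)] or frames[:1]
    pd.concat(nonempty, ignore_index=True).to_csv(
        workdir / "clusters.csv", index=False
    )


def stage_crossval(config: RunConfig, workdir: Path) -> None:
    p = config.crossval
    erps = [
        e for e in eio.load_subject_erps(workdir / "derived.h5")
        if e.alignment == "stimulus"
    ]
    res = ms.cross_validate_k(
        erps,
        k_range=range(p.k_min, p.k_max + 1),
        n_splits=p.n_splits,
        train_n=p.train_n,
        test_n=p.test_n,
        n_init=p.n_init,
        polarity=p.polarity,
        smooth=(
            {"window": p.smooth_window, "penalty": p.smooth_penalty}
            if p.smooth
            else None
        ),
        seed=_stage_seed(config, "crossval"),
    )
    res.to_frame().to_csv(workdir / "crossval.csv", index=False)
    (workdir / "crossval.json").write_text(
        json.dumps({"selected_k": res.selected_k, "seed": res.seed})
    )


def stage_segment(config: RunConfig, workdir: Path) -> None:
    p = config.segment
    gas = eio.load_grand_averages(workdir / "derived.h5")
    ks = {"stimulus": p.k_stimulus, "response": p.k_response}
    if any(v is None for v in ks.values()):
        cv_path = workdir / "crossval.json"
        if not cv_path.exists():
            raise ValueError("segment k is unset and no crossval result exists")
        selected = int(json.loads(cv_path.read_text())["selected_k"])
        ks = {a: (v if v is not None else selected) for a, v in ks.items()}
    seed = _stage_seed(config, "segment")
    out = {}
    for alignment in ("stimulus", "response"):
        group = sorted(
            (g for g in gas if g.alignment == alignment), key=lambda g: g.condition
        )
        templates, gev = ms.kmeans_segment(
            group, ks[alignment], n_init=p.n_init, seed=seed, polarity=p.polarity
        )
        out[f"{alignment}_maps"] = templates.maps
        out[f"{alignment}_gev"] = gev
        out[f"{alignment}_ids"] = np.array(templates.ids)
        out[f"{alignment}_polarity"] = templates.polarity
    np.savez(workdir / "templates.npz", **out)


def _load_templates(workdir: Path, alignment: str) -> ms.MicrostateTemplates:
    z = np.load(workdir / "templates.npz")
    return ms.MicrostateTemplates(
        maps=z[f"{alignment}_maps"],
        ids=[str(s) for s in z[f"{alignment}_ids"]],
        provenance=f"pipeline segment stage ({alignment})",
        polarity=str(z[f"{alignment}_polarity"]),
    )


def stage_fit(config: RunConfig, workdir: Path) -> None:
    p = config.fit
    gas = eio.load_grand_averages(workdir / "derived.h5")
    smooth = (
        {"window": p.smooth_window, "penalty": p.smooth_penalty} if p.smooth else None
    )
    tables = []
    for alignment in ("stimulus", "response"):
        templates = _load_templates(workdir, alignment)
        window = None
        if alignment == "stimulus" and p.fit_window_start_ms is not None:
            window = (p.fit_window_start_ms, float("inf"))
        for ga in sorted(
            (g for g in gas if g.alignment == alignment), key=lambda g: g.condition
        ):
            _, stats = ms.fit_templates(templates, ga, window, smooth)
            stats.insert(0, "alignment", alignment)
            tables.append(stats)
    pd.concat(tables, ignore_index=True).to_csv(
        workdir / "map_stats.csv", index=False
    )


def stage_randtest(config: RunConfig, workdir: Path) -> None:
    p = config.randtest
    fitp = config.fit
    erps = eio.load_subject_erps(workdir / "derived.h5")
    conditions = sorted({e.condition for e in erps})
    smooth = (
        {"window": fitp.smooth_window, "penalty": fitp.smooth_penalty}
        if fitp.smooth
        else None
    )
    seed0 = _stage_seed(config, "randtest")
    rows = []
    for alignment in ("stimulus", "response"):
        templates = _load_templates(workdir, alignment)
        sub = [e for e in erps if e.alignment == alignment]
        window = None
        if alignment == "stimulus" and fitp.fit_window_start_ms is not None:
            window = (fitp.fit_window_start_ms, float("inf"))
        map_ids = templates.ids[:-1] if p.suppress_last_map else templates.ids
        contrasts: list[list[str]] = [list(conditions)] if len(conditions) > 2 else []
        if p.pairwise or len(conditions) == 2:
            contrasts += [
                [conditions[i], conditions[jj]]
                for i in range(len(conditions))
                for jj in range(i + 1, len(conditions))
            ]
        for m_i, map_id in enumerate(map_ids):
            for statistic in p.statistics:
                for c_i, contrast in enumerate(contrasts):
                    res = ms.randomization_test(
                        sub, templates, statistic, map_id, contrast,
                        n_perm=p.n_perm,
                        seed=seed0 + 1000 * m_i + 10 * c_i + len(statistic),
                        fit_window_ms=window,
                        smooth=smooth,
                    )
                    rows.append(
                        {
                            "alignment": alignment,
                            "map": map_id,
                            "statistic": statistic,
                            "contrast": res.contrast,
                            "observed": res.observed,
                            "p_value": res.p_value,
                            "n_perm": res.n_perm,
                            "valid": res.valid,
                        }
                    )
    pd.DataFrame(rows).to_csv(workdir / "randtest.csv", index=False)


def stage_report(config: RunConfig, workdir: Path) -> str:
    sections = []
    rt = pd.read_csv(workdir / "mean_rt.csv")
    sections.append("== Mean production latency per condition ==\n" + rt.to_string(index=False))
    clusters = pd.read_csv(workdir / "clusters.csv")
    sections.append(
        "== Waveform clusters (alpha, extent-filtered) ==\n"
        + (clusters.to_string(index=False) if len(clusters) else "(none)")
    )
    cv = json.loads((workdir / "crossval.json").read_text())
    sections.append(f"== Cross-validated number of maps ==\nselected_k = {cv['selected_k']}")
    stats = pd.read_csv(workdir / "map_stats.csv")
    sections.append("== Map statistics per condition ==\n" + stats.to_string(index=False))
    rnd = pd.read_csv(workdir / "randtest.csv")
    sections.append("== Randomization tests ==\n" + rnd.to_string(index=False))
    report = "\n\n".join(sections) + "\n"
    (workdir / "report.txt").write_text(report)
    return report


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "waveform-stats": stage_waveform_stats,
    "crossval": stage_crossval,
    "segment": stage_segment,
    "fit": stage_fit,
    "randtest": stage_randtest,
    "report": stage_report,
}


def run_pipeline(
    config: RunConfig, workdir, stages: tuple[str, ...] = ALL_STAGES
) -> str | None:
    """Execute the requested stages in order; returns the report text if the
    ``report`` stage ran.  A stage failure halts the run with a
    :class:`StageError` naming the stage."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in _STAGE_FUNCS]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    report = None
    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        try:
            result = _STAGE_FUNCS[stage](config, workdir)
        except Exception as exc:  # noqa: BLE001 - re-tagged with the stage name
            raise StageError(stage, exc) from exc
        if stage == "report":
            report = result
    return report
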