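"""File formats: BDF/EDF recordings, trial logs, and the epoch container.

Raw recordings are read with :mod:`mne` (BioSemi BDF and EDF).  A minimal
24-bit BDF *writer* is included so synthetic recordings can round-trip
through the same on-disk format as real acquisitions; physical units are
converted to microvolts on read, and all downstream code works in μV/ms.

Epochs, subject averages and grand averages are stored in a single-file
hierarchical HDF5 container with explicit time-axis metadata, since no
standard exchange format covers response-locked epochs.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .containers import EpochSet, GrandAverage, Recording, SubjectERP, TrialLog
from .montage import Montage, read_montage

_BDF_DIG_MAX = 8388607  # 2^23 - 1
_BDF_DIG_MIN = -8388608


class LabelMismatchError(ValueError):
    """Recording channels and coordinate file disagree."""


def write_bdf(path, recording: Recording, phys_range_uv: float | None = None) -> None:
    """Write a continuous recording as a 24-bit BioSemi BDF file.

    Samples are quantized to the 24-bit digital range mapped onto
    ``[-phys_range_uv, +phys_range_uv]``; the default range is the smallest
    power of ten covering the data, which keeps quantization error far below
    EEG noise floors.
    """
    data = recording.data
    sfreq = recording.sfreq
    n_chan, n_samp = data.shape
    if phys_range_uv is None:
        peak = float(np.max(np.abs(data))) if data.size else 1.0
        phys_range_uv = 10.0 ** math.ceil(math.log10(max(peak, 1.0)))

    # one-second records; pad the tail with zeros
    spr = int(round(sfreq))
    if abs(sfreq - spr) > 1e-9:
        raise ValueError("BDF writer requires an integer sampling rate")
    n_rec = max(1, math.ceil(n_samp / spr))
    padded = np.zeros((n_chan, n_rec * spr))
    padded[:, :n_samp] = data

    scale = _BDF_DIG_MAX / phys_range_uv
    digital = np.clip(np.round(padded * scale), _BDF_DIG_MIN, _BDF_DIG_MAX).astype(
        np.int32
    )

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"header field too long: {text!r}")
        return b.ljust(width)

    now = _dt.datetime(2000, 1, 1)
    with open(path, "wb") as fh:
        fh.write(b"\xff" + b"BIOSEMI")
        fh.write(f("", 80))  # subject id
        fh.write(f("", 80))  # recording id
        fh.write(f(now.strftime("%d.%m.%y"), 8))
        fh.write(f(now.strftime("%H.%M.%S"), 8))
        fh.write(f(str((n_chan + 1) * 256), 8))
        fh.write(f("24BIT", 44))
        fh.write(f(str(n_rec), 8))
        fh.write(f("1", 8))  # record duration, seconds
        fh.write(f(str(n_chan), 4))
        for lab in recording.montage.labels:
            fh.write(f(lab, 16))
        for _ in range(n_chan):
            fh.write(f("Active Electrode", 80))
        for _ in range(n_chan):
            fh.write(f("uV", 8))
        for _ in range(n_chan):
            fh.write(f(str(-phys_range_uv), 8))
        for _ in range(n_chan):
            fh.write(f(str(phys_range_uv), 8))
        for _ in range(n_chan):
            fh.write(f(str(_BDF_DIG_MIN), 8))
        for _ in range(n_chan):
            fh.write(f(str(_BDF_DIG_MAX), 8))
        for _ in range(n_chan):
            fh.write(f("", 80))  # prefiltering
        for _ in range(n_chan):
            fh.write(f(str(spr), 8))
        for _ in range(n_chan):
            fh.write(f("", 32))
        # data: per record, per channel, 24-bit little-endian
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            as32 = block.astype("<i4").tobytes()
            arr = np.frombuffer(as32, dtype=np.uint8).reshape(-1, 4)
            fh.write(arr[:, :3].tobytes())


def read_raw(path, montage_path) -> Recording:
    """Read a BDF/EDF recording and attach the montage from a coordinate file.

    Returns channels x samples in μV.  The electrode labels in the recording
    must match the coordinate file (same names, same order); a mismatch
    raises :class:`LabelMismatchError`.
    """
    import mne

    montage = read_montage(montage_path)
    p = str(path)
    if p.lower().endswith(".bdf"):
        raw = mne.io.read_raw_bdf(p, preload=True, verbose="error")
    elif p.lower().endswith(".edf"):
        raw = mne.io.read_raw_edf(p, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported raw format: {path}")
    labels = list(raw.ch_names)
    if labels != montage.labels:
        raise LabelMismatchError(
            f"recording channels {labels} != coordinate labels {montage.labels}"
        )
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return Recording(data=data_uv, sfreq=float(raw.info["sfreq"]), montage=montage)


# ---------------------------------------------------------------------------
# trial logs

_LOG_COLUMNS = ["subject", "trial", "condition", "distractor", "rt_ms", "correct", "filler"]


@dataclass
class RejectedRow:
    row: int  # 1-based data row number in the file
    reason: str


def read_trial_log(path) -> tuple[list[TrialLog], list[RejectedRow]]:
    """Parse a CSV trial log into :class:`TrialLog` records.

    Rows violating the record invariants (e.g. a correct trial without a
    latency) are rejected and reported with their row numbers rather than
    aborting the whole file.  A missing column or a non-numeric latency is a
    hard error.
    """
    df = pd.read_csv(path, dtype={"rt_ms": str})
    missing = [c for c in _LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log {path} missing columns: {missing}")
    records: list[TrialLog] = []
    rejected: list[RejectedRow] = []
    for i, row in df.iterrows():
        rt_raw = row["rt_ms"]
        if pd.isna(rt_raw) or str(rt_raw).strip() == "":
            rt = None
        else:
            try:
                rt = float(rt_raw)
            except ValueError as exc:
                raise ValueError(
                    f"trial log {path} row {i + 1}: unparseable latency {rt_raw!r}"
                ) from exc
        try:
            records.append(
                TrialLog(
                    subject=str(row["subject"]),
                    trial=int(row["trial"]),
                    condition=str(row["condition"]),
                    distractor=str(row["distractor"]),
                    rt_ms=rt,
                    correct=bool(int(row["correct"])),
                    filler=bool(int(row["filler"])),
                )
            )
        except ValueError as exc:
            rejected.append(RejectedRow(row=i + 1, reason=str(exc)))
    return records, rejected


def write_trial_log(path, records: list[TrialLog]) -> None:
    rows = [
        {
            "subject": r.subject,
            "trial": r.trial,
            "condition": r.condition,
            "distractor": r.distractor,
            "rt_ms": "" if r.rt_ms is None else r.rt_ms,
            "correct": int(r.correct),
            "filler": int(r.filler),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_LOG_COLUMNS).to_csv(path, index=False)


def analyzable(records: list[TrialLog]) -> list[TrialLog]:
    """Correct, non-filler trials — the only ones that may enter averages."""
    return [r for r in records if r.correct and not r.filler]


# ---------------------------------------------------------------------------
# hierarchical epoch container (HDF5)


def _epoch_group(subject: str, condition: str, alignment: str) -> str:
    return f"epochs/{subject}/{condition}/{alignment}"


def save_epochs(path, epochsets: list[EpochSet], mode: str = "a") -> None:
    with h5py.File(path, mode) as fh:
        for ep in epochsets:
            name = _epoch_group(ep.subject, ep.condition, ep.alignment)
            if name in fh:
                del fh[name]
            g = fh.create_group(name)
            g.create_dataset("data", data=ep.data)
            g.create_dataset("times", data=ep.times)
            g.create_dataset("latencies", data=ep.latencies)
            g.create_dataset("mask", data=ep.mask)
            g.attrs["sfreq"] = ep.sfreq
            g.attrs["subject"] = ep.subject
            g.attrs["condition"] = ep.condition
            g.attrs["alignment"] = ep.alignment


def load_epochs(path) -> list[EpochSet]:
    out: list[EpochSet] = []
    with h5py.File(path, "r") as fh:
        if "epochs" not in fh:
            return out
        for subject in fh["epochs"]:
            for condition in fh[f"epochs/{subject}"]:
                for alignment in fh[f"epochs/{subject}/{condition}"]:
                    g = fh[_epoch_group(subject, condition, alignment)]
                    out.append(
                        EpochSet(
                            subject=str(g.attrs["subject"]),
                            condition=str(g.attrs["condition"]),
                            alignment=str(g.attrs["alignment"]),
                            sfreq=float(g.attrs["sfreq"]),
                            data=g["data"][()],
                            times=g["times"][()],
                            latencies=g["latencies"][()],
                            mask=g["mask"][()].astype(bool),
                        )
                    )
    return out


def save_subject_erps(path, erps: list[SubjectERP], mode: str = "a") -> None:
    with h5py.File(path, mode) as fh:
        for erp in erps:
            name = f"subject_erps/{erp.subject}/{erp.condition}/{erp.alignment}"
            if name in fh:
                del fh[name]
            g = fh.create_group(name)
            g.create_dataset("data", data=erp.data)
            g.create_dataset("times", data=erp.times)
            g.attrs["sfreq"] = erp.sfreq
            g.attrs["subject"] = erp.subject
            g.attrs["condition"] = erp.condition
            g.attrs["alignment"] = erp.alignment
            g.attrs["n_epochs"] = erp.n_epochs
            g.attrs["mean_rt_ms"] = np.nan if erp.mean_rt_ms is None else erp.mean_rt_ms


def load_subject_erps(path) -> list[SubjectERP]:
    out: list[SubjectERP] = []
    with h5py.File(path, "r") as fh:
        if "subject_erps" not in fh:
            return out
        for subject in fh["subject_erps"]:
            for condition in fh[f"subject_erps/{subject}"]:
                for alignment in fh[f"subject_erps/{subject}/{condition}"]:
                    g = fh[f"subject_erps/{subject}/{condition}/{alignment}"]
                    rt = float(g.attrs["mean_rt_ms"])
                    out.append(
                        SubjectERP(
                            subject=str(g.attrs["subject"]),
                            condition=str(g.attrs["condition"]),
                            alignment=str(g.attrs["alignment"]),
                            sfreq=float(g.attrs["sfreq"]),
                            data=g["data"][()],
                            times=g["times"][()],
                            n_epochs=int(g.attrs["n_epochs"]),
                            mean_rt_ms=None if np.isnan(rt) else rt,
                        )
                    )
    return out


def save_grand_averages(path, gas: list[GrandAverage], mode: str = "a") -> None:
    with h5py.File(path, mode) as fh:
        for ga in gas:
            name = f"grand_averages/{ga.condition}/{ga.alignment}"
            if name in fh:
                del fh[name]
            g = fh.create_group(name)
            g.create_dataset("data", data=ga.data)
            g.create_dataset("times", data=ga.times)
            g.attrs["sfreq"] = ga.sfreq
            g.attrs["condition"] = ga.condition
            g.attrs["alignment"] = ga.alignment
            g.attrs["subjects"] = [s.encode() for s in ga.subjects]
            g.attrs["mean_rt_ms"] = np.nan if ga.mean_rt_ms is None else ga.mean_rt_ms
            if ga.trimmed_span_ms is not None:
                g.attrs["trimmed_span_ms"] = list(ga.trimmed_span_ms)


def load_grand_averages(path) -> list[GrandAverage]:
    out: list[GrandAverage] = []
    with h5py.File(path, "r") as fh:
        if "grand_averages" not in fh:
            return out
        for condition in fh["grand_averages"]:
            for alignment in fh[f"grand_averages/{condition}"]:
                g = fh[f"grand_averages/{condition}/{alignment}"]
                rt = float(g.attrs["mean_rt_ms"])
                span = g.attrs.get("trimmed_span_ms")
                out.append(
                    GrandAverage(
                        condition=str(g.attrs["condition"]),
                        alignment=str(g.attrs["alignment"]),
                        sfreq=float(g.attrs["sfreq"]),
                        data=g["data"][()],
                        times=g["times"][()],
                        subjects=[
                            s.decode() if isinstance(s, bytes) else str(s)
                            for s in g.attrs["subjects"]
                        ],
                        mean_rt_ms=None if np.isnan(rt) else rt,
                        trimmed_span_ms=None if span is None else (span[0], span[1]),
                    )
                )
    return out
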