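"""Mass-univariate waveform statistics with a spatio-temporal cluster filter.

A one-way repeated-measures ANOVA (factor: task, three levels) is computed
on single-subject average amplitudes at every electrode and time point, and
planned pairwise contrasts use the paired t test.  Multiple comparisons are
handled by an extent criterion rather than p-value adjustment: only effects
covering at least ``min_elec`` montage-adjacent electrodes and extending at
least ``min_ms`` are retained, at a conservative alpha (default 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SubjectERP
from .montage import Montage

DEFAULT_ALPHA = 0.01
DEFAULT_MIN_ELEC = 5
DEFAULT_MIN_MS = 20.0


@dataclass
class StatMap:
    """Per-grid-point test statistics on the electrodes x samples grid."""

    stat: np.ndarray  # electrodes x samples: F (anova) or t (pairwise)
    p: np.ndarray
    kind: str  # "rm_anova" | "paired_t"
    df: tuple[float, float] | float
    factor: str
    times: np.ndarray  # ms
    sfreq: float

    def __post_init__(self) -> None:
        if self.stat.shape != self.p.shape:
            raise ValueError("stat and p arrays must share shape")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p-values outside [0, 1]")


@dataclass
class Cluster:
    points: set[tuple[int, int]]  # (electrode index, sample index)
    electrodes: set[int]
    max_extent: int  # max simultaneous electrode count
    t_start_ms: float
    t_end_ms: float
    duration_ms: float
    min_p: float


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    alpha: float
    min_elec: int
    min_ms: float

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self, labels: list[str] | None = None) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            elec = sorted(c.electrodes)
            rows.append(
                {
                    "electrodes": ";".join(
                        labels[e] if labels else str(e) for e in elec
                    ),
                    "n_electrodes": len(elec),
                    "max_extent": c.max_extent,
                    "t_start_ms": c.t_start_ms,
                    "t_end_ms": c.t_end_ms,
                    "duration_ms": c.duration_ms,
                    "min_p": c.min_p,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "electrodes", "n_electrodes", "max_extent",
                "t_start_ms", "t_end_ms", "duration_ms", "min_p",
            ],
        )


def _stack(erps: list[SubjectERP], conditions: list[str]) -> tuple[np.ndarray, np.ndarray, float]:
    """Arrange subject ERPs as (subjects, conditions, electrodes, samples).

    Subjects missing any requested condition are excluded (with all their
    data) so the design stays fully crossed.
    """
    by_subj: dict[str, dict[str, SubjectERP]] = {}
    for e in erps:
        by_subj.setdefault(e.subject, {})[e.condition] = e
    complete = [s for s, d in by_subj.items() if all(c in d for c in conditions)]
    dropped = sorted(set(by_subj) - set(complete))
    if dropped:
        import logging

        logging.getLogger(__name__).warning(
            "excluding subjects with missing cells: %s", dropped
        )
    if len(complete) < 2:
        raise ValueError("need at least 2 subjects with complete designs")
    ref = by_subj[complete[0]][conditions[0]]
    Y = np.stack(
        [np.stack([by_subj[s][c].data for c in conditions]) for s in complete]
    )
    return Y, ref.times, ref.sfreq


def pointwise_anova(
    erps: list[SubjectERP],
    conditions: list[str],
    correction: str | None = None,
) -> StatMap:
    """One-way repeated-measures F at every electrode and time point.

    ``correction="gg"`` applies the Greenhouse–Geisser sphericity correction
    to the degrees of freedom (off by default).  Grid points with no
    variance at all (all cells identical across subjects) report F = 0,
    p = 1.
    """
    Y, times, sfreq = _stack(erps, conditions)  # n x k x E x S
    n, k = Y.shape[0], Y.shape[1]
    if n < 3:
        raise ValueError("repeated-measures ANOVA needs at least 3 subjects")
    grand = Y.mean(axis=(0, 1))
    cond_m = Y.mean(axis=0)  # k x E x S
    subj_m = Y.mean(axis=1)  # n x E x S
    ss_cond = n * ((cond_m - grand) ** 2).sum(axis=0)
    ss_subj = k * ((subj_m - grand) ** 2).sum(axis=0)
    ss_tot = ((Y - grand) ** 2).sum(axis=(0, 1))
    ss_err = np.maximum(ss_tot - ss_cond - ss_subj, 0.0)
    df1, df2 = float(k - 1), float((k - 1) * (n - 1))
    # relative tolerance for "no variance" cells to absorb roundoff
    tol = 1e-10 * np.maximum(ss_tot, np.finfo(float).tiny)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_cond / df1) / (ss_err / df2)
    F = np.where(ss_err < tol, np.where(ss_cond < tol, 0.0, np.inf), F)

    eps = np.ones_like(F)
    if correction == "gg":
        eps = _gg_epsilon(Y)
    elif correction is not None:
        raise ValueError(f"unknown sphericity correction {correction!r}")
    p = stats.f.sf(F, df1 * eps, df2 * eps)
    p = np.where(F == 0.0, 1.0, p)
    return StatMap(
        stat=F, p=p, kind="rm_anova", df=(df1, df2),
        factor="x".join(conditions), times=times, sfreq=sfreq,
    )


def _gg_epsilon(Y: np.ndarray) -> np.ndarray:
    """Greenhouse–Geisser epsilon per grid point for an n x k x E x S stack."""
    n, k = Y.shape[0], Y.shape[1]
    Yc = Y - Y.mean(axis=0, keepdims=True)  # center over subjects
    # covariance matrices of the k conditions at each grid point
    S = np.einsum("niES,njES->ijES", Yc, Yc) / (n - 1)
    mean_diag = np.einsum("iiES->ES", S) / k
    mean_all = S.mean(axis=(0, 1))
    row_means = S.mean(axis=1)  # k x E x S
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (
        (S**2).sum(axis=(0, 1))
        - 2 * k * (row_means**2).sum(axis=0)
        + k**2 * mean_all**2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        eps = num / den
    eps = np.where(np.isfinite(eps), eps, 1.0)
    return np.clip(eps, 1.0 / (k - 1), 1.0)


def planned_pairwise(erps: list[SubjectERP], pair: tuple[str, str]) -> StatMap:
    """Two-sided paired t test per grid point for one condition pair.

    A grid point with zero difference everywhere (e.g. a condition compared
    with itself) reports t = 0, p = 1.
    """
    Y, times, sfreq = _stack(erps, list(pair))
    n = Y.shape[0]
    d = Y[:, 0] - Y[:, 1]  # n x E x S
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where((sd == 0) & (mean == 0), 0.0, t)
        t = np.where(np.isfinite(t), t, np.inf * np.sign(mean))
    df = float(n - 1)
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(t == 0.0, 1.0, p)
    return StatMap(
        stat=t, p=p, kind="paired_t", df=df,
        factor=f"{pair[0]}-{pair[1]}", times=times, sfreq=sfreq,
    )


def spatiotemporal_filter(
    statmap: StatMap,
    montage: Montage,
    alpha: float = DEFAULT_ALPHA,
    min_elec: int = DEFAULT_MIN_ELEC,
    min_ms: float = DEFAULT_MIN_MS,
) -> ClusterSet:
    """Retain connected suprathreshold regions meeting both extent criteria.

    Grid points with ``p <= alpha`` are joined into connected components:
    two points are linked if they share a sample and their electrodes are
    montage-adjacent, or share an electrode at consecutive samples.  A
    component survives if its maximal simultaneous electrode extent is at
    least ``min_elec`` AND its time span is at least ``min_ms``.
    """
    if montage.adjacency is None:
        raise ValueError("montage adjacency required; call build_adjacency")
    n_e, n_s = statmap.p.shape
    if min_elec > n_e:
        raise ValueError(f"min_elec={min_elec} exceeds electrode count {n_e}")
    supra = statmap.p <= alpha
    adj = montage.adjacency
    dt = 1000.0 / statmap.sfreq

    comp = -np.ones((n_e, n_s), dtype=int)
    n_comp = 0
    for e0 in range(n_e):
        for s0 in range(n_s):
            if not supra[e0, s0] or comp[e0, s0] >= 0:
                continue
            stack = [(e0, s0)]
            comp[e0, s0] = n_comp
            while stack:
                e, s = stack.pop()
                for e2 in np.flatnonzero(adj[e]):
                    if supra[e2, s] and comp[e2, s] < 0:
                        comp[e2, s] = n_comp
                        stack.append((e2, s))
                for s2 in (s - 1, s + 1):
                    if 0 <= s2 < n_s and supra[e, s2] and comp[e, s2] < 0:
                        comp[e, s2] = n_comp
                        stack.append((e, s2))
            n_comp += 1

    clusters: list[Cluster] = []
    for c in range(n_comp):
        es, ss = np.nonzero(comp == c)
        extent = int(np.bincount(ss).max())  # max electrodes at one sample
        s_min, s_max = int(ss.min()), int(ss.max())
        duration = (s_max - s_min + 1) * dt
        if extent < min_elec or duration < min_ms:
            continue
        clusters.append(
            Cluster(
                points=set(zip(es.tolist(), ss.tolist())),
                electrodes=set(es.tolist()),
                max_extent=extent,
                t_start_ms=float(statmap.times[s_min]),
                t_end_ms=float(statmap.times[s_max]),
                duration_ms=float(duration),
                min_p=float(statmap.p[es, ss].min()),
            )
        )
    clusters.sort(key=lambda c: (c.t_start_ms, -c.max_extent))
    return ClusterSet(clusters=clusters, alpha=alpha, min_elec=min_elec, min_ms=min_ms)
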