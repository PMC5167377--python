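"""Topographic microstate analysis of grand-average ERPs.

ERP data are modeled as a sequence of a small number of quasi-stable scalp
topographies ("microstate maps").  The module provides:

* modified k-means segmentation of one or several grand averages into k
  template maps, scored by global explained variance (GEV);
* penalized label smoothing that removes temporally isolated, weakly
  fitting labels;
* cross-validated selection of k by repeatedly splitting subjects into
  training and test halves;
* template fitting (per-sample best-correlation labeling) yielding map
  duration, onset and offset per condition;
* randomization inference on those map statistics by shuffling condition
  labels within subjects;
* correlation/matching of two template sets (e.g. stimulus- vs
  response-aligned maps).

Polarity: event-related (polarity-sensitive) comparison is the default, so
a map and its sign-flip are distinct states; ``polarity="ignore"`` switches
to absolute spatial correlation as used for spontaneous EEG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GrandAverage, SubjectERP

DEFAULT_N_INIT = 50
DEFAULT_SMOOTH_WINDOW = 10
DEFAULT_SMOOTH_PENALTY = 3.0
DEFAULT_N_SPLITS = 50
DEFAULT_TRAIN_N = 8
DEFAULT_TEST_N = 8
DEFAULT_K_RANGE = range(1, 21)
DEFAULT_N_PERM = 5000


# ---------------------------------------------------------------------------
# topography arithmetic


def gfp(data: np.ndarray) -> np.ndarray:
    """Global field power: spatial standard deviation per time point.

    ``data`` is electrodes x samples (or a single topography vector).
    """
    data = np.asarray(data, dtype=float)
    return data.std(axis=0)


def _zero_mean(data: np.ndarray) -> np.ndarray:
    return data - data.mean(axis=0, keepdims=True)


def normalize_map(v: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-GFP version of a topography."""
    v = _zero_mean(np.asarray(v, dtype=float))
    g = v.std(axis=0)
    if np.any(g == 0):
        raise ValueError("cannot normalize a zero-variance topography")
    return v / g


def spatial_correlation(a: np.ndarray, b: np.ndarray, polarity: str = "sensitive") -> float:
    """Pearson correlation of two topographies across electrodes.

    ``polarity="ignore"`` returns the absolute value, treating a map and
    its inversion as the same state.
    """
    a = _zero_mean(np.asarray(a, dtype=float))
    b = _zero_mean(np.asarray(b, dtype=float))
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("spatial correlation undefined for a zero-variance map")
    r = float(a @ b / (na * nb))
    if polarity == "ignore":
        return abs(r)
    if polarity != "sensitive":
        raise ValueError(f"unknown polarity mode {polarity!r}")
    return r


def _corr_templates_data(maps: np.ndarray, data: np.ndarray) -> np.ndarray:
    """k x T matrix of spatial correlations (polarity-sensitive).

    ``maps`` is k x electrodes, ``data`` electrodes x T.  Zero-variance
    data columns yield correlation 0 with every template.
    """
    W = _zero_mean(maps.T).T  # k x E, zero-mean rows
    W = W / np.linalg.norm(W, axis=1, keepdims=True)
    V = _zero_mean(data)
    norms = np.linalg.norm(V, axis=0)
    safe = np.where(norms == 0, 1.0, norms)
    return (W @ V) / safe * (norms > 0)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class MicrostateTemplates:
    """k normalized template topographies with provenance."""

    maps: np.ndarray  # k x electrodes, zero-mean unit-GFP rows
    ids: list[str]
    provenance: str = ""
    polarity: str = "sensitive"

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2 or self.maps.shape[0] < 1:
            raise ValueError("maps must be k x electrodes with k >= 1")
        if len(self.ids) != self.maps.shape[0]:
            raise ValueError("one id per map required")
        mean = np.abs(self.maps.mean(axis=1)).max()
        g = self.maps.std(axis=1)
        if mean > 1e-8 or np.any(np.abs(g - 1) > 1e-6):
            raise ValueError("template maps must be zero-mean with unit GFP")

    @property
    def k(self) -> int:
        return self.maps.shape[0]


@dataclass
class SegmentationLabels:
    """Per-sample map assignment for one condition."""

    condition: str
    times: np.ndarray  # ms, the fitted samples
    labels: np.ndarray  # indices into the template set; -1 = unassigned
    sfreq: float
    smoothing: dict | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.times.shape != self.labels.shape:
            raise ValueError("times and labels must align")


@dataclass
class CrossValidationResult:
    k_values: list[int]
    mean_test_corr: np.ndarray  # per k, averaged over splits; drives selection
    mean_test_maxcorr: np.ndarray  # diagnostic: best-match corr per test sample
    selected_k: int
    splits: list[dict]  # train/test subject ids per split
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "mean_test_corr": self.mean_test_corr,
                "mean_test_maxcorr": self.mean_test_maxcorr,
            }
        )


@dataclass
class RandomizationResult:
    contrast: str
    statistic: str
    map_id: str
    observed: float
    per_condition: dict[str, float]
    n_perm: int
    n_valid: int
    null_mean: float
    null_sd: float
    p_value: float
    seed: int | None
    valid: bool = True
    warning: str | None = None


# ---------------------------------------------------------------------------
# segmentation (modified k-means)


def _concat_gas(gas: list[GrandAverage]) -> tuple[np.ndarray, list[tuple[str, slice]]]:
    data = np.concatenate([g.data for g in gas], axis=1)
    spans, start = [], 0
    for g in gas:
        spans.append((g.condition, slice(start, start + g.data.shape[1])))
        start += g.data.shape[1]
    return data, spans


def kmeans_segment(
    gas: GrandAverage | list[GrandAverage],
    k: int,
    n_init: int = DEFAULT_N_INIT,
    seed: int | None = None,
    polarity: str = "sensitive",
    max_iter: int = 200,
) -> tuple[MicrostateTemplates, float]:
    """Modified k-means segmentation maximizing global explained variance.

    All condition grand averages are segmented jointly (shared template
    set).  Each restart seeds the templates from k random time points and
    alternates best-correlation labeling with template re-estimation; the
    restart with the highest GEV wins.  Deterministic given ``seed``.

    GEV = sum_t (GFP_t * r_t)^2 / sum_t GFP_t^2, with r the spatial
    correlation between sample t and its assigned template.
    """
    if isinstance(gas, GrandAverage):
        gas = [gas]
    X, _ = _concat_gas(gas)
    X = _zero_mean(X)
    T = X.shape[1]
    if not 1 <= k <= T:
        raise ValueError(f"k={k} outside 1..{T} (number of time points)")
    norms = np.linalg.norm(X, axis=0)
    if np.count_nonzero(norms > 0) < k:
        raise ValueError("k exceeds the number of non-degenerate topographies")
    rng = np.random.default_rng(seed)
    g = gfp(X)
    denom = float((g**2).sum())
    valid_t = np.flatnonzero(norms > 0)

    best_gev, best_maps = -1.0, None
    for _ in range(n_init):
        maps = X[:, rng.choice(valid_t, size=k, replace=False)].T
        maps = maps / np.linalg.norm(maps, axis=1, keepdims=True)
        labels = None
        for _ in range(max_iter):
            R = _corr_templates_data(maps, X)
            new_labels = np.argmax(np.abs(R) if polarity == "ignore" else R, axis=0)
            if labels is not None and np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(k):
                members = labels == j
                if not members.any():
                    # re-seed an empty cluster from the worst-fit sample
                    fit = np.abs(R) if polarity == "ignore" else R
                    worst = valid_t[np.argmin(fit.max(axis=0)[valid_t])]
                    maps[j] = X[:, worst] / np.linalg.norm(X[:, worst])
                    continue
                Vj = X[:, members]
                if polarity == "ignore":
                    # principal spatial component of the member topographies
                    M = Vj @ Vj.T
                    vals, vecs = np.linalg.eigh(M)
                    w = vecs[:, -1]
                else:
                    w = Vj.sum(axis=1)
                n = np.linalg.norm(w)
                if n > 0:
                    maps[j] = w / n
        R = _corr_templates_data(maps, X)
        fit = np.abs(R) if polarity == "ignore" else R
        labels = np.argmax(fit, axis=0)
        r_win = R[labels, np.arange(T)]
        if polarity == "ignore":
            r_win = np.abs(r_win)
        gev = float(((g * r_win) ** 2).sum() / denom) if denom > 0 else 0.0
        if gev > best_gev:
            best_gev, best_maps = gev, maps.copy()

    # normalize to zero-mean unit-GFP and order by first appearance
    R = _corr_templates_data(best_maps, X)
    fit = np.abs(R) if polarity == "ignore" else R
    labels = np.argmax(fit, axis=0)
    first = [
        int(np.flatnonzero(labels == j)[0]) if (labels == j).any() else T + j
        for j in range(k)
    ]
    order = np.argsort(first, kind="stable")
    maps = best_maps[order]
    maps = _zero_mean(maps.T).T
    maps = maps / maps.std(axis=1, keepdims=True)
    templates = MicrostateTemplates(
        maps=maps,
        ids=[str(i + 1) for i in range(k)],
        provenance="kmeans on " + "+".join(
            f"{ga.condition}/{ga.alignment}" for ga in gas
        ),
        polarity=polarity,
    )
    return templates, best_gev


def gev_of_labeling(
    data: np.ndarray, templates: MicrostateTemplates, labels: np.ndarray
) -> float:
    """GEV of a given labeling of ``data`` (electrodes x T); -1 = unassigned."""
    X = _zero_mean(np.asarray(data, dtype=float))
    g = gfp(X)
    R = _corr_templates_data(templates.maps, X)
    idx = np.arange(X.shape[1])
    assigned = labels >= 0
    r = np.zeros(X.shape[1])
    r[assigned] = R[labels[assigned], idx[assigned]]
    if templates.polarity == "ignore":
        r = np.abs(r)
    denom = float((g**2).sum())
    return float(((g * r) ** 2)[assigned].sum() / denom) if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# label smoothing


def _smooth_scores(
    fit: np.ndarray, labels: np.ndarray, window: int, penalty: float
) -> np.ndarray:
    k, T = fit.shape
    half = max(1, window // 2)
    counts = np.zeros((k, T))
    onehot = np.zeros((k, T))
    valid = labels >= 0
    onehot[labels[valid], np.flatnonzero(valid)] = 1.0
    kernel = np.ones(2 * half + 1)
    kernel[half] = 0.0  # exclude the sample itself
    for j in range(k):
        counts[j] = np.convolve(onehot[j], kernel, mode="same")
    return fit + penalty * counts


def smooth_labels(
    labels: np.ndarray,
    data: np.ndarray,
    templates: MicrostateTemplates,
    window: int = DEFAULT_SMOOTH_WINDOW,
    penalty: float = DEFAULT_SMOOTH_PENALTY,
    max_iter: int = 100,
) -> np.ndarray:
    """Penalized relabeling that absorbs temporally isolated labels.

    Each sample's assignment score is its spatial correlation with a
    template plus ``penalty`` times the count of same-labeled samples
    within a ±window/2 neighborhood; samples are synchronously relabeled
    to the best-scoring template until a fixed point (ties keep the
    incumbent label).  ``penalty=0`` leaves a best-correlation labeling
    untouched.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    labels = np.asarray(labels, dtype=int).copy()
    X = _zero_mean(np.asarray(data, dtype=float))
    R = _corr_templates_data(templates.maps, X)
    fit = np.abs(R) if templates.polarity == "ignore" else R
    for _ in range(max_iter):
        score = _smooth_scores(fit, labels, window, penalty)
        best = np.argmax(score, axis=0)
        # ties keep the incumbent
        assigned = labels >= 0
        keep = np.zeros_like(assigned)
        keep[assigned] = (
            score[labels[assigned], np.flatnonzero(assigned)]
            >= score[best[assigned], np.flatnonzero(assigned)]
        )
        new = np.where(keep, labels, best)
        new[~assigned] = -1  # never label samples outside the fit window
        if np.array_equal(new, labels):
            break
        labels = new
    return labels


# ---------------------------------------------------------------------------
# template fitting and map statistics


def fit_templates(
    templates: MicrostateTemplates,
    ga: GrandAverage,
    fit_window_ms: tuple[float, float] | None = None,
    smooth: dict | None = None,
) -> tuple[SegmentationLabels, pd.DataFrame]:
    """Label every sample of a grand average with its best-correlating map.

    Returns the labeling and a per-map statistics table with duration
    (total labeled time, possibly over discontiguous runs), onset (start of
    the first labeled sample), offset (end of the last labeled sample),
    mean spatial correlation and GEV share.  Maps never winning a sample
    have duration 0 and undefined onset/offset (``expressed=False``).

    ``smooth`` may carry ``{"window": int, "penalty": float}`` to apply
    penalized smoothing after the initial argmax labeling.
    """
    times = ga.times
    if fit_window_ms is not None:
        sel = (times >= fit_window_ms[0]) & (times <= fit_window_ms[1])
        if not sel.any():
            raise ValueError(f"empty fit window {fit_window_ms}")
    else:
        sel = np.ones_like(times, dtype=bool)
    data = ga.data[:, sel]
    X = _zero_mean(data)
    R = _corr_templates_data(templates.maps, X)
    fitmat = np.abs(R) if templates.polarity == "ignore" else R
    labels = np.argmax(fitmat, axis=0)
    if smooth:
        labels = smooth_labels(
            labels, data, templates,
            window=smooth.get("window", DEFAULT_SMOOTH_WINDOW),
            penalty=smooth.get("penalty", DEFAULT_SMOOTH_PENALTY),
        )
    seg = SegmentationLabels(
        condition=ga.condition,
        times=times[sel],
        labels=labels,
        sfreq=ga.sfreq,
        smoothing=smooth,
    )
    stats = map_stats(seg, data, templates)
    return seg, stats


def map_stats(
    seg: SegmentationLabels, data: np.ndarray, templates: MicrostateTemplates
) -> pd.DataFrame:
    """Duration/onset/offset/mean-correlation/GEV-share per template map."""
    dt = 1000.0 / seg.sfreq
    X = _zero_mean(np.asarray(data, dtype=float))
    g = gfp(X)
    denom = float((g**2).sum())
    R = _corr_templates_data(templates.maps, X)
    if templates.polarity == "ignore":
        R = np.abs(R)
    rows = []
    for j, map_id in enumerate(templates.ids):
        idx = np.flatnonzero(seg.labels == j)
        expressed = idx.size > 0
        if expressed:
            onset = float(seg.times[idx[0]])
            offset = float(seg.times[idx[-1]] + dt)  # end of last labeled sample
            mean_corr = float(R[j, idx].mean())
            gev_share = float(((g[idx] * R[j, idx]) ** 2).sum() / denom) if denom else 0.0
        else:
            onset = offset = mean_corr = gev_share = float("nan")
        rows.append(
            {
                "condition": seg.condition,
                "map": map_id,
                "duration_ms": idx.size * dt,
                "onset_ms": onset,
                "offset_ms": offset,
                "mean_corr": mean_corr,
                "gev_share": 0.0 if not expressed else gev_share,
                "expressed": expressed,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-validated selection of k


def cross_validate_k(
    erps: list[SubjectERP],
    k_range=DEFAULT_K_RANGE,
    n_splits: int = DEFAULT_N_SPLITS,
    train_n: int = DEFAULT_TRAIN_N,
    test_n: int = DEFAULT_TEST_N,
    seed: int | None = None,
    n_init: int = 10,
    polarity: str = "sensitive",
    smooth: dict | None = None,
) -> CrossValidationResult:
    """Select the number of microstate maps by split-half cross-validation.

    Repeatedly split the subjects into disjoint training and test sets and
    segment the training grand averages at every k.  The selection
    criterion transfers the training labeling to the held-out data: each
    training sample is labeled with its best-correlating training template
    (optionally smoothed; pass ``{"window": ..., "penalty": ...}``), and
    the criterion is the mean spatial correlation between each *test*
    sample and the template its training label points to, averaged over
    samples, conditions and splits.  Overfit templates that capture
    training noise lower this criterion, so it peaks at the supported
    model order; the best-match correlation on test samples (which can
    only grow with k) is recorded alongside as a diagnostic.  The k with
    the highest criterion is selected (ties go to the smaller k).
    """
    by_subj: dict[str, dict[str, SubjectERP]] = {}
    for e in erps:
        by_subj.setdefault(e.subject, {})[e.condition] = e
    subjects = sorted(by_subj)
    conditions = sorted({e.condition for e in erps})
    for s in subjects:
        if set(by_subj[s]) != set(conditions):
            raise ValueError(f"subject {s} is missing conditions")
    if train_n + test_n > len(subjects):
        raise ValueError(
            f"train_n+test_n={train_n + test_n} exceeds {len(subjects)} subjects"
        )
    k_values = list(k_range)
    ref = erps[0]
    n_t = ref.data.shape[1] * len(conditions)
    if max(k_values) > n_t:
        raise ValueError("k range upper bound exceeds available time points")

    rng = np.random.default_rng(seed)
    corr = np.zeros((n_splits, len(k_values)))
    maxcorr = np.zeros((n_splits, len(k_values)))
    splits = []
    for s_i in range(n_splits):
        perm = rng.permutation(subjects)
        train, test = list(perm[:train_n]), list(perm[train_n : train_n + test_n])
        splits.append({"train": train, "test": test})
        train_gas = [
            _mean_ga([by_subj[s][c] for s in train], c) for c in conditions
        ]
        train_X = _zero_mean(np.concatenate([g.data for g in train_gas], axis=1))
        test_X = np.concatenate(
            [
                _zero_mean(_mean_ga([by_subj[s][c] for s in test], c).data)
                for c in conditions
            ],
            axis=1,
        )
        sub_seed = int(rng.integers(2**31 - 1))
        for k_i, k in enumerate(k_values):
            templates, _ = kmeans_segment(
                train_gas, k, n_init=n_init, seed=sub_seed + k, polarity=polarity
            )
            Rtr = _corr_templates_data(templates.maps, train_X)
            fit_tr = np.abs(Rtr) if polarity == "ignore" else Rtr
            labels = np.argmax(fit_tr, axis=0)
            if smooth:
                labels = smooth_labels(
                    labels, train_X, templates,
                    window=smooth.get("window", DEFAULT_SMOOTH_WINDOW),
                    penalty=smooth.get("penalty", DEFAULT_SMOOTH_PENALTY),
                )
            R = _corr_templates_data(templates.maps, test_X)
            fit = np.abs(R) if polarity == "ignore" else R
            corr[s_i, k_i] = float(fit[labels, np.arange(test_X.shape[1])].mean())
            maxcorr[s_i, k_i] = float(fit.max(axis=0).mean())
    mean_corr = corr.mean(axis=0)
    selected = k_values[int(np.argmax(mean_corr))]  # argmax takes first ⇒ smaller k
    return CrossValidationResult(
        k_values=k_values,
        mean_test_corr=mean_corr,
        mean_test_maxcorr=maxcorr.mean(axis=0),
        selected_k=selected,
        splits=splits,
        seed=seed,
    )


def _mean_ga(erps: list[SubjectERP], condition: str) -> GrandAverage:
    stack = np.stack([e.data for e in erps])
    rts = [e.mean_rt_ms for e in erps if e.mean_rt_ms is not None]
    return GrandAverage(
        condition=condition,
        alignment=erps[0].alignment,
        sfreq=erps[0].sfreq,
        data=stack.mean(axis=0),
        times=erps[0].times,
        subjects=[e.subject for e in erps],
        mean_rt_ms=float(np.mean(rts)) if rts else None,
    )


# ---------------------------------------------------------------------------
# randomization inference on map statistics


def _stat_from_labels(
    labels: np.ndarray, times: np.ndarray, dt: float, j: int, statistic: str
) -> float:
    idx = np.flatnonzero(labels == j)
    if statistic == "duration":
        return idx.size * dt
    if idx.size == 0:
        return float("nan")
    if statistic == "onset":
        return float(times[idx[0]])
    if statistic == "offset":
        return float(times[idx[-1]] + dt)
    raise ValueError(f"unknown statistic {statistic!r}")


def randomization_test(
    erps: list[SubjectERP],
    templates: MicrostateTemplates,
    statistic: str,
    map_id: str,
    conditions: list[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    fit_window_ms: tuple[float, float] | None = None,
    smooth: dict | None = None,
) -> RandomizationResult:
    """Permutation test on a map statistic across conditions.

    For every permutation, each subject's ERPs are randomly reassigned to
    the condition slots, the per-condition grand averages are rebuilt, the
    templates are re-fitted, and the statistic (map duration / onset /
    offset) is recomputed.  The observed statistic is compared with this
    null distribution using the add-one rule
    ``p = (#{null >= observed} + 1) / (n_perm + 1)``.

    Two conditions: the statistic is the (two-sided, absolute) difference.
    Three conditions: an omnibus range statistic (max - min).

    Permutations in which the map's statistic is undefined (map never
    expressed — only possible for onset/offset) are dropped from the null;
    if the map is expressed in fewer than half the permutations, the result
    is flagged invalid.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if len(conditions) < 2:
        raise ValueError("contrast needs at least 2 conditions")
    if map_id not in templates.ids:
        raise ValueError(f"unknown map id {map_id!r}")
    j = templates.ids.index(map_id)

    by_subj: dict[str, dict[str, SubjectERP]] = {}
    for e in erps:
        if e.condition in conditions:
            by_subj.setdefault(e.subject, {})[e.condition] = e
    subjects = sorted(s for s, d in by_subj.items() if len(d) == len(conditions))
    if len(subjects) < 2:
        raise ValueError("need >= 2 subjects with all contrast conditions")
    ref = by_subj[subjects[0]][conditions[0]]
    times, dt = ref.times, 1000.0 / ref.sfreq
    if fit_window_ms is not None:
        sel = (times >= fit_window_ms[0]) & (times <= fit_window_ms[1])
    else:
        sel = np.ones_like(times, dtype=bool)
    ft = times[sel]
    # data cube: subjects x conditions x electrodes x fitted samples
    D = np.stack(
        [[by_subj[s][c].data[:, sel] for c in conditions] for s in subjects]
    )
    n_subj, n_cond = D.shape[0], D.shape[1]

    def stats_for(assign: np.ndarray) -> np.ndarray:
        # assign: subjects x conditions permutation of condition indices
        out = np.empty(n_cond)
        for ci in range(n_cond):
            ga = D[np.arange(n_subj), assign[:, ci]].mean(axis=0)
            X = _zero_mean(ga)
            R = _corr_templates_data(templates.maps, X)
            fitm = np.abs(R) if templates.polarity == "ignore" else R
            labels = np.argmax(fitm, axis=0)
            if smooth:
                labels = smooth_labels(
                    labels, ga, templates,
                    window=smooth.get("window", DEFAULT_SMOOTH_WINDOW),
                    penalty=smooth.get("penalty", DEFAULT_SMOOTH_PENALTY),
                )
            out[ci] = _stat_from_labels(labels, ft, dt, j, statistic)
        return out

    identity = np.tile(np.arange(n_cond), (n_subj, 1))
    obs_per_cond = stats_for(identity)
    if n_cond == 2:
        observed = float(obs_per_cond[0] - obs_per_cond[1])
    else:
        observed = float(np.nanmax(obs_per_cond) - np.nanmin(obs_per_cond))

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    expressed = 0
    for p_i in range(n_perm):
        assign = np.stack([rng.permutation(n_cond) for _ in range(n_subj)])
        per_cond = stats_for(assign)
        if n_cond == 2:
            null[p_i] = per_cond[0] - per_cond[1]
        else:
            null[p_i] = np.nanmax(per_cond) - np.nanmin(per_cond)
        if not np.any(np.isnan(per_cond)):
            expressed += 1

    valid_null = null[~np.isnan(null)]
    n_valid = valid_null.size
    warning = None
    valid = True
    if np.isnan(observed):
        p = float("nan")
        valid = False
        warning = f"map {map_id} not expressed in the observed data"
    else:
        if n_cond == 2:
            exceed = int(np.sum(np.abs(valid_null) >= abs(observed)))
        else:
            exceed = int(np.sum(valid_null >= observed))
        p = (exceed + 1) / (n_valid + 1)
    if statistic != "duration" and expressed < n_perm / 2:
        valid = False
        warning = (
            f"map {map_id} expressed in only {expressed}/{n_perm} permutations; "
            "p-value unreliable"
        )
    if not valid and warning:
        warnings.warn(warning, stacklevel=2)
    return RandomizationResult(
        contrast="|".join(conditions),
        statistic=statistic,
        map_id=map_id,
        observed=observed,
        per_condition=dict(zip(conditions, obs_per_cond.tolist())),
        n_perm=n_perm,
        n_valid=n_valid,
        null_mean=float(np.mean(valid_null)) if n_valid else float("nan"),
        null_sd=float(np.std(valid_null)) if n_valid else float("nan"),
        p_value=p,
        seed=seed,
        valid=valid,
        warning=warning,
    )


# ---------------------------------------------------------------------------
# template-set correlation across alignments


def correlate_template_sets(
    a: MicrostateTemplates, b: MicrostateTemplates, polarity: str | None = None
) -> tuple[np.ndarray, list[tuple[str, str, float]]]:
    """Pairwise spatial correlations between two template sets.

    Returns the full ``k_a x k_b`` correlation matrix and a greedy
    one-to-one matching by descending correlation (absolute correlation in
    polarity-ignoring mode), e.g. to identify response-aligned maps with
    stimulus-aligned ones.
    """
    if a.maps.shape[1] != b.maps.shape[1]:
        raise ValueError("template sets must share the electrode set")
    if polarity is None:
        polarity = a.polarity
    M = np.array(
        [
            [spatial_correlation(wa, wb, "sensitive") for wb in b.maps]
            for wa in a.maps
        ]
    )
    key = np.abs(M) if polarity == "ignore" else M
    matching: list[tuple[str, str, float]] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    order = np.argsort(key, axis=None)[::-1]
    for flat in order:
        i, jj = divmod(int(flat), M.shape[1])
        if i in used_a or jj in used_b:
            continue
        used_a.add(i)
        used_b.add(jj)
        matching.append((a.ids[i], b.ids[jj], float(M[i, jj])))
        if len(matching) == min(M.shape):
            break
    matching.sort(key=lambda triple: a.ids.index(triple[0]))
    return M, matching
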