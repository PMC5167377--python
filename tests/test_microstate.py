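import itertools

import numpy as np
import pytest

from erpstates.microstate import (
    MicrostateTemplates,
    _corr_templates_data,
    correlate_template_sets,
    cross_validate_k,
    fit_templates,
    gev_of_labeling,
    gfp,
    kmeans_segment,
    randomization_test,
    smooth_labels,
    spatial_correlation,
)
from erpstates.simulate import make_montage, make_templates
from tests.conftest import make_ga, make_subject_erp

SFREQ = 512.0
DT = 1000.0 / SFREQ


def norm_map(v):
    v = v - v.mean()
    return v / v.std()


@pytest.fixture(scope="module")
def tpl3(montage16_module=None):
    m = make_montage(16)
    return make_templates(3, m, corr_cap=0.6, seed=11)


class TestSpatialCorrelation:
    def test_self_correlation_is_one(self):
        v = np.arange(8.0)
        assert spatial_correlation(v, v) == pytest.approx(1.0)

    def test_sign_flip_polarity_modes(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=16)
        assert spatial_correlation(v, -v) == pytest.approx(-1.0)
        assert spatial_correlation(v, -v, polarity="ignore") == pytest.approx(1.0)

    def test_matches_direct_covariance_formula(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=128), rng.normal(size=128)
        az, bz = a - a.mean(), b - b.mean()
        expected = (az * bz).mean() / (az.std() * bz.std())
        assert spatial_correlation(a, b) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_map_is_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            spatial_correlation(np.ones(8), np.arange(8.0))


class TestKmeansSegment:
    def test_single_map_with_varying_gfp_gives_gev_one(self):
        rng = np.random.default_rng(2)
        w = norm_map(rng.normal(size=12))
        scale = np.linspace(0.5, 3.0, 40)
        ga = make_ga(np.outer(w, scale))
        tpl, gev = kmeans_segment(ga, 1, n_init=5, seed=0)
        assert gev == pytest.approx(1.0)
        assert abs(spatial_correlation(tpl.maps[0], w)) == pytest.approx(1.0)

    def test_two_orthogonal_maps_k2_perfect_k1_lower(self):
        rng = np.random.default_rng(3)
        a = norm_map(rng.normal(size=12))
        b = norm_map(rng.normal(size=12))
        b = norm_map(b - a * spatial_correlation(a, b))  # orthogonalize
        data = np.empty((12, 30))
        data[:, ::2] = a[:, None]
        data[:, 1::2] = b[:, None]
        ga = make_ga(data)
        _, gev2 = kmeans_segment(ga, 2, n_init=10, seed=0)
        _, gev1 = kmeans_segment(ga, 1, n_init=10, seed=0)
        assert gev2 == pytest.approx(1.0)
        assert gev1 < gev2 - 0.2

    def test_best_restart_matches_partition_enumeration(self):
        # tiny instances: exhaustive over all 2-colorings of 6 time points
        rng = np.random.default_rng(4)
        for trial in range(10):
            X = rng.normal(size=(4, 6))
            ga = make_ga(X)
            _, gev = kmeans_segment(ga, 2, n_init=20, seed=trial, polarity="ignore")
            assert gev == pytest.approx(brute_force_gev(X), abs=1e-9)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        ga = make_ga(rng.normal(size=(8, 50)))
        t1, g1 = kmeans_segment(ga, 3, n_init=10, seed=42)
        t2, g2 = kmeans_segment(ga, 3, n_init=10, seed=42)
        assert g1 == g2
        np.testing.assert_array_equal(t1.maps, t2.maps)

    def test_gev_bounds_and_monotone_in_k(self):
        rng = np.random.default_rng(6)
        ga = make_ga(rng.normal(size=(8, 40)))
        gevs = [
            kmeans_segment(ga, k, n_init=20, seed=1)[1] for k in (1, 2, 3, 4)
        ]
        assert all(0.0 <= g <= 1.0 for g in gevs)
        assert all(b >= a - 1e-9 for a, b in zip(gevs, gevs[1:]))

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 40))
        t1, g1 = kmeans_segment(make_ga(X), 3, n_init=10, seed=3)
        t2, g2 = kmeans_segment(make_ga(7.3 * X), 3, n_init=10, seed=3)
        assert g1 == pytest.approx(g2, rel=1e-12)
        np.testing.assert_allclose(t1.maps, t2.maps, atol=1e-10)

    def test_polarity_ignore_invariant_to_column_sign_flips(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(8, 30))
        flip = np.where(rng.random(30) < 0.5, -1.0, 1.0)
        _, g1 = kmeans_segment(make_ga(X), 2, n_init=20, seed=4, polarity="ignore")
        _, g2 = kmeans_segment(make_ga(X * flip), 2, n_init=20, seed=4, polarity="ignore")
        assert g1 == pytest.approx(g2, abs=1e-9)

    def test_k_exceeding_time_points_is_error(self):
        ga = make_ga(np.random.default_rng(9).normal(size=(6, 4)))
        with pytest.raises(ValueError):
            kmeans_segment(ga, 5, n_init=2, seed=0)


def brute_force_gev(X, k=2):
    """Exhaustive enumeration over all k-group partitions of time points."""
    E, T = X.shape
    Xz = X - X.mean(axis=0)
    g = gfp(Xz)
    denom = (g**2).sum()
    best = -1.0
    for assign in itertools.product(range(k), repeat=T):
        assign = np.asarray(assign)
        maps = []
        if len(set(assign.tolist())) < k:
            continue
        for j in range(k):
            V = Xz[:, assign == j]
            _, vecs = np.linalg.eigh(V @ V.T)
            maps.append(vecs[:, -1])
        R = _corr_templates_data(np.stack(maps), Xz)
        r = np.abs(R).max(axis=0)
        best = max(best, ((g * r) ** 2).sum() / denom)
    return best


class TestSmoothing:
    def _setup(self, seed=0, T=40, noise=0.35):
        rng = np.random.default_rng(seed)
        m = make_montage(16)
        tpl = make_templates(2, m, corr_cap=0.5, seed=seed)
        seq, lab = [], []
        l = int(rng.integers(0, 2))
        while len(seq) < T:
            for _ in range(int(rng.integers(4, 9))):
                if len(seq) >= T:
                    break
                seq.append(
                    rng.uniform(0.8, 1.2) * tpl.maps[l] + noise * rng.normal(size=16)
                )
                lab.append(l)
            l = 1 - l
        X = np.array(seq).T
        R = _corr_templates_data(tpl.maps, X - X.mean(axis=0))
        return X, tpl, R, np.argmax(R, axis=0)

    def test_zero_penalty_keeps_argmax_labeling(self):
        X, tpl, _, labels0 = self._setup()
        out = smooth_labels(labels0, X, tpl, window=10, penalty=0.0)
        np.testing.assert_array_equal(out, labels0)

    def test_isolated_island_absorbed(self):
        rng = np.random.default_rng(1)
        m = make_montage(16)
        tpl = make_templates(2, m, corr_cap=0.5, seed=1)
        # 21 samples of map 0 with a single-island of map 1 in the middle;
        # the island's fit advantage is tiny
        X = np.tile(tpl.maps[0][:, None], (1, 21))
        X[:, 10] = 0.55 * tpl.maps[1] + 0.5 * tpl.maps[0]
        R = _corr_templates_data(tpl.maps, X - X.mean(axis=0))
        labels0 = np.argmax(R, axis=0)
        assert labels0[10] == 1  # argmax fit prefers the island label
        out = smooth_labels(labels0, X, tpl, window=10, penalty=3.0)
        assert (out == 0).all()

    def test_fixed_point_is_single_flip_optimum_of_objective(self):
        # oracle: no single label change may improve the global objective
        #   sum_t fit(t, l_t) + 2*penalty*#{same-label pairs within window/2}
        for seed in range(8):
            X, tpl, R, labels0 = self._setup(seed=seed)
            window, penalty, half = 4, 3.0, 2
            out = smooth_labels(labels0, X, tpl, window=window, penalty=penalty)
            T = len(out)

            def objective(lab):
                s = R[lab, np.arange(T)].sum()
                pairs = sum(
                    int(lab[t] == lab[u])
                    for t in range(T)
                    for u in range(t + 1, min(T, t + half + 1))
                )
                return s + 2 * penalty * pairs

            base = objective(out)
            for t in range(T):
                flipped = out.copy()
                flipped[t] = 1 - flipped[t]
                assert objective(flipped) <= base + 1e-9

    def test_switch_count_nonincreasing_in_penalty(self):
        X, tpl, _, labels0 = self._setup(seed=3, noise=0.6)
        switches = []
        for penalty in (0.0, 1.0, 3.0, 6.0):
            out = smooth_labels(labels0, X, tpl, window=10, penalty=penalty)
            switches.append(int((out[1:] != out[:-1]).sum()))
        assert switches == sorted(switches, reverse=True)


class TestFitTemplates:
    def test_refitting_training_data_reproduces_training_gev(self):
        rng = np.random.default_rng(10)
        m = make_montage(16)
        tpl = make_templates(3, m, corr_cap=0.5, seed=10)
        seq = np.repeat(np.arange(3), 10)
        X = tpl.maps[seq].T * rng.uniform(0.5, 2.0, 30)
        ga = make_ga(X)
        trained, gev = kmeans_segment(ga, 3, n_init=10, seed=0)
        seg, stats = fit_templates(trained, ga)
        assert gev_of_labeling(ga.data, trained, seg.labels) == pytest.approx(gev)
        assert gev == pytest.approx(1.0)

    def test_unexpressed_map_flagged_with_zero_duration(self):
        rng = np.random.default_rng(11)
        m = make_montage(16)
        tpl = make_templates(3, m, corr_cap=0.5, seed=11)
        X = np.tile(tpl.maps[0][:, None], (1, 20))  # only map 1 present
        _, stats = fit_templates(tpl, make_ga(X))
        row = stats[stats["map"] == "3"].iloc[0]
        assert row["duration_ms"] == 0.0
        assert not row["expressed"]
        assert np.isnan(row["onset_ms"]) and np.isnan(row["offset_ms"])

    def test_planted_aba_sequence_durations_and_offsets(self):
        m = make_montage(16)
        tpl = make_templates(2, m, corr_cap=0.5, seed=12)
        sfreq = 500.0  # 2 ms samples make the arithmetic exact
        n = {"A": 50, "B": 100}  # 100 ms A, 200 ms B, 100 ms A
        seq = [0] * n["A"] + [1] * n["B"] + [0] * n["A"]
        X = tpl.maps[np.array(seq)].T
        ga = make_ga(X, sfreq=sfreq)
        _, stats = fit_templates(tpl, ga)
        a = stats[stats["map"] == "1"].iloc[0]
        b = stats[stats["map"] == "2"].iloc[0]
        assert a["duration_ms"] == pytest.approx(200.0)
        assert b["duration_ms"] == pytest.approx(200.0)
        assert b["offset_ms"] == pytest.approx(300.0)  # B spans 100..300 ms
        assert a["onset_ms"] == pytest.approx(0.0)

    def test_durations_sum_to_fitted_window(self):
        rng = np.random.default_rng(13)
        m = make_montage(16)
        tpl = make_templates(3, m, corr_cap=0.6, seed=13)
        ga = make_ga(rng.normal(size=(16, 64)))
        seg, stats = fit_templates(tpl, ga)
        assert stats["duration_ms"].sum() == pytest.approx(64 * DT)

    def test_empty_fit_window_is_error(self):
        m = make_montage(16)
        tpl = make_templates(2, m, seed=14)
        ga = make_ga(np.random.default_rng(0).normal(size=(16, 20)))
        with pytest.raises(ValueError, match="empty fit window"):
            fit_templates(tpl, ga, fit_window_ms=(1000.0, 2000.0))


class TestCrossValidation:
    def _erps_from_planted(self, k, n_subjects=8, T=60, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        m = make_montage(16)
        tpl = make_templates(k, m, corr_cap=0.5, seed=seed)
        seq = np.repeat(np.arange(k), T // k)
        erps = []
        for i in range(n_subjects):
            X = tpl.maps[seq].T * rng.uniform(0.8, 1.5, len(seq))
            X = X + noise * rng.normal(size=X.shape)
            erps.append(make_subject_erp(X, f"S{i:02d}", "ST"))
        return erps

    def test_noise_free_planted_k_selected(self):
        erps = self._erps_from_planted(3)
        res = cross_validate_k(
            erps, k_range=range(1, 7), n_splits=5, train_n=4, test_n=4,
            seed=0, n_init=5,
        )
        assert res.selected_k == 3

    def test_selected_criterion_at_least_k1(self):
        erps = self._erps_from_planted(3, noise=0.5, seed=1)
        res = cross_validate_k(
            erps, k_range=range(1, 7), n_splits=4, train_n=4, test_n=4,
            seed=1, n_init=5,
        )
        sel = res.k_values.index(res.selected_k)
        assert res.mean_test_corr[sel] >= res.mean_test_corr[0]

    def test_split_sizes_validated(self):
        erps = self._erps_from_planted(2, n_subjects=6)
        with pytest.raises(ValueError, match="exceeds"):
            cross_validate_k(erps, k_range=range(1, 3), n_splits=2,
                             train_n=4, test_n=4, seed=0)

    def test_recorded_splits_are_disjoint(self):
        erps = self._erps_from_planted(2, n_subjects=8, seed=2)
        res = cross_validate_k(
            erps, k_range=range(1, 4), n_splits=3, train_n=4, test_n=4,
            seed=2, n_init=3,
        )
        for split in res.splits:
            assert not set(split["train"]) & set(split["test"])


class TestRandomization:
    def _null_erps(self, n_subjects=8, seed=0, conditions=("ST", "aDT")):
        rng = np.random.default_rng(seed)
        m = make_montage(16)
        tpl = make_templates(3, m, corr_cap=0.5, seed=seed)
        seq = np.repeat(np.arange(3), 20)
        erps = []
        for i in range(n_subjects):
            base = tpl.maps[seq].T * rng.uniform(0.8, 1.4, 60)
            for c in conditions:
                erps.append(
                    make_subject_erp(
                        base + 0.4 * rng.normal(size=base.shape), f"S{i:02d}", c
                    )
                )
        return erps, tpl

    def test_self_contrast_p_near_one(self):
        # both "conditions" share the same per-subject data
        rng = np.random.default_rng(20)
        m = make_montage(16)
        tpl = make_templates(2, m, corr_cap=0.5, seed=20)
        seq = np.array([0] * 20 + [1] * 20)
        erps = []
        for i in range(6):
            X = tpl.maps[seq].T * rng.uniform(0.8, 1.2, 40)
            for c in ("ST", "aDT"):
                erps.append(make_subject_erp(X, f"S{i:02d}", c))
        res = randomization_test(
            erps, tpl, "duration", "1", ["ST", "aDT"], n_perm=100, seed=0
        )
        assert res.observed == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_planted_duration_difference_detected(self):
        rng = np.random.default_rng(21)
        m = make_montage(16)
        tpl = make_templates(2, m, corr_cap=0.5, seed=21)
        erps = []
        for i in range(10):
            for c, n0 in (("ST", 12), ("aDT", 28)):  # >2x the planted duration
                # per-subject boundary jitter keeps the null distribution smooth
                b = int(np.clip(round(rng.normal(n0, 2.0)), 4, 36))
                seq = np.array([0] * b + [1] * (40 - b))
                X = tpl.maps[seq].T * rng.uniform(0.9, 1.1, 40)
                X = X + 0.2 * rng.normal(size=X.shape)
                erps.append(make_subject_erp(X, f"S{i:02d}", c))
        res = randomization_test(
            erps, tpl, "duration", "1", ["ST", "aDT"], n_perm=199, seed=1
        )
        assert res.p_value < 0.05
        assert res.observed < 0  # ST shorter than aDT

    def test_p_uses_add_one_rule_bounds(self):
        erps, tpl = self._null_erps(seed=22)
        res = randomization_test(
            erps, tpl, "duration", "1", ["ST", "aDT"], n_perm=100, seed=2
        )
        assert 1 / 101 <= res.p_value <= 1.0

    def test_deterministic_given_seed(self):
        erps, tpl = self._null_erps(seed=23)
        r1 = randomization_test(
            erps, tpl, "offset", "2", ["ST", "aDT"], n_perm=120, seed=7
        )
        r2 = randomization_test(
            erps, tpl, "offset", "2", ["ST", "aDT"], n_perm=120, seed=7
        )
        assert r1.p_value == r2.p_value
        assert r1.observed == r2.observed

    def test_minimum_permutations_enforced(self):
        erps, tpl = self._null_erps(seed=24)
        with pytest.raises(ValueError, match="n_perm"):
            randomization_test(
                erps, tpl, "duration", "1", ["ST", "aDT"], n_perm=50, seed=0
            )


class TestTemplateSetCorrelation:
    def test_identical_sets_identity_matching(self):
        m = make_montage(16)
        tpl = make_templates(3, m, corr_cap=0.5, seed=30)
        M, matching = correlate_template_sets(tpl, tpl)
        np.testing.assert_allclose(np.diag(M), 1.0)
        assert [(a, b) for a, b, _ in matching] == [("1", "1"), ("2", "2"), ("3", "3")]

    def test_permuted_set_recovered(self):
        m = make_montage(16)
        tpl = make_templates(4, m, corr_cap=0.5, seed=31)
        perm = [2, 0, 3, 1]
        other = MicrostateTemplates(
            maps=tpl.maps[perm], ids=["a", "b", "c", "d"], polarity="sensitive"
        )
        _, matching = correlate_template_sets(tpl, other)
        expected = {("1", "b"), ("2", "d"), ("3", "a"), ("4", "c")}
        assert {(a, b) for a, b, _ in matching} == expected

    def test_matrix_matches_per_pair_computation(self):
        m = make_montage(16)
        a = make_templates(3, m, corr_cap=0.6, seed=32)
        b = make_templates(2, m, corr_cap=0.6, seed=33)
        M, _ = correlate_template_sets(a, b)
        for i in range(3):
            for j in range(2):
                assert M[i, j] == pytest.approx(
                    spatial_correlation(a.maps[i], b.maps[j]), rel=1e-12
                )
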