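import numpy as np
import pytest
from scipy import signal

from erpstates.containers import EpochSet, Recording, TrialLog
from erpstates.preprocess import (
    average_epochs,
    bandpass,
    grand_average,
    harmonize_masks,
    make_epochs,
    reject_artifacts,
    rereference_average,
    trim_overlap,
)
from erpstates.simulate import make_montage
from tests.conftest import make_ga, make_subject_erp

SFREQ = 512.0


def sine(freq, seconds=4.0, sfreq=SFREQ, amp=1.0):
    t = np.arange(int(seconds * sfreq)) / sfreq
    return amp * np.sin(2 * np.pi * freq * t)[None, :]


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        # long signal so the 0.2 Hz high-pass transient dies out mid-signal
        out = bandpass(sine(10.0, seconds=30.0), SFREQ)
        mid = out[0, 10 * 512 : 20 * 512]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuation_matches_designed_response(self):
        # independent oracle: the designed filter's magnitude response at 100 Hz
        sos = signal.butter(2, [0.2, 30], btype="bandpass", fs=SFREQ, output="sos")
        _, h = signal.sosfreqz(sos, worN=[100.0], fs=SFREQ)
        expected = np.abs(h[0]) ** 2  # forward-backward squares the magnitude
        out = bandpass(sine(100.0, seconds=30.0), SFREQ)
        measured = np.abs(out[0, 10 * 512 : 20 * 512]).max()
        assert measured <= 0.1  # >= 90% attenuation
        assert measured == pytest.approx(expected, rel=0.10)

    def test_dc_offset_removed(self):
        out = bandpass(np.full((1, 4096), 50.0), SFREQ)
        assert np.abs(out.mean()) < 0.5

    def test_band_edges_validated(self):
        with pytest.raises(ValueError):
            bandpass(sine(10.0), SFREQ, low=0.2, high=300.0)


class TestAverageReference:
    def test_constant_map_zeroed(self):
        out = rereference_average(np.full((8, 10), 5.0))
        np.testing.assert_allclose(out, 0.0)

    def test_zero_mean_map_unchanged(self):
        data = np.array([[1.0], [-1.0]])
        np.testing.assert_allclose(rereference_average(data), data)

    def test_random_input_channel_means_vanish(self):
        rng = np.random.default_rng(0)
        out = rereference_average(rng.normal(0, 20, size=(128, 100)))
        assert np.abs(out.mean(axis=0)).max() < 1e-9

    def test_commutes_with_bandpass(self):
        rng = np.random.default_rng(1)
        data = rng.normal(0, 10, size=(16, 2048))
        data -= data.mean(axis=0)
        a = rereference_average(bandpass(data, SFREQ))
        b = bandpass(rereference_average(data), SFREQ)
        np.testing.assert_allclose(a, b, atol=1e-8)


def _epochs(data, sfreq=SFREQ):
    n = data.shape[0]
    return EpochSet(
        subject="S01", condition="ST", alignment="stimulus", sfreq=sfreq,
        data=data, times=np.arange(data.shape[2]) * (1000 / sfreq),
        latencies=np.full(n, 800.0), mask=np.ones(n, dtype=bool),
    )


class TestArtifactRejection:
    def test_strict_exceedance_boundary(self):
        data = np.zeros((2, 3, 10))
        data[0, 1, 5] = 100.1  # exceeds
        data[1, 2, 3] = 100.0  # exactly at threshold: kept
        out = reject_artifacts(_epochs(data))
        assert list(out.mask) == [False, True]

    def test_matches_per_sample_oracle(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 60, size=(50, 4, 40))
        out = reject_artifacts(_epochs(data), threshold=100.0)
        expected = []
        for ep in data:
            bad = any(abs(v) > 100.0 for v in ep.ravel())
            expected.append(not bad)
        assert list(out.mask) == expected

    def test_rejection_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        data = rng.normal(0, 60, size=(30, 4, 40))
        kept = [
            reject_artifacts(_epochs(data), thr).n_kept
            for thr in (50.0, 100.0, 150.0, 250.0)
        ]
        assert kept == sorted(kept)


class TestMakeEpochs:
    @pytest.fixture
    def raw(self):
        m = make_montage(4)
        return Recording(data=np.zeros((4, 6 * 512)), sfreq=SFREQ, montage=m)

    def test_response_window_arithmetic(self, raw):
        trials = [TrialLog("S01", 1, "ST", "none", 800.0, True)]
        eps = make_epochs(raw, [1024], trials, "response")
        assert eps.times[0] == pytest.approx(-600.0, abs=2.0)
        assert eps.times[-1] == pytest.approx(-100.0, abs=2.0)

    def test_impulse_at_onset_lands_at_time_zero(self, raw):
        raw.data[:, 1024] = 42.0
        trials = [TrialLog("S01", 1, "ST", "none", 800.0, True)]
        eps = make_epochs(raw, [1024], trials, "stimulus")
        i0 = int(np.argmin(np.abs(eps.times)))
        assert eps.times[i0] == 0.0
        assert eps.data[0, 0, i0] == 42.0

    def test_window_outside_recording_dropped(self, raw):
        trials = [
            TrialLog("S01", 1, "ST", "none", 800.0, True),
            TrialLog("S01", 2, "ST", "none", 800.0, True),
        ]
        eps = make_epochs(raw, [10, 1024], trials, "stimulus")  # first too early
        assert eps.n_trials == 1

    def test_error_and_filler_trials_never_epoched(self, raw):
        trials = [
            TrialLog("S01", 1, "ST", "none", None, False),
            TrialLog("S01", 2, "ST", "none", 780.0, True, filler=True),
            TrialLog("S01", 3, "ST", "none", 790.0, True),
        ]
        eps = make_epochs(raw, [1024, 1100, 1200], trials, "stimulus")
        assert eps.n_trials == 1

    def test_joint_mask_across_alignments(self, raw):
        trials = [TrialLog("S01", i + 1, "ST", "none", 800.0, True) for i in range(3)]
        stim = make_epochs(raw, [1024, 1100, 1200], trials, "stimulus")
        resp = make_epochs(raw, [1024, 1100, 1200], trials, "response")
        stim.mask[0] = False
        resp.mask[2] = False
        s2, r2 = harmonize_masks(stim, resp)
        assert list(s2.mask) == [False, True, False]
        assert list(r2.mask) == list(s2.mask)


class TestAveraging:
    def test_minimum_epoch_count_enforced(self):
        data = np.zeros((5, 2, 10))
        with pytest.raises(ValueError, match="minimum"):
            average_epochs(_epochs(data), min_epochs=31)
        erp = average_epochs(_epochs(data), min_epochs=5)
        assert erp.n_epochs == 5

    def test_identical_subjects_average_to_themselves(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(4, 20))
        erps = [make_subject_erp(data, s, "ST") for s in ("S01", "S02")]
        ga = grand_average(erps)
        np.testing.assert_allclose(ga.data, data)

    def test_opposite_subjects_cancel(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(4, 20))
        erps = [
            make_subject_erp(data, "S01", "ST"),
            make_subject_erp(-data, "S02", "ST"),
        ]
        np.testing.assert_allclose(grand_average(erps).data, 0.0, atol=1e-12)

    def test_seventeen_subjects_equal_explicit_mean(self):
        rng = np.random.default_rng(6)
        stack = rng.normal(size=(17, 4, 20))
        erps = [
            make_subject_erp(stack[i], f"S{i:02d}", "ST") for i in range(17)
        ]
        np.testing.assert_allclose(grand_average(erps).data, stack.mean(axis=0))

    def test_pooled_equals_mean_of_halves(self):
        rng = np.random.default_rng(7)
        stack = rng.normal(size=(8, 4, 20))
        erps = [make_subject_erp(stack[i], f"S{i:02d}", "ST") for i in range(8)]
        pooled = grand_average(erps).data
        halves = np.stack(
            [grand_average(erps[:4]).data, grand_average(erps[4:]).data]
        ).mean(axis=0)
        np.testing.assert_allclose(pooled, halves, atol=1e-12)

    def test_heterogeneous_time_axes_rejected(self):
        a = make_subject_erp(np.zeros((4, 20)), "S01", "ST", t0=0.0)
        b = make_subject_erp(np.zeros((4, 20)), "S02", "ST", t0=50.0)
        with pytest.raises(ValueError, match="time axes"):
            grand_average([a, b])


class TestTrimOverlap:
    def _resp_ga(self, mean_rt):
        rng = np.random.default_rng(8)
        return make_ga(
            rng.normal(size=(4, 256)), condition="ST", alignment="response",
            t0=-600.0, mean_rt_ms=mean_rt,
        )

    def test_no_overlap_nothing_trimmed(self):
        out = trim_overlap(self._resp_ga(1100.0))
        assert out.trimmed_span_ms is None
        assert out.data.shape[1] == 256

    def test_overlap_trimmed_per_rule(self):
        # mean RT 817: response window covers 217..717 ms post stimulus;
        # the first 283 ms (everything before 500-817=-317) overlaps
        out = trim_overlap(self._resp_ga(817.0))
        dt = 1000 / 512
        # first kept sample straddles the -317 ms cutoff
        assert out.times[0] + dt > -317.0 >= out.times[0]
        assert out.times[0] == pytest.approx(-317.0, abs=dt)
        assert out.trimmed_span_ms is not None
        assert out.trimmed_span_ms[0] == pytest.approx(-600.0, abs=2.0)
        removed = 256 - out.data.shape[1]
        assert removed * (1000 / 512) == pytest.approx(283.0, abs=2.0)

    def test_near_total_overlap_warns_but_proceeds(self):
        with pytest.warns(UserWarning, match="samples"):
            out = trim_overlap(self._resp_ga(601.0))
        assert out.data.shape[1] >= 1

    def test_total_overlap_is_error(self):
        with pytest.raises(ValueError, match="whole"):
            trim_overlap(self._resp_ga(400.0))

    def test_requires_mean_rt(self):
        ga = self._resp_ga(817.0)
        ga.mean_rt_ms = None
        with pytest.raises(ValueError, match="latency"):
            trim_overlap(ga)
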