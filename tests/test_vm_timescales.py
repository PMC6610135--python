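import numpy as np
import pytest
from scipy import signal as sps

from cpgnet.vm_timescales import (
    FAST_CUTOFF,
    FILTER_ORDER,
    SLOW_BAND,
    decompose,
    fastcorr_rate_dependence,
    pair_phase,
    pearson,
    quiescence_mask,
    remove_action_potentials,
    shuffle_null,
    sliding_correlation,
    summarize_pair,
)

FS = 1000.0


def _t(duration):
    return np.arange(int(duration * FS)) / FS


class TestDecompose:
    def test_in_band_sinusoid_goes_to_slow(self):
        x = np.sin(2 * np.pi * 1.0 * _t(30))
        split = decompose(x, FS)
        assert np.sqrt(np.mean(split.fast ** 2)) < 0.01 * np.sqrt(np.mean(x ** 2))
        assert pearson(split.slow, x) > 0.99

    def test_out_of_band_sinusoid_goes_to_fast(self):
        x = np.sin(2 * np.pi * 50.0 * _t(30))
        split = decompose(x, FS)
        inner = slice(int(5 * FS), int(25 * FS))  # skip filter edge transients
        assert np.sqrt(np.mean(split.slow[inner] ** 2)) < \
            0.01 * np.sqrt(np.mean(x ** 2))
        assert pearson(split.fast, x) > 0.99

    def test_white_noise_power_fractions_match_filter_gains(self, rng):
        # FFT oracle: E[var(filtered)] = mean over frequencies of |H|^4
        # (the filter is applied forward and backward)
        x = rng.standard_normal(int(120 * FS))
        split = decompose(x, FS)
        f = np.fft.rfftfreq(x.size, 1 / FS)
        inner = slice(int(5 * FS), int(115 * FS))
        for comp, kind, cutoff, tol in [
                (split.slow, "bandpass", SLOW_BAND, 0.10),
                (split.fast, "highpass", FAST_CUTOFF, 0.05)]:
            sos = sps.butter(FILTER_ORDER, cutoff, btype=kind, fs=FS,
                             output="sos")
            _, h = sps.sosfreqz(sos, worN=f, fs=FS)
            expected = np.mean(np.abs(h) ** 4)
            observed = comp[inner].var() / x.var()
            assert abs(observed - expected) < tol * expected

    def test_linearity(self, rng):
        x = rng.standard_normal(int(20 * FS))
        a = 3.7
        s1 = decompose(a * x, FS)
        s0 = decompose(x, FS)
        assert np.allclose(s1.slow, a * s0.slow, atol=1e-9)
        assert np.allclose(s1.fast, a * s0.fast, atol=1e-9)

    def test_nyquist_and_length_guards(self, rng):
        with pytest.raises(ValueError):
            decompose(rng.standard_normal(100000), 15.0)
        with pytest.raises(ValueError):
            decompose(rng.standard_normal(1000), FS)  # 1 s trace


class TestPearson:
    def test_hand_computed_example(self):
        assert pearson([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_perfect_and_anti(self, rng):
        x = rng.standard_normal(100)
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_matches_scipy(self, rng):
        from scipy.stats import pearsonr

        x, y = rng.standard_normal((2, 500))
        assert pearson(x, y) == pytest.approx(pearsonr(x, y).statistic)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSlidingCorrelation:
    def test_identical_inputs_give_unity_zero_lag(self, rng):
        x = rng.standard_normal(int(5 * FS))
        _, _, _, zl = sliding_correlation(x, x, FS)
        assert np.allclose(zl, 1.0, atol=1e-9)

    def test_delayed_copy_puts_ridge_at_lag(self, rng):
        delay_s = 0.03
        x = rng.standard_normal(int(5 * FS))
        y = np.roll(x, int(delay_s * FS))
        _, lags, gram, _ = sliding_correlation(x, y, FS)
        ridge = lags[np.argmax(gram.mean(axis=0))]
        assert ridge == pytest.approx(delay_s, abs=1.5 / FS)

    def test_independent_noise_spread_matches_fisher(self, rng):
        x, y = rng.standard_normal((2, int(30 * FS)))
        _, _, _, zl = sliding_correlation(x, y, FS, step_s=0.4)  # disjoint windows
        assert abs(zl.mean()) < 0.03
        expected_sd = 1.0 / np.sqrt(0.4 * FS)
        assert zl.std() == pytest.approx(expected_sd, rel=0.25)

    def test_degenerate_window_rejected(self, rng):
        with pytest.raises(ValueError):
            sliding_correlation(rng.standard_normal(1000),
                                rng.standard_normal(1000), FS, window_s=0.005)


class TestShuffleNull:
    def test_circular_shift_preserves_marginals(self, rng):
        x = rng.standard_normal(int(4 * FS))
        y = rng.standard_normal(int(4 * FS))
        *_, null = shuffle_null(x, y, FS, n_shuffles=10, seed=1)
        assert null.shape == (10,)
        # a roll is a permutation: same sorted values, so shuffle R is a
        # genuine correlation of the same marginal distributions
        assert np.all(np.abs(null) < 1.0)

    def test_shared_fast_input_flagged(self, rng):
        common = rng.standard_normal(int(6 * FS))
        x = common + 0.3 * rng.standard_normal(common.size)
        y = common + 0.3 * rng.standard_normal(common.size)
        mu, sigma, (lo, hi), _ = shuffle_null(x, y, FS, seed=2)
        assert pearson(x, y) > hi

    def test_shift_range_guard(self, rng):
        x = rng.standard_normal(int(1 * FS))
        with pytest.raises(ValueError):
            shuffle_null(x, x, FS, shift_range_s=(0.5, 2.0))


class TestPairPhase:
    def test_identical_traces_zero_phase(self):
        x = np.sin(2 * np.pi * _t(20))
        assert pair_phase(x, x, FS).phase_deg == pytest.approx(0.0, abs=2.0)

    def test_antiphase_is_180(self):
        x = np.sin(2 * np.pi * _t(20))
        assert pair_phase(x, -x, FS).phase_deg == pytest.approx(180.0, abs=2.0)

    def test_quarter_period_shift_is_90(self):
        t = _t(20)
        x = np.sin(2 * np.pi * t)
        y = np.sin(2 * np.pi * (t - 0.25))
        ph = pair_phase(x, y, FS)
        assert ph.period_s == pytest.approx(1.0, rel=0.05)
        assert ph.phase_deg == pytest.approx(90.0, abs=3.0)

    def test_nonrhythmic_rejected(self, rng):
        with pytest.raises(ValueError, match="rhythmic"):
            pair_phase(rng.standard_normal(int(20 * FS)),
                       rng.standard_normal(int(20 * FS)), FS)


class TestQuiescence:
    def test_fully_active_unmasked(self):
        x = np.sin(2 * np.pi * _t(10))
        assert not quiescence_mask(x, FS).any()

    def test_silent_second_half_masked(self):
        x = np.sin(2 * np.pi * _t(20))
        x[int(10 * FS):] = 0.0
        mask = quiescence_mask(x, FS)
        assert not mask[:int(9 * FS)].any()
        assert mask[int(11 * FS):].all()

    def test_masking_changes_r_for_bursty_shared_input(self, rng):
        # shared noise only in the first half; silent second half drags the
        # full-trace R toward the shared fraction of the active part
        n = int(20 * FS)
        common = rng.standard_normal(n)
        x = np.sin(2 * np.pi * _t(20)) * 3
        x[n // 2:] = 0.0
        a = x + 0.5 * common + 0.5 * rng.standard_normal(n)
        b = x + 0.5 * common + 0.5 * rng.standard_normal(n)
        s = summarize_pair(a, b, FS, with_phase=False, n_shuffles=20)
        assert s.quiescent_fraction > 0.3
        assert s.fast_R_active is not None


class TestRateDependence:
    def test_planted_antiphase_modulation_recovered(self, rng):
        # fast-correlation amplitude modulated in anti-phase with a slow
        # envelope; the dependence R must come out negative
        n_windows = 600
        t = np.arange(n_windows) * 0.1
        envelope = np.sin(2 * np.pi * 0.2 * t)
        zl = 0.3 - 0.2 * envelope + 0.02 * rng.standard_normal(n_windows)
        vm = -55 + 5 * envelope  # low-pass Vm in phase with the envelope
        fs_vm = 10.0
        r, r_null = fastcorr_rate_dependence(t, zl, vm, fs_vm, seed=0)
        assert r < -0.5
        assert abs(np.mean(r_null)) < 0.3

    def test_rate_independent_null(self, rng):
        t = np.arange(500) * 0.1
        zl = 0.3 + 0.05 * rng.standard_normal(500)
        vm = -55 + 5 * np.sin(2 * np.pi * 0.2 * np.arange(5000) / 100)
        r, r_null = fastcorr_rate_dependence(t, zl, vm, 100.0, seed=1)
        lo, hi = np.quantile(r_null, [0.01, 0.99])
        assert lo < r < hi


def test_spike_removal_interpolates_excursions(rng):
    vm = rng.standard_normal(5000)
    vm[1000:1005] += 40.0  # action-potential-like excursion
    cleaned = remove_action_potentials(vm)
    assert cleaned[1000:1005].max() < 10.0
    untouched = np.ones(5000, dtype=bool)
    untouched[1000:1005] = False
    assert np.array_equal(cleaned[untouched], vm[untouched])


def test_same_cell_control_couples_timescales(dense_sim):
    # feeding one trace as both inputs: slow R = fast R = 1
    vm, _ = dense_sim
    s = summarize_pair(vm.potentials[0], vm.potentials[0], vm.fs,
                       with_phase=False, n_shuffles=20)
    assert s.slow_R == pytest.approx(1.0, abs=1e-9)
    assert s.fast_R == pytest.approx(1.0, abs=1e-9)
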