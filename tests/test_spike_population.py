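import numpy as np
import pytest

from cpgnet.datatypes import SpikeTrainSet
from cpgnet.spike_population import (
    instantaneous_phase,
    kernel_rate,
    rate_correlation_matrices,
    rayleigh_test,
    screen_rhythmic_units,
    spike_triggered_phase_hist,
)

FS = 1000.0


class TestKernelRate:
    def test_single_spike_is_unit_area_gaussian(self):
        sigma = 0.005
        trace = kernel_rate([5.0], sigma, FS, (0.0, 10.0))
        peak = trace.rate.max()
        assert peak == pytest.approx(1.0 / (np.sqrt(2 * np.pi) * sigma),
                                     rel=1e-6)
        area = np.trapezoid(trace.rate, dx=1 / FS)
        assert area == pytest.approx(1.0, abs=1e-3)

    def test_integral_counts_spikes(self, rng):
        spikes = np.sort(rng.uniform(1.0, 19.0, size=200))
        trace = kernel_rate(spikes, 0.150, FS, (0.0, 20.0))
        area = np.trapezoid(trace.rate, dx=1 / FS)
        assert area == pytest.approx(200, rel=1e-3)

    def test_poisson_rate_recovery(self, rng):
        lam, T = 20.0, 100.0
        spikes = np.sort(rng.uniform(0, T, size=rng.poisson(lam * T)))
        trace = kernel_rate(spikes, 0.150, FS, (0.0, T))
        sem = np.sqrt(lam / T)
        assert abs(trace.rate.mean() - lam) < 3 * sem

    def test_linearity_in_spike_trains(self, rng):
        a = np.sort(rng.uniform(0, 10, 50))
        b = np.sort(rng.uniform(0, 10, 70))
        ra = kernel_rate(a, 0.02, FS, (0, 10)).rate
        rb = kernel_rate(b, 0.02, FS, (0, 10)).rate
        rab = kernel_rate(np.sort(np.concatenate([a, b])), 0.02, FS, (0, 10)).rate
        assert np.allclose(rab, ra + rb, atol=1e-9)

    def test_empty_train_gives_zero_trace(self):
        assert not kernel_rate([], 0.005, FS, (0.0, 1.0)).rate.any()


class TestRateMatrices:
    def test_duplicated_unit_fully_correlated(self, rng):
        spk = np.sort(rng.uniform(0.5, 19.5, 300))
        trains = {"a": spk, "b": spk.copy(),
                  "c": np.sort(rng.uniform(0.5, 19.5, 300))}
        slow, fast = rate_correlation_matrices(
            SpikeTrainSet(trains, (0.0, 20.0)))
        assert slow.loc["a", "b"] == pytest.approx(1.0, abs=1e-9)
        assert fast.loc["a", "b"] == pytest.approx(1.0, abs=1e-9)

    def test_independent_poisson_fast_near_zero(self, rng):
        T = 60.0
        trains = {f"u{i}": np.sort(rng.uniform(0, T, rng.poisson(20 * T)))
                  for i in range(4)}
        slow, fast = rate_correlation_matrices(SpikeTrainSet(trains, (0.0, T)))
        off = fast.values[np.triu_indices(4, 1)]
        # effective sample count of the sigma=5 ms smoothed trace is about
        # T / (2 sqrt(pi) sigma); 3 sigma of a null Pearson R on that
        n_eff = T / (2 * np.sqrt(np.pi) * 0.005)
        assert np.all(np.abs(off) < 3.0 / np.sqrt(n_eff))

    def test_matrices_symmetric_unit_diagonal(self, rng):
        trains = {f"u{i}": np.sort(rng.uniform(0, 30, 400)) for i in range(3)}
        slow, fast = rate_correlation_matrices(SpikeTrainSet(trains, (0.0, 30.0)))
        for m in (slow.values, fast.values):
            assert np.allclose(m, m.T)
            assert np.allclose(np.diag(m), 1.0)
            assert np.all(np.abs(m) <= 1.0 + 1e-12)

    def test_decoupled_population_structure(self):
        # common slow modulation with independent spike timing: slow entries
        # high, fast entries near zero
        from cpgnet.synthetic import TunedPopulationSpec, make_tuned_population

        spec = TunedPopulationSpec(n_units=4, preferred_phases_deg=(90,) * 4,
                                   kappas=2.0, base_rate=2.0, mod_rate=30.0,
                                   duration_s=120.0, seed=5)
        spikes, _, _ = make_tuned_population(spec)
        slow, fast = rate_correlation_matrices(spikes)
        iu = np.triu_indices(4, 1)
        assert slow.values[iu].mean() > 0.5
        assert np.abs(fast.values[iu]).mean() < 0.05


class TestRayleigh:
    def test_perfect_concentration(self):
        res = rayleigh_test(np.full(10, 1.3))
        assert res.R == pytest.approx(1.0)
        assert res.z == pytest.approx(10.0)
        assert res.significant

    def test_uniform_grid_not_significant(self):
        # 100 evenly spaced phases: resultant length exactly 0, p = 1
        res = rayleigh_test(np.linspace(0, 2 * np.pi, 100, endpoint=False))
        assert res.R == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        ph = rng.vonmises(1.0, 1.5, size=200) % (2 * np.pi)
        res = rayleigh_test(ph)
        z_pg, p_pg = pingouin.circ_rayleigh(ph)
        assert res.z == pytest.approx(z_pg, rel=1e-6)
        assert res.p == pytest.approx(p_pg, rel=0.05)

    def test_p_strictly_decreasing_in_R(self):
        for n in (5, 20, 100, 1000):
            log_ps = []
            for R in np.linspace(0.0, 0.99, 25):
                arg = 1 + 4 * n + 4 * (n ** 2 - (R * n) ** 2)
                # log p, immune to underflow at large N R^2
                log_ps.append(np.sqrt(arg) - (1 + 2 * n))
            assert np.all(np.diff(log_ps) < 0)

    def test_empty_phases_error(self):
        with pytest.raises(ValueError):
            rayleigh_test([])


class TestInstantaneousPhase:
    def test_sinusoid_phase_ramp(self):
        f0, T = 1.0, 60.0
        t = np.arange(int(T * FS)) / FS
        ph = instantaneous_phase(np.sin(2 * np.pi * f0 * t), FS)
        mid = slice(int(5 * FS), int(55 * FS))
        slope = np.polyfit(t[mid], np.unwrap(ph[mid]), 1)[0]
        assert slope == pytest.approx(2 * np.pi * f0, rel=0.01)

    def test_envelope_invariance(self):
        t = np.arange(int(60 * FS)) / FS
        carrier = np.sin(2 * np.pi * 1.0 * t)
        am = (1.0 + 0.5 * np.sin(2 * np.pi * 0.05 * t)) * carrier
        mid = slice(int(10 * FS), int(50 * FS))
        p0 = np.unwrap(instantaneous_phase(carrier, FS)[mid])
        p1 = np.unwrap(instantaneous_phase(am, FS)[mid])
        assert np.abs(p1 - p0).max() < 0.25

    def test_dc_offset_removed(self):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * t)
        mid = slice(int(10 * FS), int(50 * FS))
        p0 = instantaneous_phase(x, FS)[mid]
        p1 = instantaneous_phase(x + 7.5, FS)[mid]
        assert np.abs(np.angle(np.exp(1j * (p1 - p0)))).max() < 0.1

    def test_empty_mask_rejected(self):
        t = np.arange(int(10 * FS)) / FS
        with pytest.raises(ValueError):
            instantaneous_phase(np.sin(2 * np.pi * t), FS,
                                activity_mask=np.zeros(t.size, bool))


class TestPhaseHistogramAndScreen:
    def test_locked_spikes_single_bin(self):
        t = np.arange(int(30 * FS)) / FS
        ref = np.sin(2 * np.pi * 1.0 * t)
        phase = instantaneous_phase(ref, FS)
        # analytic-signal convention: sin peaks at phase 0, descending zero
        # crossings (t = 0.5 mod 1) at phase pi/2
        spikes = np.arange(2.5, 28.0, 1.0)
        edges, counts, pref = spike_triggered_phase_hist(spikes, phase, FS)
        # all mass concentrated at the locked phase (at most 2 adjacent bins
        # when the estimate straddles a bin edge)
        assert (counts > 0).sum() <= 2
        assert counts.max() >= 0.9 * counts.sum()
        assert pref == pytest.approx(90.0, abs=10.0)

    def test_uniform_spiking_flat(self, rng):
        t = np.arange(int(60 * FS)) / FS
        phase = instantaneous_phase(np.sin(2 * np.pi * t), FS)
        spikes = np.sort(rng.uniform(1, 59, 2000))
        _, counts, _ = spike_triggered_phase_hist(spikes, phase, FS)
        assert counts.min() > 0.5 * counts.mean()

    def test_screen_separates_tuned_from_untuned(self):
        from cpgnet.synthetic import TunedPopulationSpec, make_tuned_population

        n_each = 10
        spec = TunedPopulationSpec(
            n_units=2 * n_each,
            preferred_phases_deg=tuple([90.0] * n_each + [0.0] * n_each),
            kappas=tuple([2.0] * n_each + [0.0] * n_each),
            base_rate=2.0, mod_rate=8.0, duration_s=60.0, seed=8)
        spikes, ref, _ = make_tuned_population(spec)
        phase = instantaneous_phase(ref, spec.fs)
        included, excluded, _ = screen_rhythmic_units(spikes, phase, spec.fs)
        tuned = {f"unit_{i}" for i in range(n_each)}
        untuned = {f"unit_{i}" for i in range(n_each, 2 * n_each)}
        assert len(tuned & set(included)) >= 9      # power: tuned retained
        assert len(untuned & set(excluded)) >= 7    # most untuned rejected

    def test_zero_spike_unit_excluded_with_reason(self):
        t = np.arange(int(20 * FS)) / FS
        phase = instantaneous_phase(np.sin(2 * np.pi * t), FS)
        spikes = SpikeTrainSet({"a": np.arange(1.25, 19, 1.0), "b": []},
                               (0.0, 20.0))
        included, excluded, _ = screen_rhythmic_units(spikes, phase, FS)
        assert "a" in included
        assert excluded["b"] == "no spikes"
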