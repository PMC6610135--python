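"""Ground-truth-labelled synthetic data generators.

Every statistical structure the analysis modules assume can be planted here
with known parameters, so each pipeline stage is testable without recorded
data and independently of the network simulator:

- Vm pairs whose fast-component correlation equals a controlled shared-input
  fraction c (common and independent band-limited noise mixed as sqrt(c)
  and sqrt(1-c)), riding on a slow sinusoidal envelope with per-cell phase
  offsets;
- populations of phase-tuned spiking units (von Mises tuning around a common
  rhythm) together with the reference rhythm trace;
- an intracellular trace containing planted postsynaptic potentials of known
  amplitude and decay constant on an Ornstein-Uhlenbeck background, paired
  with the presynaptic spike train.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps
from scipy.special import i0

from .datatypes import SpikeTrainSet, VmTraceSet

__all__ = [
    "SharedInputSpec",
    "TunedPopulationSpec",
    "ConnectedPairSpec",
    "make_shared_input_pair",
    "make_tuned_population",
    "make_connected_pair",
]


@dataclass
class SharedInputSpec:
    """Two-cell Vm fixture with controlled shared fast-input fraction.

    ``shared_fraction`` c sets the expected fast-component Pearson R between
    the pair by construction; ``phase_offsets_deg`` sets the expected slow R
    to cos(delta phase).
    """

    shared_fraction: float = 0.36
    slow_freq_hz: float = 1.0
    slow_amp_mV: float = 5.0
    phase_offsets_deg: tuple = (0.0, 0.0)
    fast_band_hz: tuple = (5.0, 100.0)
    fast_sigma_mV: float = 1.0
    rest_mV: float = -60.0
    duration_s: float = 60.0
    fs: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError(f"shared fraction {self.shared_fraction} outside [0, 1]")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("invalid duration or sampling rate")


@dataclass
class TunedPopulationSpec:
    """Phase-tuned Poisson population around a common rhythm.

    Per-unit rate: lambda_i(t) = base + mod * f_vM(theta(t); mu_i, kappa_i),
    with f_vM the von Mises density scaled so kappa = 0 gives a flat,
    rhythm-independent rate (non-rhythmic unit).
    """

    n_units: int = 20
    preferred_phases_deg: tuple | None = None  # default: evenly spread
    kappas: tuple | float = 2.0
    base_rate: float = 2.0
    mod_rate: float = 20.0
    rhythm_freq_hz: float = 1.0
    duration_s: float = 60.0
    fs: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if self.base_rate < 0 or self.mod_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.n_units < 1:
            raise ValueError("need at least one unit")


@dataclass
class ConnectedPairSpec:
    """One postsynaptic Vm with planted PSPs from one presynaptic train.

    ``psp_amp_mV`` < 0 plants IPSPs (inhibitory identity), > 0 EPSPs. The
    background is an Ornstein-Uhlenbeck process with standard deviation
    ``noise_sigma_mV`` and correlation time ``noise_tau_ms``.
    """

    presyn_rate: float = 10.0
    psp_amp_mV: float = -0.5
    psp_tau_ms: float = 5.0
    noise_sigma_mV: float = 1.0
    noise_tau_ms: float = 5.0
    rest_mV: float = -60.0
    duration_s: float = 200.0
    fs: float = 10000.0
    seed: int = 0

    def __post_init__(self):
        if self.psp_tau_ms <= 0:
            raise ValueError("PSP decay constant must be positive")
        if self.presyn_rate < 0:
            raise ValueError("presynaptic rate must be nonnegative")


def _bandlimited_noise(n, fs, band, rng):
    """Unit-variance Gaussian noise band-limited with a zero-phase filter."""
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(3, (lo, hi), btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def make_shared_input_pair(spec: SharedInputSpec):
    """Generate the two-cell shared-input fixture.

    Returns (VmTraceSet, truth) where truth records the construction targets:
    expected fast R (= c), expected slow R (= cos of the phase offset
    difference), and the spec fields.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    common = _bandlimited_noise(n, spec.fs, spec.fast_band_hz, rng)
    c = spec.shared_fraction
    traces = []
    for off_deg in spec.phase_offsets_deg:
        indep = _bandlimited_noise(n, spec.fs, spec.fast_band_hz, rng)
        fast = spec.fast_sigma_mV * (np.sqrt(c) * common + np.sqrt(1 - c) * indep)
        slow = spec.slow_amp_mV * np.sin(
            2 * np.pi * spec.slow_freq_hz * t + np.radians(off_deg))
        traces.append(spec.rest_mV + slow + fast)
    vm = VmTraceSet(cell_ids=["cell_0", "cell_1"], fs=spec.fs,
                    potentials=np.array(traces))
    dphi = np.radians(spec.phase_offsets_deg[1] - spec.phase_offsets_deg[0])
    truth = {
        "expected_fast_R": c,
        "expected_slow_R": float(np.cos(dphi)),
        "spec": asdict(spec),
    }
    return vm, truth


def _von_mises_rate(theta, mu_rad, kappa, base, mod):
    # scaled so the phase-average of the modulated part is `mod` for any kappa,
    # and kappa=0 gives a flat rate
    dens = np.exp(kappa * np.cos(theta - mu_rad)) / i0(kappa)
    return base + mod * dens


def make_tuned_population(spec: TunedPopulationSpec):
    """Generate phase-tuned Poisson spike trains plus the reference rhythm.

    Returns (SpikeTrainSet, reference trace ndarray, truth). The reference
    is a unit-amplitude sinusoid at the rhythm frequency sampled at
    ``spec.fs``; its analytic-signal phase theta(t) = 2 pi f t - pi/2 drives
    the per-unit von Mises rate modulation.
    """
    n_units = spec.n_units
    if spec.preferred_phases_deg is None:
        prefs = np.linspace(0.0, 360.0, n_units, endpoint=False)
    else:
        prefs = np.asarray(spec.preferred_phases_deg, dtype=float)
        if prefs.size != n_units:
            raise ValueError("one preferred phase per unit required")
    kappas = np.broadcast_to(np.asarray(spec.kappas, dtype=float), (n_units,))
    if np.any(kappas < 0):
        raise ValueError("kappa must be nonnegative")
    T = spec.duration_s
    children = np.random.SeedSequence(spec.seed).spawn(n_units)
    trains = {}
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        mu = np.radians(prefs[i])
        kap = kappas[i]
        lam_max = spec.base_rate + spec.mod_rate * np.exp(kap) / i0(kap)
        n_cand = rng.poisson(lam_max * T)
        t_cand = np.sort(rng.uniform(0.0, T, size=n_cand))
        theta = 2 * np.pi * spec.rhythm_freq_hz * t_cand - np.pi / 2
        lam = _von_mises_rate(theta, mu, kap, spec.base_rate, spec.mod_rate)
        keep = rng.uniform(0.0, 1.0, size=n_cand) < lam / lam_max
        trains[f"unit_{i}"] = t_cand[keep]
    spikes = SpikeTrainSet(trains, interval=(0.0, T))
    t = np.arange(int(round(T * spec.fs))) / spec.fs
    reference = np.sin(2 * np.pi * spec.rhythm_freq_hz * t)
    truth = {
        "preferred_phases_deg": prefs.tolist(),
        "kappas": np.asarray(kappas).tolist(),
        "spec": asdict(spec),
    }
    return spikes, reference, truth


def make_connected_pair(spec: ConnectedPairSpec):
    """Generate the planted-connection fixture.

    Returns (VmTraceSet with one cell, presynaptic SpikeTrainSet, truth).
    The Vm is an OU background plus, for every presynaptic spike, a causal
    exponential PSP kernel of the planted amplitude and decay constant.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    dt = 1.0 / spec.fs
    # exact OU update
    a = np.exp(-dt / (spec.noise_tau_ms * 1e-3))
    innov = rng.standard_normal(n) * spec.noise_sigma_mV * np.sqrt(1 - a * a)
    innov[0] = rng.standard_normal() * spec.noise_sigma_mV  # stationary start
    noise = sps.lfilter([1.0], [1.0, -a], innov)
    n_spk = rng.poisson(spec.presyn_rate * spec.duration_s)
    spk = np.sort(rng.uniform(0.0, spec.duration_s, size=n_spk))
    # superpose causal exponential kernels via an impulse train + lfilter
    impulses = np.zeros(n)
    idx = np.floor(spk * spec.fs).astype(np.int64)
    np.add.at(impulses, idx[idx < n], 1.0)
    decay = np.exp(-dt / (spec.psp_tau_ms * 1e-3))
    psp = sps.lfilter([spec.psp_amp_mV], [1.0, -decay], impulses)
    vm = VmTraceSet(cell_ids=["post"], fs=spec.fs,
                    potentials=(spec.rest_mV + noise + psp)[None, :])
    spikes = SpikeTrainSet({"pre": spk}, interval=(0.0, spec.duration_s))
    truth = {
        "psp_amp_mV": spec.psp_amp_mV,
        "psp_tau_ms": spec.psp_tau_ms,
        "n_presyn_spikes": int(spk.size),
        "spec": asdict(spec),
    }
    return vm, spikes, truth
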