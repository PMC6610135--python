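"""Population spike-train analysis: kernel rates, slow/fast rate-correlation
matrices, Rayleigh rhythmicity screening and Hilbert-phase tuning histograms.

Spike trains are turned into rate traces by convolving the spike times with
Gaussian kernels — a narrow one (sigma = 5 ms) capturing fast, near-synchronous
discharge and a broad one (sigma = 150 ms) capturing the slow rate modulation.
After high-pass filtering (10 Hz fast, 0.3 Hz slow; 3-pole zero-phase
Butterworth) the pairwise Pearson matrices on the two timescales quantify the
same decoupling observable as the membrane-potential analysis: functionally
related units correlate on the slow matrix but, absent shared connections,
not on the fast one.

Rhythmicity of each unit relative to the motor rhythm is screened with the
Rayleigh test for circular uniformity: R is the mean resultant length of the
spike phases, z = N R^2, and

    p = exp( sqrt(1 + 4N + 4(N^2 - R_N^2)) - (1 + 2N) ),   R_N = R * N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .datatypes import SpikeTrainSet

__all__ = [
    "RateTrace",
    "RhythmicityResult",
    "kernel_rate",
    "rate_correlation_matrices",
    "rayleigh_test",
    "instantaneous_phase",
    "spike_triggered_phase_hist",
    "screen_rhythmic_units",
]

log = logging.getLogger(__name__)

SLOW_SIGMA_S = 0.150
FAST_SIGMA_S = 0.005
SLOW_HP_HZ = 0.3
FAST_HP_HZ = 10.0
KERNEL_TRUNC_SIGMAS = 5.0


@dataclass
class RateTrace:
    """Kernel-estimated firing rate (spikes/s) on a regular grid."""

    unit_id: object
    fs: float
    rate: np.ndarray
    sigma_s: float
    t0: float = 0.0

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.rate.size) / self.fs


@dataclass
class RhythmicityResult:
    """Rayleigh-test outcome for one unit."""

    unit_id: object
    n_spikes: int
    R: float
    R_N: float
    z: float
    p: float
    significant: bool
    preferred_phase_deg: float


def kernel_rate(spike_times, sigma_s: float, fs: float, interval) -> RateTrace:
    """Gaussian-kernel rate estimate: the sum over spikes of unit-area
    Gaussian bumps k(t) = exp(-t^2 / 2 sigma^2) / (sqrt(2 pi) sigma),
    evaluated exactly at the grid points (kernel truncated at +/-5 sigma).

    An empty train yields a zero trace.
    """
    if sigma_s <= 0:
        raise ValueError("kernel sigma must be positive")
    if fs <= 1.0 / sigma_s:
        raise ValueError(f"sampling rate {fs} Hz cannot resolve sigma={sigma_s}s")
    t0, t1 = interval
    n = int(round((t1 - t0) * fs))
    rate = np.zeros(n)
    times = np.asarray(spike_times, dtype=float)
    if times.size == 0:
        return RateTrace(None, fs, rate, sigma_s, t0)
    half = int(np.ceil(KERNEL_TRUNC_SIGMAS * sigma_s * fs))
    norm = 1.0 / (np.sqrt(2 * np.pi) * sigma_s)
    grid_idx = np.round((times - t0) * fs).astype(np.int64)
    offsets = np.arange(-half, half + 1)
    for t_spk, gi in zip(times, grid_idx):
        idx = gi + offsets
        ok = (idx >= 0) & (idx < n)
        tt = t0 + idx[ok] / fs
        rate[idx[ok]] += norm * np.exp(-((tt - t_spk) ** 2) / (2 * sigma_s ** 2))
    return RateTrace(None, fs, rate, sigma_s, t0)


def _highpass(x, cutoff, fs):
    sos = sps.butter(3, cutoff, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def rate_correlation_matrices(spike_set: SpikeTrainSet, fs: float = 1000.0):
    """Slow and fast pairwise rate-correlation matrices.

    Slow: sigma = 150 ms kernel, then 0.3 Hz high-pass. Fast: sigma = 5 ms
    kernel, then 10 Hz high-pass. Pearson correlation for all unit pairs.
    Units with zero spikes are excluded (logged).

    Returns (slow DataFrame, fast DataFrame), symmetric with unit diagonal,
    indexed by unit id.
    """
    import pandas as pd

    t0, t1 = spike_set.interval
    if not np.isfinite(t1):
        raise ValueError("spike set needs a finite recording interval")
    units = [u for u in spike_set.unit_ids if spike_set.trains[u].size > 0]
    dropped = [u for u in spike_set.unit_ids if spike_set.trains[u].size == 0]
    for u in dropped:
        log.warning("unit %r excluded from rate matrices: no spikes", u)
    if len(units) < 2:
        raise ValueError("need at least two units with spikes")
    mats = {}
    for label, sigma, cutoff in [("slow", SLOW_SIGMA_S, SLOW_HP_HZ),
                                 ("fast", FAST_SIGMA_S, FAST_HP_HZ)]:
        traces = np.array([
            _highpass(kernel_rate(spike_set.trains[u], sigma, fs, (t0, t1)).rate,
                      cutoff, fs)
            for u in units
        ])
        m = np.corrcoef(traces)
        np.fill_diagonal(m, 1.0)
        mats[label] = pd.DataFrame(m, index=units, columns=units)
    return mats["slow"], mats["fast"]


def rayleigh_test(phases, unit_id=None, alpha: float = 0.05) -> RhythmicityResult:
    """Rayleigh test for circular uniformity of spike phases (radians).

    R is the length of the mean unit vector of the phases, the test statistic
    is z = N R^2, and the p-value uses the standard large-N approximation
    (see module docstring). Significant at ``alpha`` means the unit is
    rhythmically locked to the reference.
    """
    ph = np.asarray(phases, dtype=float)
    ph = ph[np.isfinite(ph)]
    n = ph.size
    if n == 0:
        raise ValueError("no spikes with defined phase")
    vec = np.exp(1j * ph).mean()
    R = float(np.abs(vec))
    R_n = R * n
    z = n * R ** 2
    arg = 1.0 + 4.0 * n + 4.0 * (n ** 2 - R_n ** 2)
    p = float(np.exp(np.sqrt(max(arg, 0.0)) - (1.0 + 2.0 * n)))
    p = min(p, 1.0)
    pref = float(np.degrees(np.angle(vec)) % 360.0)
    return RhythmicityResult(
        unit_id=unit_id, n_spikes=n, R=R, R_N=R_n, z=float(z), p=p,
        significant=p < alpha, preferred_phase_deg=pref,
    )


def instantaneous_phase(
    reference,
    fs: float,
    activity_mask=None,
    smooth_sigma_s: float = 0.150,
    highpass_hz: float = 0.1,
) -> np.ndarray:
    """Instantaneous phase (radians, in (-pi, pi]) of a rhythmic reference
    signal (e.g. a nerve trace) via the analytic signal.

    The reference is smoothed with a Gaussian kernel (sigma = 150 ms),
    high-pass filtered at 0.1 Hz (3-pole zero-phase Butterworth) and
    Hilbert-transformed. Samples outside ``activity_mask`` (True = ongoing
    activity) are set to NaN; the mask defaults to everywhere-active.
    """
    x = np.asarray(reference, dtype=float)
    if x.size < 10:
        raise ValueError("reference trace too short")
    smoothed = gaussian_filter1d(x, smooth_sigma_s * fs)
    hp = _highpass(smoothed, highpass_hz, fs)
    phase = np.angle(sps.hilbert(hp))
    if activity_mask is not None:
        mask = np.asarray(activity_mask, dtype=bool)
        if mask.shape != phase.shape:
            raise ValueError("activity mask must match the reference length")
        if not mask.any():
            raise ValueError("empty-phase: no ongoing activity in mask")
        phase = np.where(mask, phase, np.nan)
    return phase


def _phases_at_spikes(spike_times, phase, fs, t0=0.0):
    idx = np.round((np.asarray(spike_times, dtype=float) - t0) * fs).astype(np.int64)
    idx = idx[(idx >= 0) & (idx < phase.size)]
    ph = phase[idx]
    return ph[np.isfinite(ph)]


def spike_triggered_phase_hist(
    spike_times,
    phase,
    fs: float,
    n_bins: int = 18,
    t0: float = 0.0,
):
    """Polar histogram of the reference phase at spike times.

    Returns (bin edges in degrees [0, 360], counts, preferred phase in
    degrees) with the preferred phase taken as the circular mean direction.
    """
    ph = _phases_at_spikes(spike_times, phase, fs, t0)
    if ph.size == 0:
        raise ValueError("empty histogram: no spikes with defined phase")
    deg = np.degrees(ph) % 360.0
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(deg, bins=edges)
    pref = float(np.degrees(np.angle(np.exp(1j * ph).mean())) % 360.0)
    return edges, counts, pref


def screen_rhythmic_units(
    spike_set: SpikeTrainSet,
    phase,
    fs: float,
    alpha: float = 0.05,
    bonferroni: bool = False,
    t0: float = 0.0,
):
    """Partition units into rhythmic and non-rhythmic by the Rayleigh test.

    Units whose spike phases are consistent with circular uniformity at
    level ``alpha`` (optionally Bonferroni-corrected across units) are
    excluded from the correlation-matrix analyses, as are units with no
    spikes in active epochs.

    Returns (included ids, excluded dict id -> reason, results list).
    """
    level = alpha / spike_set.n_units if bonferroni else alpha
    included, excluded, results = [], {}, []
    for u in spike_set.unit_ids:
        ph = _phases_at_spikes(spike_set.trains[u], np.asarray(phase, float), fs, t0)
        if ph.size == 0:
            excluded[u] = "no spikes"
            continue
        res = rayleigh_test(ph, unit_id=u, alpha=level)
        results.append(res)
        if res.significant:
            included.append(u)
        else:
            excluded[u] = f"not rhythmic (p={res.p:.3g})"
    log.info("rhythmicity screen: %d included, %d excluded of %d units",
             len(included), len(excluded), spike_set.n_units)
    return included, excluded, results
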