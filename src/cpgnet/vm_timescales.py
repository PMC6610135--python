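"""Two-timescale decomposition and correlation analysis of membrane potentials.

The membrane potential of a rhythmically driven neuron carries information on
two timescales: a slow component (0.2-5 Hz band) reflecting the rate
modulation of its synaptic drive, and a fast component (>5 Hz) reflecting the
individual synaptic potentials. Strong slow correlation between two cells
marks them as functionally related (same module); strong fast correlation
requires actually shared presynaptic partners. Comparing the two — slow R
versus fast R per pair, against a shuffle null — is how the wiring of the
common-drive network is inferred from pairwise recordings.

Filtering follows the published analysis: 3-pole Butterworth applied forward
and backward (zero phase), 5 Hz high-pass for the fast signal and 0.2-5 Hz
band-pass for the slow signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "TimescaleSplit",
    "CorrelationSummary",
    "PairPhase",
    "remove_action_potentials",
    "decompose",
    "pearson",
    "sliding_correlation",
    "shuffle_null",
    "pair_phase",
    "fastcorr_rate_dependence",
    "rate_dependence_population",
    "quiescence_mask",
    "summarize_pair",
]

SLOW_BAND = (0.2, 5.0)
FAST_CUTOFF = 5.0
FILTER_ORDER = 3


@dataclass
class TimescaleSplit:
    """Slow (band-passed) and fast (high-passed) components of one trace."""

    slow: np.ndarray
    fast: np.ndarray
    filter_desc: dict = field(default_factory=dict)


@dataclass
class PairPhase:
    """Phase lag between two rhythmic slow traces."""

    phase_deg: float
    period_s: float


@dataclass
class CorrelationSummary:
    """Per-pair two-timescale correlation summary."""

    slow_R: float
    fast_R: float
    null_mean: float
    null_sigma: float
    conf_limits: tuple
    fast_R_active: float | None = None
    phase_deg: float | None = None
    zero_lag_times: np.ndarray | None = None
    zero_lag_trace: np.ndarray | None = None
    correlogram: np.ndarray | None = None
    lags_s: np.ndarray | None = None
    quiescent_fraction: float = 0.0

    @property
    def significant(self) -> bool:
        lo, hi = self.conf_limits
        return not (lo <= self.fast_R <= hi)


def remove_action_potentials(vm: np.ndarray, z: float = 5.0) -> np.ndarray:
    """Clip spike excursions: samples beyond mean + z*SD are replaced by
    linear interpolation from the neighbouring sub-threshold samples."""
    vm = np.asarray(vm, dtype=float)
    mu, sd = vm.mean(), vm.std()
    if sd == 0:
        return vm.copy()
    bad = vm > mu + z * sd
    if not bad.any():
        return vm.copy()
    out = vm.copy()
    idx = np.arange(vm.size)
    out[bad] = np.interp(idx[bad], idx[~bad], vm[~bad])
    return out


def _sos(kind, cutoff, fs):
    return sps.butter(FILTER_ORDER, cutoff, btype=kind, fs=fs, output="sos")


def decompose(vm, fs: float) -> TimescaleSplit:
    """Split a membrane-potential trace into slow (0.2-5 Hz band-pass) and
    fast (>5 Hz high-pass) components with zero-phase Butterworth filters.

    The trace must be free of action potentials (see
    :func:`remove_action_potentials`); ``fs`` must comfortably exceed twice
    the 5 Hz cutoff and the trace must span at least three periods of the
    slowest band edge for the band-pass to be meaningful.
    """
    vm = np.asarray(vm, dtype=float)
    if fs <= 2 * FAST_CUTOFF * 2:
        raise ValueError(f"sampling rate {fs} Hz too low for a {FAST_CUTOFF} Hz cutoff")
    min_len = int(3 * fs / SLOW_BAND[0])
    if vm.size < min_len:
        raise ValueError(
            f"trace of {vm.size} samples shorter than 3 periods of the "
            f"{SLOW_BAND[0]} Hz band edge ({min_len} samples)"
        )
    slow = sps.sosfiltfilt(_sos("bandpass", SLOW_BAND, fs), vm)
    fast = sps.sosfiltfilt(_sos("highpass", FAST_CUTOFF, fs), vm)
    return TimescaleSplit(
        slow=slow,
        fast=fast,
        filter_desc={
            "order": FILTER_ORDER,
            "slow_band_hz": SLOW_BAND,
            "fast_cutoff_hz": FAST_CUTOFF,
            "bidirectional": True,
        },
    )


def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length arrays of at least 2 samples")
    xd = x - x.mean()
    yd = y - y.mean()
    den = np.sqrt((xd * xd).sum()) * np.sqrt((yd * yd).sum())
    if den == 0:
        raise ValueError("undefined correlation: zero variance")
    return float((xd * yd).sum() / den)


def _rolling_pearson(x, y, win: int, starts: np.ndarray) -> np.ndarray:
    """Pearson R over windows x[s:s+win] vs y[s:s+win] for each start s,
    via cumulative sums (O(T) regardless of the number of windows)."""
    n = min(x.size, y.size)
    x, y = x[:n], y[:n]
    cs = lambda a: np.concatenate(([0.0], np.cumsum(a)))
    cx, cy = cs(x), cs(y)
    cxx, cyy, cxy = cs(x * x), cs(y * y), cs(x * y)
    e = starts + win
    sx = cx[e] - cx[starts]
    sy = cy[e] - cy[starts]
    sxx = cxx[e] - cxx[starts]
    syy = cyy[e] - cyy[starts]
    sxy = cxy[e] - cxy[starts]
    num = win * sxy - sx * sy
    var_x = win * sxx - sx * sx
    var_y = win * syy - sy * sy
    den = np.sqrt(np.maximum(var_x, 0.0) * np.maximum(var_y, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.clip(r, -1.0, 1.0)


def sliding_correlation(
    fast_x,
    fast_y,
    fs: float,
    window_s: float = 0.4,
    step_s: float = 0.01,
    max_lag_s: float = 0.1,
):
    """Time-resolved pairwise correlation of the fast components.

    Pearson R is computed in a sliding window (default 400 ms) moving in
    steps of ``step_s``, for every lag of y relative to x up to
    ``max_lag_s``, yielding a (window, lag) correlogram plus the zero-lag
    trace used in the rate-dependence analysis.

    Returns
    -------
    times : window-centre times (s)
    lags : lag axis (s), positive = y delayed relative to x
    correlogram : (n_windows, n_lags) Pearson R
    zero_lag : (n_windows,) R at zero lag
    """
    x = np.asarray(fast_x, dtype=float)
    y = np.asarray(fast_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("traces must have equal length")
    win = int(round(window_s * fs))
    if win < 10:
        raise ValueError(f"degenerate window: {win} samples")
    if win >= x.size:
        raise ValueError("window longer than trace")
    step = max(1, int(round(step_s * fs)))
    max_lag = int(round(max_lag_s * fs))
    starts = np.arange(max_lag, x.size - win - max_lag + 1, step)
    if starts.size == 0:
        raise ValueError("trace too short for the requested window and lag range")
    lags = np.arange(-max_lag, max_lag + 1)
    correlogram = np.empty((starts.size, lags.size))
    for j, lag in enumerate(lags):
        correlogram[:, j] = _rolling_pearson(x[max_lag:], y[max_lag + lag:],
                                             win, starts - max_lag)
    zero_lag = correlogram[:, max_lag]
    times = (starts + win / 2) / fs
    return times, lags / fs, correlogram, zero_lag


def shuffle_null(
    x,
    y,
    fs: float,
    n_shuffles: int = 200,
    shift_range_s: tuple = (0.5, 2.0),
    seed=0,
):
    """Shuffle null for the pairwise correlation.

    One trace is circularly shifted by an offset drawn uniformly from
    ``shift_range_s`` for each shuffle and the Pearson R recomputed; the 95%
    confidence limits are mean +/- 1.96 sigma of the resulting distribution.

    Returns (null mean, null sigma, (lower, upper), null samples).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lo, hi = (int(round(s * fs)) for s in shift_range_s)
    if hi >= x.size:
        raise ValueError("shift range exceeds trace length")
    if lo < 1 or hi < lo:
        raise ValueError("invalid shift range")
    rng = np.random.default_rng(seed)
    shifts = rng.integers(lo, hi + 1, size=n_shuffles)
    null = np.array([pearson(x, np.roll(y, s)) for s in shifts])
    mu, sigma = float(null.mean()), float(null.std(ddof=1))
    return mu, sigma, (mu - 1.96 * sigma, mu + 1.96 * sigma), null


def _dominant_frequency(trace, fs: float, fmin: float = 0.05):
    f, pxx = sps.periodogram(trace, fs=fs)
    sel = f >= fmin
    f, pxx = f[sel], pxx[sel]
    if pxx.sum() == 0:
        return None, 0.0
    i = int(np.argmax(pxx))
    return float(f[i]), float(pxx[i] / pxx.sum())


def pair_phase(slow_x, slow_y, fs: float, rhythm_floor: float = 0.2) -> PairPhase:
    """Phase lag between two rhythmic slow components, from the location of
    the peak of their cross-correlation function, in degrees of the dominant
    oscillation period.

    Both traces must be rhythmic: the dominant spectral peak must carry at
    least ``rhythm_floor`` of total power above 0.05 Hz.
    """
    x = np.asarray(slow_x, dtype=float)
    y = np.asarray(slow_y, dtype=float)
    fx, px = _dominant_frequency(x, fs)
    fy, py = _dominant_frequency(y, fs)
    if fx is None or fy is None or px < rhythm_floor or py < rhythm_floor:
        raise ValueError("undefined phase: traces are not rhythmic")
    period = 2.0 / (fx + fy)
    xc = sps.correlate(y - y.mean(), x - x.mean(), mode="full")
    lags = sps.correlation_lags(y.size, x.size, mode="full") / fs
    # restrict to one period around zero so the wrapped phase is unambiguous
    sel = np.abs(lags) <= period / 2
    lag = lags[sel][np.argmax(xc[sel])]
    phase = (lag / period * 360.0) % 360.0
    return PairPhase(phase_deg=float(phase), period_s=float(period))


def fastcorr_rate_dependence(
    zero_lag_times,
    zero_lag_trace,
    lowpass_vm,
    fs_vm: float,
    n_shuffles: int = 100,
    seed=0,
):
    """Correlation between the time-resolved fast correlation of a pair and
    the slow (low-pass) membrane potential.

    Under active decorrelation the fast correlation is suppressed when the
    drive (and hence Vm) is high, so this dependence R is negative; without
    rate dependence it scatters around zero. The shuffle distribution is
    built by circularly shifting the zero-lag trace relative to the Vm.

    Returns (dependence R, shuffled R array).
    """
    t = np.asarray(zero_lag_times, dtype=float)
    z = np.asarray(zero_lag_trace, dtype=float)
    v = np.asarray(lowpass_vm, dtype=float)
    if t.shape != z.shape:
        raise ValueError("zero-lag trace and times must align")
    v_at = np.interp(t, np.arange(v.size) / fs_vm, v)
    ok = np.isfinite(z)
    z, v_at = z[ok], v_at[ok]
    if z.size < 10:
        raise ValueError("too few valid windows after resampling")
    r_obs = pearson(z, v_at)
    rng = np.random.default_rng(seed)
    shifts = rng.integers(1, z.size, size=n_shuffles)
    r_null = np.array([pearson(np.roll(z, s), v_at) for s in shifts])
    return r_obs, r_null


def rate_dependence_population(observed_R, shuffled_R):
    """Two-sample Kolmogorov-Smirnov comparison between the population of
    per-pair dependence correlations and the pooled shuffle distribution.

    Returns (KS statistic, p-value, mean observed R, mean shuffled R).
    """
    from scipy.stats import ks_2samp

    obs = np.asarray(observed_R, dtype=float)
    nul = np.asarray(shuffled_R, dtype=float)
    res = ks_2samp(obs, nul)
    return float(res.statistic), float(res.pvalue), float(obs.mean()), float(nul.mean())


def quiescence_mask(slow, fs: float, threshold: float = 0.1,
                    epoch_s: float = 1.0) -> np.ndarray:
    """Boolean mask of quiescent epochs (True = quiescent).

    An epoch is quiescent when the RMS of the slow component within it falls
    below ``threshold`` times the whole-trace slow RMS.
    """
    s = np.asarray(slow, dtype=float)
    global_rms = np.sqrt(np.mean(s * s))
    n = max(1, int(round(epoch_s * fs)))
    mask = np.zeros(s.size, dtype=bool)
    if global_rms == 0:
        return ~mask  # all quiescent
    for start in range(0, s.size, n):
        seg = s[start:start + n]
        if np.sqrt(np.mean(seg * seg)) < threshold * global_rms:
            mask[start:start + n] = True
    if mask.all():
        import warnings

        warnings.warn("no active epochs found; fast correlation will be "
                      "computed on the full trace", stacklevel=2)
    return mask


def summarize_pair(
    vm_x,
    vm_y,
    fs: float,
    n_shuffles: int = 200,
    seed=0,
    with_phase: bool = True,
    with_correlogram: bool = False,
) -> CorrelationSummary:
    """Full two-timescale summary for one pair of membrane-potential traces:
    slow/fast Pearson R, shuffle-null confidence limits, quiescence-excluded
    fast R, phase lag, and (optionally) the sliding correlogram."""
    x = remove_action_potentials(vm_x)
    y = remove_action_potentials(vm_y)
    dx = decompose(x, fs)
    dy = decompose(y, fs)
    slow_R = pearson(dx.slow, dy.slow)
    fast_R = pearson(dx.fast, dy.fast)
    mu, sigma, limits, _ = shuffle_null(dx.fast, dy.fast, fs,
                                        n_shuffles=n_shuffles, seed=seed)
    quiet = quiescence_mask(dx.slow, fs) | quiescence_mask(dy.slow, fs)
    active = ~quiet
    fast_R_active = pearson(dx.fast[active], dy.fast[active]) if active.sum() > 2 \
        else None
    phase = None
    if with_phase:
        try:
            phase = pair_phase(dx.slow, dy.slow, fs).phase_deg
        except ValueError:
            phase = None
    times = trace = gram = lags = None
    if with_correlogram:
        times, lags, gram, trace = sliding_correlation(dx.fast, dy.fast, fs)
    return CorrelationSummary(
        slow_R=slow_R,
        fast_R=fast_R,
        null_mean=mu,
        null_sigma=sigma,
        conf_limits=limits,
        fast_R_active=fast_R_active,
        phase_deg=phase,
        zero_lag_times=times,
        zero_lag_trace=trace,
        correlogram=gram,
        lags_s=lags,
        quiescent_fraction=float(quiet.mean()),
    )
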