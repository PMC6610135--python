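"""Conductance-based leaky-integrator network simulation.

Receivers are leaky integrate-and-fire cells with spiking disabled (pure
subthreshold integrators), driven through exponentially decaying
conductance-based synapses by an uncorrelated population of inhomogeneous
Poisson sources whose rate is modulated by a 1 Hz sinusoid (the imitated
motor rhythm). Optionally a local inhibitory interneuron pool (identical
membrane but with spiking enabled at -50 mV) provides feedforward or
recurrent inhibition — the active-decorrelation motifs.

Membrane dynamics (units: pF, nS, mV, ms):

    C dV/dt = -g_L (V - E_L) - g_e(t) (V - E_e) - g_i(t) (V - E_i)

Each presynaptic spike increments its synapse's conductance by the peak
value; conductances decay exponentially with tau_syn. Integration uses
exponential Euler for the conductances and forward Euler for the voltage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._util import as_seedseq
from .datatypes import SpikeTrainSet, VmTraceSet
from .topology import MotifSpec, NetworkTopology, build_motif

__all__ = [
    "CellParams",
    "SynapseParams",
    "DriveParams",
    "SimulationConfig",
    "sample_inhomogeneous_poisson",
    "simulate",
    "run_size_sweep",
    "run_motif_comparison",
    "FIG2_CELL",
    "FIG2_SYNAPSE",
    "FIG2_DRIVE",
    "MOTIF_CELL",
    "MOTIF_SYNAPSE",
    "MOTIF_DRIVE",
]


@dataclass(frozen=True)
class CellParams:
    """Leaky integrator membrane parameters (paper's receiver/interneuron cell)."""

    capacitance_pF: float = 250.0
    leak_nS: float = 16.67
    rest_mV: float = -60.0
    threshold_mV: float | None = None  # None = spiking disabled (receivers)
    reset_mV: float = -60.0
    refractory_ms: float = 2.0

    def __post_init__(self):
        if self.capacitance_pF <= 0 or self.leak_nS <= 0:
            raise ValueError("capacitance and leak conductance must be positive")
        if self.threshold_mV is not None and self.threshold_mV <= self.reset_mV:
            raise ValueError("spike threshold must exceed reset potential")


@dataclass(frozen=True)
class SynapseParams:
    """Exponentially decaying conductance synapses."""

    tau_ms: float = 1.0
    e_exc_mV: float = 0.0
    e_inh_mV: float = -80.0
    g_exc_nS: float = 10.0
    g_inh_nS: float = 10.0
    # short local-circuit delay: inhibitory feedback can only cancel shared
    # fluctuations it still tracks, so the loop delay must stay well below
    # the membrane timescale (see docs/methods.md)
    delay_ms: float = 0.5

    def __post_init__(self):
        if self.tau_ms <= 0:
            raise ValueError("synaptic decay constant must be positive")
        if not self.e_inh_mV < self.e_exc_mV:
            raise ValueError("inhibitory reversal must lie below excitatory")
        if self.delay_ms <= 0:
            raise ValueError("transmission delay must be positive")


@dataclass(frozen=True)
class DriveParams:
    """Sinusoidally modulated Poisson drive: lambda(t) = max(0, r0 + r1 sin(2 pi f t))."""

    r0: float = 12.0
    r1: float = 10.0
    f_hz: float = 1.0
    duration_s: float = 60.0

    def __post_init__(self):
        if self.r0 < 0:
            raise ValueError("mean rate must be nonnegative")
        if self.duration_s <= 0:
            raise ValueError("invalid duration")

    def rate(self, t):
        """Instantaneous rate, clipped at zero."""
        return np.maximum(0.0, self.r0 + self.r1 * np.sin(2 * np.pi * self.f_hz * t))

    @property
    def rate_max(self) -> float:
        return max(0.0, self.r0 + max(0.0, self.r1))


# Parameter sets of the two published simulation regimes: the size-sweep
# configuration (10 nS excitation, 12 +/- 10 spikes/s drive) and the motif /
# decorrelation configuration (5 nS exc / 15 nS inh, 80 +/- 70 spikes/s,
# 100 receivers and 100 interneurons).
FIG2_CELL = CellParams()
FIG2_SYNAPSE = SynapseParams(g_exc_nS=10.0)
FIG2_DRIVE = DriveParams(r0=12.0, r1=10.0, f_hz=1.0, duration_s=60.0)

MOTIF_CELL = CellParams()
# interneurons must keep tracking the drive at its cycle peaks (200+ spikes/s)
# for inhibitory feedback to cancel shared input there; a long absolute
# refractory rate-limits them exactly where decorrelation matters most
MOTIF_INH_CELL = CellParams(threshold_mV=-50.0, refractory_ms=0.5)
MOTIF_SYNAPSE = SynapseParams(g_exc_nS=5.0, g_inh_nS=15.0)
MOTIF_DRIVE = DriveParams(r0=80.0, r1=70.0, f_hz=1.0, duration_s=30.0)


@dataclass
class SimulationConfig:
    """Everything needed to rerun a simulation: membrane, synapse, drive,
    motif and integration parameters plus the seed."""

    cell: CellParams
    synapse: SynapseParams
    drive: DriveParams
    motif: MotifSpec | None = None
    inh_cell: CellParams | None = None
    dt_ms: float = 0.1
    record_fs: float = 1000.0
    seed: int = 0


def sample_inhomogeneous_poisson(drive: DriveParams, n_units: int, seed) -> SpikeTrainSet:
    """Independent inhomogeneous Poisson realizations by thinning.

    Candidate spikes are drawn from a homogeneous process at rate
    ``r0 + r1`` and kept with probability lambda(t) / lambda_max, which is
    exact for any bounded rate profile. Each unit gets its own child seed so
    trains are reproducible and independent.
    """
    if n_units < 1:
        raise ValueError("need at least one unit")
    lam_max = drive.rate_max
    T = drive.duration_s
    trains = {}
    children = as_seedseq(seed).spawn(n_units)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        if lam_max == 0:
            trains[f"src_{i}"] = np.empty(0)
            continue
        n_cand = rng.poisson(lam_max * T)
        t_cand = np.sort(rng.uniform(0.0, T, size=n_cand))
        keep = rng.uniform(0.0, 1.0, size=n_cand) < drive.rate(t_cand) / lam_max
        trains[f"src_{i}"] = t_cand[keep]
    return SpikeTrainSet(trains, interval=(0.0, T))


# ---------------------------------------------------------------------------
# stepping kernel (numba-jitted when available)
# ---------------------------------------------------------------------------

def _integrate_core(
    T_steps, dt,
    inc_rec, inc_inh,            # (T, n_rec), (T, n_inh) float32 exc spike counts
    W_ir, W_ii,                  # (n_rec, n_inh), (n_inh, n_inh) float64 adjacency
    C_m, g_L, E_L, E_e, E_i,
    g_exc, g_inh, decay,
    V_th, V_reset, ref_steps, delay_steps,
    rec_stride, V_rec_out, inh_raster,
):
    n_rec = inc_rec.shape[1]
    n_inh = inc_inh.shape[1]
    V_r = np.full(n_rec, E_L)
    V_i = np.full(n_inh, E_L)
    g_er = np.zeros(n_rec)
    g_ir = np.zeros(n_rec)
    g_ei = np.zeros(n_inh)
    g_ii = np.zeros(n_inh)
    refr = np.zeros(n_inh, dtype=np.int64)
    buf = np.zeros((delay_steps, n_inh))
    k_rec = 0
    for t in range(T_steps):
        if n_inh > 0:
            slot = t % delay_steps
            sp_delayed = buf[slot].copy()
            buf[slot] = 0.0
            g_ir += g_inh * np.dot(W_ir, sp_delayed)
            g_ii += g_inh * np.dot(W_ii, sp_delayed)
            g_ei += g_exc * inc_inh[t]
        g_er += g_exc * inc_rec[t]
        # forward-Euler voltage update
        V_r += (dt / C_m) * (
            -g_L * (V_r - E_L) - g_er * (V_r - E_e) - g_ir * (V_r - E_i)
        )
        if n_inh > 0:
            dV = (dt / C_m) * (
                -g_L * (V_i - E_L) - g_ei * (V_i - E_e) - g_ii * (V_i - E_i)
            )
            for i in range(n_inh):
                if refr[i] > 0:
                    refr[i] -= 1
                    V_i[i] = V_reset
                else:
                    V_i[i] += dV[i]
                    if V_i[i] >= V_th:
                        V_i[i] = V_reset
                        refr[i] = ref_steps
                        buf[t % delay_steps, i] += 1.0
                        inh_raster[t, i] = True
        # exponential-Euler conductance decay
        g_er *= decay
        g_ir *= decay
        g_ei *= decay
        g_ii *= decay
        if t % rec_stride == 0:
            if k_rec < V_rec_out.shape[1]:
                V_rec_out[:, k_rec] = V_r
                k_rec += 1
    return k_rec


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _integrate = njit(cache=False)(_integrate_core)
except Exception:  # pragma: no cover
    _integrate = _integrate_core


def _pooled_counts(spike_set: SpikeTrainSet, topology: NetworkTopology,
                   dt_s: float, n_steps: int) -> np.ndarray:
    """Per-receiver binned counts of pooled presynaptic spikes, (T, n_recv)."""
    unit_ids = spike_set.unit_ids
    out = np.zeros((n_steps, topology.n_receiver), dtype=np.float32)
    for j in range(topology.n_receiver):
        srcs = topology.sources_of(j)
        times = np.concatenate([spike_set.trains[unit_ids[s]] for s in srcs]) \
            if srcs.size else np.empty(0)
        if times.size:
            idx = np.floor(times / dt_s).astype(np.int64)
            idx = idx[(idx >= 0) & (idx < n_steps)]
            out[:, j] = np.bincount(idx, minlength=n_steps)
    return out


def simulate(
    cell: CellParams,
    synapse: SynapseParams,
    topologies: dict | NetworkTopology,
    drive: DriveParams,
    dt_ms: float = 0.1,
    seed=0,
    inh_cell: CellParams | None = None,
    record_fs: float = 1000.0,
    source_spikes: SpikeTrainSet | None = None,
):
    """Run one network simulation.

    Parameters
    ----------
    topologies : NetworkTopology or dict
        A bare drive->receiver topology, or the dict produced by
        :func:`cpgnet.topology.build_motif` (keys ``drive_to_receiver`` and
        optionally ``drive_to_inh``, ``inh_to_receiver``, ``inh_to_inh``).
    source_spikes : SpikeTrainSet, optional
        Pre-sampled drive spike trains; sampled from ``drive`` when omitted.

    Returns
    -------
    vm : VmTraceSet
        Receiver membrane potentials at ``record_fs``.
    spikes : SpikeTrainSet
        Source (and, if present, interneuron) spike trains.
    """
    if isinstance(topologies, NetworkTopology):
        topologies = {"drive_to_receiver": topologies}
    if "drive_to_receiver" not in topologies:
        raise ValueError("wiring error: drive_to_receiver topology required")
    if dt_ms > 0.1 * synapse.tau_ms:
        raise ValueError(
            f"stability error: dt={dt_ms} ms exceeds 0.1*tau_syn={0.1 * synapse.tau_ms} ms"
        )
    top_dr = topologies["drive_to_receiver"]
    top_di = topologies.get("drive_to_inh")
    top_ir = topologies.get("inh_to_receiver")
    top_ii = topologies.get("inh_to_inh")
    if (top_di is None) != (top_ir is None):
        raise ValueError("wiring error: feedforward inhibition needs both "
                         "drive_to_inh and inh_to_receiver")
    n_rec = top_dr.n_receiver
    n_inh = top_di.n_receiver if top_di is not None else 0
    if top_di is not None and top_di.n_source != top_dr.n_source:
        raise ValueError("wiring error: inconsistent source population size")
    if top_ir is not None and (top_ir.n_source != n_inh or top_ir.n_receiver != n_rec):
        raise ValueError("wiring error: inh_to_receiver size mismatch")
    if top_ii is not None and (top_ii.n_source != n_inh or top_ii.n_receiver != n_inh):
        raise ValueError("wiring error: inh_to_inh size mismatch")
    if n_inh > 0 and inh_cell is None:
        inh_cell = MOTIF_INH_CELL
    if n_inh > 0 and inh_cell.threshold_mV is None:
        raise ValueError("interneurons need a spike threshold")

    dt_s = dt_ms * 1e-3
    n_steps = int(round(drive.duration_s / dt_s))
    rec_stride = max(1, int(round(1.0 / (record_fs * dt_s))))
    n_rec_samples = (n_steps + rec_stride - 1) // rec_stride

    ss = as_seedseq(seed)
    if source_spikes is None:
        source_spikes = sample_inhomogeneous_poisson(
            drive, top_dr.n_source, ss.spawn(1)[0])

    inc_rec = _pooled_counts(source_spikes, top_dr, dt_s, n_steps)
    if n_inh > 0:
        inc_inh = _pooled_counts(source_spikes, top_di, dt_s, n_steps)
        W_ir = top_ir.adjacency().T.astype(np.float64)  # (n_rec, n_inh)
        if top_ii is not None:
            W_ii = top_ii.adjacency().T.astype(np.float64)
        else:
            W_ii = np.zeros((n_inh, n_inh))
        inh_raster = np.zeros((n_steps, n_inh), dtype=np.bool_)
    else:
        inc_inh = np.zeros((n_steps, 0), dtype=np.float32)
        W_ir = np.zeros((n_rec, 0))
        W_ii = np.zeros((0, 0))
        inh_raster = np.zeros((n_steps, 0), dtype=np.bool_)

    V_out = np.empty((n_rec, n_rec_samples))
    decay = float(np.exp(-dt_ms / synapse.tau_ms))
    delay_steps = max(1, int(round(synapse.delay_ms / dt_ms)))
    ref_steps = int(round((inh_cell.refractory_ms if inh_cell else 2.0) / dt_ms))

    k_rec = _integrate(
        n_steps, dt_ms, inc_rec, inc_inh, W_ir, W_ii,
        cell.capacitance_pF, cell.leak_nS, cell.rest_mV,
        synapse.e_exc_mV, synapse.e_inh_mV,
        synapse.g_exc_nS, synapse.g_inh_nS, decay,
        (inh_cell.threshold_mV if n_inh > 0 else 0.0),
        (inh_cell.reset_mV if n_inh > 0 else 0.0),
        ref_steps, delay_steps, rec_stride, V_out, inh_raster,
    )
    V_out = V_out[:, :k_rec]

    vm = VmTraceSet(
        cell_ids=[f"recv_{j}" for j in range(n_rec)],
        fs=1.0 / (rec_stride * dt_s),
        potentials=V_out,
    )
    trains = dict(source_spikes.trains)
    if n_inh > 0:
        t_idx, unit_idx = np.nonzero(inh_raster)
        for i in range(n_inh):
            trains[f"inh_{i}"] = t_idx[unit_idx == i] * dt_s
    spikes = SpikeTrainSet(trains, interval=(0.0, drive.duration_s))
    return vm, spikes


# ---------------------------------------------------------------------------
# higher-level experiments
# ---------------------------------------------------------------------------

def _pairwise_fast_slow(vm: VmTraceSet):
    """Pairwise Pearson R of fast/slow Vm components.

    Returns (fast pair R, slow pair R, fast correlation matrix) with the pair
    vectors taken from the upper triangle.
    """
    from .vm_timescales import decompose

    fast = np.empty_like(vm.potentials)
    slow = np.empty_like(vm.potentials)
    for i in range(vm.n_cells):
        split = decompose(vm.potentials[i], vm.fs)
        fast[i] = split.fast
        slow[i] = split.slow
    iu = np.triu_indices(vm.n_cells, k=1)
    fast_mat = np.corrcoef(fast)
    return fast_mat[iu], np.corrcoef(slow)[iu], fast_mat


def run_size_sweep(
    source_sizes,
    k: int = 10,
    seeds=(0, 1, 2),
    n_receiver: int = 30,
    cell: CellParams = FIG2_CELL,
    synapse: SynapseParams = FIG2_SYNAPSE,
    drive: DriveParams = FIG2_DRIVE,
    dt_ms: float = 0.1,
):
    """Vary the source-population size at constant in-degree and measure the
    mean pairwise fast-component correlation of the receivers.

    Returns a DataFrame with one row per size: n, rho, predicted k/n, mean
    fast R (over pairs and seeds), sd across seeds, mean slow R.
    """
    import pandas as pd

    from .topology import build_fixed_indegree, predicted_correlation, sparseness

    rows = []
    for n in source_sizes:
        if n < k:
            raise ValueError(f"source size {n} below in-degree {k}")
        seed_means, seed_means_slow = [], []
        for s in seeds:
            ss = np.random.SeedSequence([int(s), int(n)])
            top_seed, sim_seed = ss.spawn(2)
            top = build_fixed_indegree(n, n_receiver, k, top_seed)
            vm, _ = simulate(cell, synapse, top, drive, dt_ms=dt_ms, seed=sim_seed)
            fast_r, slow_r, _ = _pairwise_fast_slow(vm)
            seed_means.append(fast_r.mean())
            seed_means_slow.append(slow_r.mean())
        rows.append({
            "n_source": n,
            "sparseness": sparseness(top),
            "predicted_R": predicted_correlation(k, n),
            "fast_R_mean": float(np.mean(seed_means)),
            "fast_R_sd": float(np.std(seed_means, ddof=1)) if len(seeds) > 1 else 0.0,
            "slow_R_mean": float(np.mean(seed_means_slow)),
        })
    return pd.DataFrame(rows)


def run_motif_comparison(
    motifs: dict,
    drive: DriveParams = MOTIF_DRIVE,
    seeds=(0, 1, 2, 3, 4),
    cell: CellParams = MOTIF_CELL,
    inh_cell: CellParams = MOTIF_INH_CELL,
    synapse: SynapseParams = MOTIF_SYNAPSE,
    dt_ms: float = 0.1,
):
    """Simulate each motif over several seeds and collect receiver-pair
    fast-component correlations.

    Parameters
    ----------
    motifs : dict of name -> MotifSpec

    Returns
    -------
    dict of name -> dict with keys ``pair_R`` (pooled pair correlations),
    ``per_seed_mean`` (per-seed mean pair correlation) and ``matrix``
    (pair correlation matrix of the last seed).
    """
    out = {}
    for name, spec in motifs.items():
        pooled, per_seed = [], []
        matrix = None
        for s in seeds:
            graphs = build_motif(spec, np.random.SeedSequence([int(s), 17]))
            vm, _ = simulate(cell, synapse, graphs, drive, dt_ms=dt_ms,
                             seed=np.random.SeedSequence([int(s), 23]),
                             inh_cell=inh_cell)
            fast_r, _, matrix = _pairwise_fast_slow(vm)
            pooled.append(fast_r)
            per_seed.append(fast_r.mean())
        out[name] = {
            "pair_R": np.concatenate(pooled),
            "per_seed_mean": np.array(per_seed),
            "matrix": matrix,
        }
    return out
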