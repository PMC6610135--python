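# Methods

## The inference problem

During rhythmic motor behaviour most spinal neurons receive an oscillatory
synaptic drive. Whether that drive comes from a small, densely divergent
common-drive network or a large, sparsely convergent one cannot be read from
a single recording — but it leaves a signature in *pairs*: receivers wired to
the same small source pool share many presynaptic partners and therefore show
correlated synaptic fluctuations on the fast (>5 Hz) timescale, while
receivers sampling a large pool share almost none, so only the slow rate
modulation (0.2–5 Hz) correlates. `cpgnet` implements both sides of this
argument: a simulator that generates membrane potentials under controlled
wiring, and the analysis pipeline that measures the two-timescale correlation
structure in such data.

## Network model

A source population of `n₁` units fires as independent inhomogeneous Poisson
processes with rate `λ(t) = max(0, r₀ + r₁ sin(2πft))` (thinning against
`λ_max = r₀ + r₁`, exact for bounded rates). Each of `n₂` receivers draws a
fixed number `k` of distinct sources uniformly at random (constant
in-degree). Graph density is `ξ = k/n₁`, sparseness `ρ = 1 − ξ`, and the
expected shared-input fraction of a receiver pair — hence the expected
fast-timescale correlation — is `k/n₁` (the pair overlap is hypergeometric
with mean `k²/n₁`).

Receivers are conductance-based leaky integrators with spiking disabled:

    C dV/dt = −g_L (V − E_L) − g_e(t)(V − E_e) − g_i(t)(V − E_i)

with `C = 250 pF`, `g_L = 16.67 nS`, `E_L = −60 mV`, `E_e = 0 mV`,
`E_i = −80 mV`. Every presynaptic spike increments the corresponding synaptic
conductance by its peak value (10 nS excitatory in the size-sweep
configuration; 5 nS excitatory / 15 nS inhibitory in the motif
configuration); conductances decay exponentially with `τ_syn = 1 ms`.

Three input motifs are built from fixed-in-degree sub-graphs:

- **ff_exc** — drive → receivers only;
- **ff_inh** — adds an interneuron pool (same membrane, spiking enabled at
  −50 mV) receiving the drive at the same sparseness, projecting
  inhibition onto the receivers (`ρ_inh`);
- **recurrent_inh** — additionally connects the interneuron pool to itself
  (`ρ_rec`, self-connections excluded). This is the active-decorrelation
  motif: the recurrently coupled pool desynchronizes internally and its
  summed inhibition tracks and cancels the shared excitatory fluctuations.

The source-population size for the motif experiments is a configuration
value (default 100, as are the 100 receivers and 100 interneurons).

### Integration scheme

Exponential Euler for conductances (exact decay factor per step) and forward
Euler for the voltage at `dt = 0.1 ms` (enforced `dt ≤ 0.1 τ_syn`); halving
`dt` changes receiver voltages by well under 0.1 mV RMS. Receiver voltages
are recorded at 1 kHz. The stepping kernel is JIT-compiled with numba when
available and runs as plain Python otherwise, with identical semantics.

### Loop delay and interneuron refractory period — why they matter

Two parameters of the spiking pathway are not dictated by the membrane
constants but control whether active decorrelation exists at all:

- **Transmission delay (default 0.5 ms).** Inhibitory feedback can only
  cancel the shared fluctuations it still tracks. With a 1 ms loop delay the
  cancellation is marginal, and by 3 ms the delayed feedback *resonates* and
  enhances correlations instead. A short local-circuit delay (0.2–0.5 ms)
  keeps the recurrent pool in the tracking regime; 0.5 ms is the default and
  is numerically safe at `dt = 0.1 ms`.
- **Interneuron refractory period (default 0.5 ms).** At the drive-cycle
  peaks the interneurons run above 200 spikes/s. A 2 ms absolute refractory
  rate-limits them exactly there, so the decorrelation collapses at the cycle
  phase where it should be strongest — and the rate dependence of the fast
  correlation comes out with the wrong sign. With 0.5 ms the pool keeps
  tracking across the whole cycle: constant-rate sweeps
  (`r₀ = 10…150 spikes/s`) then place the suppression optimum above the
  cycle-peak rate, and the oscillating-drive simulation shows the expected
  anti-phase relation between the sliding fast correlation and the low-pass
  membrane potential.

The interneuron reset is −60 mV (the resting potential).

## Analysis pipeline

**Timescale decomposition.** Membrane potentials are split with 3-pole
Butterworth filters applied forward and backward (zero phase): slow =
0.2–5 Hz band-pass, fast = >5 Hz high-pass. Action potentials, if present,
are clipped beforehand (samples beyond mean + 5 SD, linear interpolation).
Traces must span at least three periods of the 0.2 Hz band edge (15 s).

**Pairwise correlation.** Standard product-moment Pearson, on each component.
Significance of a fast-component correlation is judged against a shuffle
null: one trace is circularly shifted by an offset drawn uniformly from
0.5–2 s (200 shuffles by default); the 95% confidence limits are the null
mean ± 1.96 σ. Coverage under independence is ~95% (verified by simulation).

**Sliding correlation.** Pearson R in a 400 ms window stepped every 10 ms,
over lags up to ±100 ms, computed with cumulative-sum rolling statistics.
The zero-lag trace feeds the rate-dependence analysis: its correlation with
the low-pass membrane potential of the pair, compared against circular-shift
shuffles, with a two-sample Kolmogorov–Smirnov test at the population level.

**Phase.** The lag of the cross-correlation peak of the slow components,
expressed in degrees of the dominant period and wrapped to [0°, 360°);
requires both traces to be rhythmic (dominant spectral peak carrying ≥20% of
power). Quiescent epochs (1 s epochs whose slow-envelope RMS falls below 10%
of the whole-trace RMS — an operational choice) can be excluded from the
fast-correlation summary.

**Spike populations.** Rates are estimated by summing unit-area Gaussian
kernels at the spike times (σ = 5 ms for the fast, 150 ms for the slow
component; kernels truncated at ±5σ; evaluated exactly on a 1 kHz grid),
then high-pass filtered at 10 Hz and 0.3 Hz respectively before building
pairwise Pearson matrices. Units are screened for rhythmicity with the
Rayleigh test on their spike phases relative to a reference rhythm: with
mean resultant length `R` over `N` spikes, `z = N R²` and

    p = exp( √(1 + 4N + 4(N² − R_N²)) − (1 + 2N) ),   R_N = R·N,

significant at α = 5% per unit (Bonferroni available as a flag, off by
default). The reference phase comes from the analytic signal (Hilbert
transform) of the 150 ms-smoothed, 0.1 Hz high-passed reference trace, and
is only evaluated where the reference is active. Preferred phase is the
circular mean direction; polar histograms default to 18 bins of 20°.

**Connection probe.** For each candidate presynaptic unit the spike-triggered
*median* membrane potential (window −20 to +80 ms; the median resists spike
contamination of snippets) is z-scored with whole-recording statistics and
compared with surrogates built by interval jitter: time is partitioned into
fixed 100 ms bins anchored at the recording start and every spike is redrawn
uniformly within its bin, preserving per-bin counts exactly. The deviation
extremum within a causal window (0.5–30 ms) is normalized by the spread of
the *same extremum statistic* across the 100 surrogates — a pointwise ±2 σ
band alone would be anti-conservative, because the extremum search spans
many correlated samples — and a connection is declared at |peak| > 2. That
calibration keeps the false-positive rate on independent data near the
nominal level. For significant negative peaks (IPSPs) the decay constant is
fitted as a single exponential from the trough with the baseline fixed to
the pre-spike median (freeing the baseline trades noise into τ); the fit
span starts at 15 ms and widens to ~4τ when the first pass indicates slow
kinetics, so ~5 ms (glycinergic-like) and ~25 ms (GABAergic-like) decays are
both resolved and distinguishable.

## Synthetic fixtures

Every distributional assumption the pipeline makes can be planted with known
ground truth, independently of the simulator:

- **Shared-input pairs**: two traces = slow sinusoid (per-cell phase
  offsets) + `√c ·` common + `√(1−c) ·` independent band-limited (5–100 Hz)
  Gaussian noise, so the expected fast R is `c` by construction and the
  expected slow R is the cosine of the phase offset. The band-limited
  Gaussian model makes the filter split clean; real synaptic noise has a
  non-flat spectrum, so recovery accuracy on these fixtures bounds, but does
  not guarantee, accuracy on data.
- **Tuned populations**: Poisson units with von Mises phase tuning (κ = 0
  degenerates to phase-uniform, i.e. non-rhythmic) around a common rhythm,
  plus the reference trace.
- **Connected pairs**: an Ornstein–Uhlenbeck background (σ configurable,
  correlation time 5 ms — a plausible synaptic timescale) plus causal
  exponential PSP kernels of known amplitude (sign encodes E/I identity) and
  decay constant at each presynaptic spike.

All generators are reproducible per seed and verified against their own
closed forms before being used to test the pipeline.

## Problem sizes and determinism

The shipped experiments run at desk scale: 60 s simulations with three seeds
for the size-sweep configurations, 30 s with five seeds for the motif
comparison, one 60 s run with 60 sampled pairs for the rate-dependence
analysis, 200 s recordings with ~2000 presynaptic spikes for connection-probe
power. Global seeds are split into per-stage seeds with numpy's
`SeedSequence`, and identical (configuration, seed) pairs reproduce outputs
bitwise.

## Known limitations

- Under the weak size-sweep drive (12 ± 10 spikes/s, pooled ~120 spikes/s
  per receiver) the Poisson shot noise *inside* the 0.2–5 Hz band bounds the
  slow-component pair correlation at ~0.93 (dense) / ~0.86 (sparse wiring),
  however long the simulation; "slow R ≈ 1" holds only for stronger drives
  where the 1 Hz signal dominates the in-band noise (e.g. the motif
  configuration, where it exceeds 0.99).
- In the motif configuration the strong 1 Hz conductance oscillation drives
  the receivers far from rest; harmonics of the nonlinear driving-force
  modulation leak above the 5 Hz cutoff and are common to all receivers,
  inflating the ff_exc fast correlation slightly above the `k/n₁` prediction
  (~0.55 vs 0.5).
- Feedforward inhibition routed through a sparse interneuron projection
  (`ρ_inh = 0.9`) removes an appreciable part of the receiver correlation in
  this model (partly independent inhibitory variance, partly tracking
  cancellation) in every regime we scanned; configurations in which
  feedforward inhibition leaves pair correlations strictly unchanged were
  not found.
- Receivers are point neurons; dendritic filtering and electrotonic
  separation of inputs are outside the model.
- The quiescence threshold and the activity mask for the reference rhythm
  are operational defaults, not measured properties of any recording system.
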