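# Methods

## The circuit model

`finchra` simulates a single RA projection neuron — the zebra finch's motor
cortex analogue output cell — embedded in the feed-forward HVC → RA ← LMAN
circuit. HVC acts as a time-keeper: each of the `N_HVC = 100` model HVC
neurons fires one stereotyped burst of 5 spikes, 2 ms apart, and the burst
onsets at `(i−1)·10 ms` tile a 1000 ms "song" without overlap, identically
on every rendition. LMAN, the cortical outflow of the basal-ganglia
pathway, is the variability source: two ~40 Hz neurons merged into a single
80 Hz Poisson process (per-rendition independent noise).

The RA neuron is leaky integrate-and-fire:

    tau_m dV/dt = (V_R − V) + R·I_HVC + R·I_LMAN − V_INH

with `tau_m = 20 ms`, `V_R = −70 mV`, `V_th = −50 mV`, `R = 260 MΩ` and a
1.5 ms refractory period during which V is clamped at `V_R` while the
synaptic currents keep evolving. HVC synapses are exponential
(`tau_s = 5 ms`); each spike of HVC neuron *i* increments `I_HVC` by its
weight `W_i` (the peak EPSC, pA). LMAN input splits into an AMPA component
(fraction `r = 0.1` of `W_LMAN = 120 pA`, decay `tau_s`) and an NMDA
component (fraction `1 − r`, decay `tau_NMDA = 100 ms`) whose increments
are scaled by the Jahr–Stevens-style magnesium block

    G(V) = 1 / (1 + [Mg]/3.57 mM · exp(−V / 16.13 mV)),   [Mg] = 0.5 mM,

evaluated at the membrane potential when the presynaptic spike arrives
(increment-frozen gating; continuous gating of the accumulated pool is a
documented alternative that was implemented for comparison and changes the
steady firing rate by < 10%). Tonic inhibition is a constant offset
proportional to the mean HVC drive, `V_INH = R_INH · m · ρ` with
`R_INH = 800 MΩ`, where `m` is the distribution mean of the active weights
(not the realized sample mean) and `ρ` the active fraction.

Units are fixed at mV / ms / pA / GΩ so `R[GΩ]·I[pA] = V[mV]`; this is
asserted by the arithmetic tests (e.g. `V_INH = 36 mV` at `m = 50 pA`,
`ρ = 0.9`).

## The learning axis

HVC→RA weights are drawn from a log-normal distribution. Development is
parameterized as *strengthening and pruning*: a fraction `1 − ρ` of the 100
inputs is set to zero (a uniformly random subset per realization — HVC
index maps to song time, so deterministic pruning would impose temporal
structure), and the surviving weights are drawn with mean `m` and SD `s`
that are linear in `ρ`, anchored at the two measured stages
(`ρ = 0.9 → m, s = 50, 35 pA`; `ρ = 0.37 → 70, 70 pA`), extrapolated
linearly over `ρ ∈ [0.2, 1]` and clipped at zero. The (m, s) → (μ, σ)
bridge is the standard moment inversion `σ² = ln(1 + s²/m²)`,
`μ = ln m − σ²/2`. The log-normal MLE uses the population (1/n) variance
of the logs.

## The variability statistic

Each rendition's RA spike train is converted to an instantaneous rate
`R(t) = 1/(t_{k+1} − t_k)` between consecutive spikes (zero outside the
first/last spike, and zero throughout for < 2 spikes; NaN-masking is the
noted alternative), sampled on a 1 ms grid, convolved with a unit-area
10 ms Gaussian (edge handling by kernel renormalization, so constants pass
through exactly), and mean-subtracted. CC is the mean pairwise Pearson
correlation over all rendition pairs; a zero-variance trace contributes 0
to its pairs and is flagged. The Pearson normalization
`√(⟨r̄_i²⟩⟨r̄_j²⟩)` is the only reading that bounds CC in [−1, 1] with
CC = 1 for identical renditions.

## Numerical scheme and initialization

Forward Euler at `dt = 0.2 ms`; events are snapped to the grid by flooring
and increments applied at the start of the containing step; NMDA gating
uses the pre-update V of that step; spikes are detected as end-of-step
crossings. The constant-drive oracle (rate `1000/(t_ref + tau_m·ln(RI/(RI−20)))`)
is matched within ~1% at this dt, and halving dt changes constant-drive
spike counts by < 1%.

Renditions model excerpts of ongoing singing, not the first notes after
silence: each simulated rendition is preceded by one uncounted warm-up pass
of the same inputs, which brings the slow NMDA pool (100 ms time constant)
and membrane to their periodic steady state. A cold start spends ~300 ms in
a shared onset transient that depresses the rate by ~25% and inflates CC
through a deterministic common signal. With the steady-state convention
the standard model (ρ = 0.9) fires at ≈ 40 Hz; a mean-field
self-consistency calculation of the same equations
(R·I_HVC ≈ 29 mV, V_INH = 36 mV, NMDA pool ≈ 864·Ḡ pA with Ḡ ≈ 0.16)
supports this value. The NMDA gate makes the operating point a soft fixed
point: rate, G(V), and NMDA drive feed back on one another, so modest
parameter changes shift the rate disproportionately.

A consequence worth knowing: because tonic inhibition is balanced against
the mean HVC drive, the sustained suprathreshold excitation is carried
mostly by the LMAN NMDA pool. Halving `W_LMAN` therefore collapses the
firing rate (to ~7 Hz at the ρ = 0.9 point) and flips the neuron into a
sparse regime locked to the strongest HVC slots, with a *higher* CC than
any point on the learning axis; the `lman_weakening_share` statistic
(≈ 100% under the default conditions, computed by `scripts/acceptance.py`)
reflects this regime change rather than a graded noise reduction.
Similarly, the strengthen-only control arm (raising m and s at fixed
ρ = 0.9, with V_INH tracking m) concentrates reliable firing in strong
slots and raises CC more than the combined axis does. Both behaviors are
intrinsic to this parameter balance; they were verified robust to the
gating convention (increment-frozen vs continuous), to the initialization
(cold vs steady-state), and to holding V_INH fixed in the control arms.

## Sweep experiments

A *realization* is one weight draw plus fresh LMAN noise for every
rendition; CC is averaged over realizations (both weights and noise are
redrawn — the nesting is a documented choice, with realization and
rendition counts as configuration knobs). Desk-scale defaults are 50
realizations × 200 renditions; the axes are: the combined
strengthen-and-prune trajectory; strengthen-only (ρ fixed at 0.9, (m, s)
moved along the same anchored trajectory); prune-only (ρ varied, (m, s)
fixed at 50/35 pA); `W_LMAN` scaling (±50%); AMPA fraction r ∈ [0, 0.2]
plus pure AMPA; tau_m ∈ [16, 25] ms (±20% F-I gain); burst fraction
b ∈ [0, 1] (tonic 40(1−b) Hz plus 8b Hz burst events of 5 spikes 2 ms
apart per neuron, two independent 40 Hz neurons superposed); and sine
rate modulation (one period per song, phase 0, depth < 1). V_INH is
recomputed from each grid point's (m, ρ) on every axis.

## Slice-recording quantification

The evoked-EPSC pipeline mirrors the minimal-stimulation protocol: traces
are smoothed with a 1 ms sliding window; the baseline noise RMS comes from
the 50 ms pre-stimulus window when not supplied (recordings have a 2–5 pA
noise floor); peaks are searched 2–30 ms post-stimulus (the first 1 ms
holds the stimulus artifact; latencies to peak run 7–13 ms). A sweep is a
*success* if its peak exceeds 2× the noise RMS. A single-fiber (SF)
measurement requires a 25–75% failure rate and > 3 successes; a second SF
from a neighboring stimulation site is accepted only if its success peaks
differ from the first's (two-sample t test, p < 0.05 — type-I calibration
is tested). The MAX current is the mean peak at the lowest intensity whose
response stops growing: all higher tested intensities, reaching at least
3× that intensity, stay within a 10% tolerance (configurable); plateau
CV ≤ 0.2 is enforced.

Input counts per age group: `mean_sf` divides each cell's MAX by the
group-mean SF and averages over cells (the group-mean variant is also
available through the same arithmetic); `fiber_fraction` inverts the
group-mean of per-SF SF/MAX ratios. Both assume linear summation and are
lower bounds. The AMPA fraction at LMAN→RA synapses comes from inverting
the holding-potential amplitude ratio
`|A(−70)|/|A(+40)| = g_A·|E+70| / ((g_A+g_N)·|E−40|)` with E = 0 mV, so
`r = ratio·40/70` and `g_N:g_A = (1−r)/r`.

F-I analysis: spikes are upward crossings of −20 mV with a 1 ms lockout;
IFF(t) is the ISI-reciprocal rate averaged across sweeps where defined;
the adaptation ratio compares mean IFF in 5 ms windows anchored at the
first and last spike (anchoring at the spikes rather than the stimulus
edges keeps the ratio exactly 1 for a non-adapting neuron whose first
spike falls after 5 ms); the decay constant is a single-exponential fit to
the first 100 ms after the first spike; the F-I slope is a linear fit of
mean IFF vs current for injections ≤ 1.4 nA.

## Synthetic recordings

No raw recordings exist to distribute, so `synthetic_ephys` generates them
with retained ground truth, and every estimator is tested closed-loop.
EPSCs are difference-of-exponentials (1 ms rise, 5 ms decay, unit peak)
with per-trial latency jitter; release failures occur only at the minimal
tested intensity that recruits a fiber (probability → 1 above it) — the
minimal mechanism producing the failure/success regime. Populations draw
per-cell input weights from the group's log-normal (means 29.5 / 49.6 /
73.6 pA for the three stages, spreads following the anchor CVs, input
counts 19 / 26 / 11), observe 1–3 of them as SFs, and set MAX to the noisy
sum. Current-clamp sweeps come in two kinds: `lif` integrates a real LIF
at the sample rate (so its rate matches the closed form and its adaptation
ratio is 1), while `adapting_lif` is deliberately phenomenological — spike
times are laid down so the IFF follows `f_∞ + (f_0 − f_∞)·exp(−t/τ)`
exactly, because a mechanistic spike-triggered adaptation current yields
only an approximately exponential decay with an emergent time constant,
which would make the recovery test circular or vague.

What the generators do **not** emulate: electrode/series-resistance
artifacts, dendritic filtering, vesicle-depletion dynamics, correlated
noise, spontaneous synaptic events, and cell-to-cell kinetic diversity.
Passing recovery tests therefore demonstrates estimator correctness under
the stated generative assumptions, not robustness to every pathology of
real recordings.

## Known limitations

- Single RA neuron; no RA interneurons, recurrence, or plasticity.
- The NMDA-gate feedback makes absolute firing rates and CC levels
  sensitive to the drive balance (see above); directional comparisons
  across conditions are the robust outputs.
- Burst trains are stereotyped (no jitter) and truncated at the song end;
  LMAN neurons are uncorrelated and non-refractory.
- CC treats epochs outside the first/last spike as zero rate; renditions
  with < 2 spikes are degenerate and down-weight the mean toward 0.
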