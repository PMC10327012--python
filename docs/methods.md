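# Methods

## Scope and data model

`hippoloom` builds spiking network models of hippocampal circuits from
per-neuron-type and per-type-pair parameter tables.  A knowledge base is
five CSV tables (UTF-8, comma-separated, "." decimal, one header row) for
one species at a time:

| file | columns |
|---|---|
| neuron_types.csv | name, subregion, polarity, rank, laminar_code |
| census.csv | name, species, count |
| izhikevich.csv | name, C_pF, k_nS_per_mV, Vr_mV, Vt_mV, Vpeak_mV, Vmin_mV, a_per_ms, b_nS, d_pA, is_default |
| connections.csv | pre, post, probability, contacts, is_default |
| synapses.csv | pre, post, g_nS, tau_d_ms, tau_r_ms, tau_f_ms, U, is_default |

Laminar codes record axonal/dendritic presence per layer (0 none, 1 axons,
2 dendrites, 3 both), with a terminal "p" marking cross-subregion
projection.  Ranks grade a type's importance for simplified models from 1
(essential) to 5 (dispensable); a blank rank defaults to 3 and is flagged
in memory (the fixed CSV column set has no flag column for it).  Every
violation of a table invariant is reported with file and row.

Missing values are never filled silently.  Connection probabilities
default to class averages — E→E 0.0117, E→I 0.0237, I→E 0.00684, I→I
0.00423 — with `is_default=true` and contacts = 1.0 (the minimum legal
value and the small-λ limit of the estimator).  Missing Izhikevich and TPM
rows receive package-defined generic constants (a regular-spiking neuron
and a moderately depressing synapse), likewise flagged.  Self-pairs
(pre == post) are legal rows: recurrent populations such as CA3 pyramidal
cells are real.

## Potential connectivity

Potential connectivity infers contact from spatial overlap of presynaptic
axons and postsynaptic dendrites in a parcel (one layer of one subregion).
Per parcel: bouton count `Nb = La / ibd` (axonal length over inter-bouton
distance, kept real-valued), per-bouton hit probability
`q = min(1, Ld·πr²/V)` — the volume fraction of the parcel occupied by the
target dendrite's interaction cylinder.  The default interaction radius is
r = 1.0 µm (order of bouton-plus-spine reach), configurable per parcel.

Treating bouton placements as independent gives, per directed neuron pair
over parcels k:

- expected synapses λ = Σ_k Nb_k·q_k
- connection probability p = 1 − Π_k (1−q_k)^{Nb_k}
- contacts per connected pair c = λ/p (conditional expectation given at
  least one contact; undefined and reported as None when p = 0)

For integer Nb this is the exact binomial model (checked against
Monte-Carlo bouton placement in the tests); for real Nb the closed form
interpolates.  With Nb ≥ 1, p ≤ λ and c ≥ 1 always; Nb < 1 is a degenerate
extrapolation where the p ≤ λ bound can fail, and is excluded from the
property suite.  The bundled mossy-fiber scenario encodes the published
anatomical constants (3,236 µm granule-cell axon in CA3; inter-bouton
distances 162 µm for CA3c pyramidal targets, 284 µm elsewhere in CA3,
67.4 µm for interneuron targets; innervation restricted to stratum
lucidum).  Its parcel volumes and dendritic lengths are synthetic
placeholders — per-parcel hull volumes are not distributed with the
package — so the scenario demonstrates the machinery, not literature
connection probabilities.

## Neuron model

Single-compartment Izhikevich hybrid dynamics:

    C dv/dt = k (v − Vr)(v − Vt) − u + I
      du/dt = a (b (v − Vr) − u)
    if v ≥ Vpeak:  v ← Vmin,  u ← u + d

Integration is forward Euler at dt = 0.1 ms (the convention of
GPU-oriented spiking simulators), configurable.  A spike is recorded at
the step where v crosses Vpeak; the stored trace shows Vpeak at that step
(spike cutoff), so recorded voltages never exceed Vpeak.  (Vr, 0) is an
exact fixed point at I = 0.

Rheobase is located by bisection of the minimal spiking step amplitude
(default tolerance 1 pA, validated against a 1 pA dense scan); F-I curves
use 10 pA amplitude steps by default, rate = spikes during stimulus /
stimulus duration.  The default phenotyping stimulus is a 1 s pulse with
100 ms padding on each side.

Known Euler limitation: spike-time error accumulates roughly one step per
emitted spike, so dt-refinement agreement (< 1 ms per spike between
dt = 0.1 and 0.01 ms) holds for sparse trains (~10 Hz regular spiking over
1 s) and for first-spike latencies, but not for every spike of dense
fast-spiking trains.  The convergence tests therefore use sparse
regular-spiking fixtures plus first-spike checks.

### Firing-pattern classifier

A deliberately simplified, deterministic ISI rule set over the closed
label vocabulary {NASP, ASP., TSTUT., PSTUT, SLN, SP, TSTUT.SLN,
TSTUT.PSTUT}; thresholds are package-defined, not literature-calibrated:

1. no spikes in the stimulus window → SLN; one spike → SP;
2. spiking confined to the first third of the stimulus and silence over at
   least its last half → TSTUT.SLN;
3. stuttering = ISI coefficient of variation ≥ 0.5 with ≥ 1 gap ≥ 3× the
   median ISI; confined to the first third → TSTUT., gaps early and late →
   TSTUT.PSTUT, otherwise PSTUT;
4. last/first ISI ratio ≥ 1.5 → ASP.; otherwise NASP.

Every spike train receives exactly one label (property-tested).

## Synapse model

TPM short-term plasticity per directed type pair, with closed-form
inter-event relaxation (R → 1 with τr, u → 0 with τf, g_t → 0 with τd) and
the facilitation-before-release spike update u⁺ = u + U(1−u), released =
R·u⁺, R⁺ = R − released, g_t += g·released.  u relaxing to 0 with the
baseline U re-added at spike time is one of the two common conventions; it
affects only facilitating pairs and is the package's documented choice.
With τf → 0 the model reduces to depression-only dynamics (u ≡ U at each
spike).  The closed form equals dense integration of the ODE form (RK4
oracle in the tests) to ≤ 1e-6 relative.

Synaptic drive is conductance-based: I = g_t (E_rev − v), with default
reversal potentials 0 mV (excitatory) and −70 mV (inhibitory).

## Network construction

Population sizes are `max(1, round_half_up(scale × census))` on contiguous
global indices.  Wiring is independent Bernoulli per ordered neuron pair
at the tabulated probability (self-edges excluded within a population),
sampled exactly by drawing the edge count Binomial(M, p) and choosing that
many distinct pair slots.  Each directed type pair uses its own random
substream derived from the master seed and the two type names (CRC32), so
adding or removing a population never perturbs other pairs' draws, and
equal (tables, scale, seed) reproduce byte-identical exported networks.

Contacts per connected pair multiply the edge's unitary conductance rather
than creating multi-edges — identical mean postsynaptic drive at lower
memory (the alternative, per-contact edges, would add contact-count
variance within a pair).  Per-edge delays default to uniform 1–2 ms (no
tabulated delays exist in the dialect).

## Simulation engine

Time-stepped co-simulation at dt = 0.1 ms: neurons advance with the same
forward-Euler update as the single-neuron path (a one-neuron network
reproduces it bit-for-bit); per-group synaptic conductances decay by
exp(−dt/τd) each step; presynaptic spikes schedule per-edge arrivals after
their delay (≥ 1 step), at which point only the affected edges' TPM states
are advanced in closed form and release is added to the target's
conductance.  No postsynaptic conductance changes before spike + delay.
Non-finite dynamics abort with a diagnostic naming the population and
time.

Background drive is an independent constant-plus-Gaussian-white-noise
current per neuron.  By default the mean is 1.3× the population's rheobase
with SD 0.3× the mean — calibrated at run time from the model parameters
themselves, which keeps every population active across parameter jitter
without hand-tuned currents.

The LFP proxy is the summed absolute synaptic current onto a reference
subset (default: the excitatory populations) — a standard computable
stand-in, not a biophysical field model.  Band filtering uses zero-phase
4th-order Butterworth band-passes (odd-reflection padding) with the
conventional bands theta 4–12 Hz, gamma 25–100 Hz, ripple 150–200 Hz.

## Synthetic fixtures and what they show

All test inputs are generated programmatically:

- **toy circuit** — 4 types (2E/2I) across DG and CA3 with complete
  tables; exercises IO, selection and wiring.
- **CA3-like demo** — one excitatory pyramidal type plus the seven main
  interneuron types of CA3 microcircuitry (axo-axonic, basket, CCK+
  basket, bistratified, ivy, mossy-fiber-associated ORDEN, QuadD-LM).
  Census counts (74,000 pyramidal cells, 1,500–8,900 per interneuron
  type), Izhikevich constants (regular-spiking pyramidal, fast-spiking
  interneurons with mild jitter), probabilities (class-scale values
  0.005–0.02) and TPM constants are package-defined plausible magnitudes,
  not measured hippocampal values.  The default desk-scale demo uses
  scale = 0.007 (707 neurons) for 1 s — chosen as the smallest circuit
  that keeps ≥ 500 pyramidal cells, echoing typical raster figures.
- **incomplete tables** — a known fraction of connection rows removed, to
  exercise default fill-in.
- **mossy-fiber scenario** — the printed anatomical constants above.

Passing tests therefore demonstrate the correctness of the machinery
(parsing, estimation formulas, integrators, wiring statistics,
determinism) and qualitative network behavior (all populations active,
band-filterable population signals).  They do not validate against in vivo
firing rates, real hippocampal connectivity matrices, or published
oscillation spectra — reproducing those requires the measured parameter
tables, which users supply in the same dialect.

## Numerical conventions

- round_half_up for census scaling (0.5 → 1); population floor 1 neuron.
- Spike time = (step index + 1)·dt at the reset step, in both the
  single-neuron and network paths.
- Floats export via `repr` (exact round-trip); booleans as `true`/`false`.
- Probability products accumulate in log space (`log1p`) for numerical
  stability; q = 1 parcels saturate p at 1 explicitly.
- Delay steps = max(1, round(delay/dt)): zero-delay synapses are promoted
  to one step to preserve causality.
- Rheobase bisection assumes spiking is monotone in step amplitude over
  the bracket; the scan-agreement test guards this for the fixture sets.

## Limitations

- Forward Euler phase drift on dense spike trains (see above); smaller dt
  is available where spike timing matters.
- The overlap estimator's interaction-cylinder geometry is an operational
  model; it ignores bouton clustering, dendritic orientation anisotropy
  and within-parcel density gradients.
- Contacts-as-weight wiring suppresses per-pair contact-count variance.
- No distance-dependent connectivity, conduction-velocity delays,
  multi-compartment neurons, NMDA/GABA-B slow components, or GPU
  execution.
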