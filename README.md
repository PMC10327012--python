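# hippoloom

Data-driven spiking neural network construction and simulation for rodent
hippocampal circuits.

Biologically detailed circuit models of the hippocampal formation (DG, CA3,
CA2, CA1, subiculum, entorhinal cortex) need four quantities on top of a
neuron-type catalog: (i) the number of neurons of each type, (ii) each
type's input-output response function, (iii) the connection probability for
each directed pair of types, and (iv) the unitary synaptic signal for each
connected pair.  `hippoloom` consumes exactly these quantities from plain
CSV parameter tables and turns them into runnable spiking networks:

* **Knowledge model** — a validated, five-table CSV dialect (neuron types
  with laminar codes and importance ranks, census, Izhikevich neuron
  parameters, connection probabilities/contacts, Tsodyks–Pawelzik–Markram
  synapse constants), with subsetting by subregion/rank/name and flagged
  default fill-in for missing values.  Missing connection probabilities
  receive the class-averaged defaults: E→E 0.0117, E→I 0.0237, I→E 0.00684,
  I→I 0.00423.
* **Potential connectivity** — axonal-dendritic overlap estimation.  An
  axon of length `La` with inter-bouton distance `ibd` carries
  `Nb = La/ibd` boutons in a parcel; each bouton hits one target neuron's
  dendrite (length `Ld`, interaction radius `r`, parcel volume `V`) with
  probability `q = min(1, Ld·πr²/V)`.  Per directed pair,
  `λ = Σ Nb_k·q_k`, `p = 1 − Π(1−q_k)^{Nb_k}`, contacts `c = λ/p`.
* **Neuron dynamics** — the 9-parameter single-compartment Izhikevich
  hybrid model (`C·dv/dt = k(v−Vr)(v−Vt) − u + I`; reset at `Vpeak`), with
  step protocols, F-I curves at 10 pA steps, rheobase, and a simplified
  ISI-based firing-pattern classifier (NASP, ASP., TSTUT., PSTUT, SLN, …).
* **Synapse dynamics** — TPM short-term plasticity (depression via
  resource recovery τr, facilitation via τf, utilization U, conductance g,
  decay τd) with exact closed-form inter-event updates.
* **Network builder & engine** — census-scaled populations, per-pair
  seeded Bernoulli wiring, a time-stepped co-simulation with delayed
  event-driven synapses, an LFP proxy (summed |synaptic current| onto the
  excitatory populations), and zero-phase band filters for theta
  (4–12 Hz), gamma (25–100 Hz) and ripple (150–200 Hz).

## Worked example

The classic mossy-fiber anatomy: a dentate granule cell has 3,236 µm of
axon inside CA3, with one en-passant/filopodial bouton every 67.4 µm along
the stretch contacting interneurons:

```pycon
>>> import hippoloom as hl
>>> hl.bouton_count(3236, 67.4)
48.01186943620178
```

≈ 48 boutons, i.e. one granule cell can contact 48 CA3 interneurons.  The
same module averages the reported Schaffer-collateral inter-bouton
distances 3.7, 4.4 and 4.29 µm to 4.1 µm (at 0.1 µm display resolution).

Building and running the bundled CA3-like demo (one excitatory pyramidal
population plus seven interneuron types, scaled to 707 neurons):

```pycon
>>> kb = hl.fill_defaults(hl.make_ca3_demo(seed=0))
>>> net = hl.build_network(kb, scale=0.007, seed=1)
>>> res = hl.run(net, duration=1000.0, seed=1)
>>> {k: round(v, 1) for k, v in hl.population_rates(res).items()}
{'CA3 Pyramidal': 8.6, 'CA3 Axo-Axonic': 105.2, 'CA3 Basket': 52.3,
 'CA3 Basket CCK+': 64.0, 'CA3 Bistratified': 118.3, 'CA3 Ivy': 71.2,
 'CA3 Mossy Fiber-Associated ORDEN': 124.6, 'CA3 QuadD-LM': 105.9}
```

Every population fires: the pyramidal cells at a low rate, the
fast-spiking interneurons much faster, as expected from their rheobase-
calibrated background drive.  `hl.lfp_proxy(res)` and `hl.bandpass(...)`
then give band-filtered population signals.

The same pipeline is scriptable from the shell:

```sh
hippoloom make-fixtures --which ca3 --seed 0 --out tables/
hippoloom run tables/ --scale 0.007 --duration 1000 --seed 1 --out out/
```

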