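"""Time-stepped co-simulation of Izhikevich populations and TPM synapses.

The engine advances all neurons with forward Euler (matching
:mod:`hippoloom.neuron` step for step) while synaptic conductances decay
exponentially and presynaptic spikes, after their per-edge delay, trigger
closed-form TPM updates on the affected edges only (event-driven synapses
inside a time-stepped neuron loop).

Each neuron receives an independent background drive: a constant mean plus
Gaussian white noise per step.  By default the mean is set per population
to a fixed multiple of that type's rheobase, which keeps every population
active without hand-tuning per-type currents.

Recorded outputs: all spike times, selected membrane traces, and a local
field potential (LFP) proxy defined as the summed absolute synaptic
currents onto a reference population subset (by default the excitatory
populations).  Band-filtered views use zero-phase 4th-order Butterworth
filters; the conventional hippocampal bands are theta 4-12 Hz, gamma
25-100 Hz, and sharp-wave ripple 150-200 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

from .network import NetworkSpec, Population
from .neuron import DEFAULT_DT, StepProtocol, rheobase
from .synapse import REVERSAL_POTENTIALS

#: Oscillation bands (Hz) used for LFP filtering.
BANDS = {"theta": (4.0, 12.0), "gamma": (25.0, 100.0), "ripple": (150.0, 200.0)}

#: Default background-drive calibration: mean = RHEOBASE_FACTOR x rheobase,
#: white-noise SD = NOISE_FRACTION x mean.
RHEOBASE_FACTOR = 1.3
NOISE_FRACTION = 0.3


@dataclass
class SimulationResult:
    """Spikes, selected traces, and the LFP proxy from one run."""

    spike_neurons: np.ndarray          # global neuron index per spike
    spike_times: np.ndarray            # ms, same order
    trace_times: np.ndarray            # ms
    traces: dict[int, np.ndarray]      # global index -> membrane potential mV
    syn_abs: dict[str, np.ndarray]     # population -> summed |I_syn| (pA) per step
    populations: list[Population]
    duration: float                    # ms
    polarity: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def spikes_of(self, population: Population) -> np.ndarray:
        mask = ((self.spike_neurons >= population.first_index)
                & (self.spike_neurons < population.first_index + population.size))
        return self.spike_times[mask]


def default_background_drive(net: NetworkSpec,
                             factor: float = RHEOBASE_FACTOR,
                             noise_fraction: float = NOISE_FRACTION,
                             ) -> dict[str, tuple[float, float]]:
    """Per-population (mean, SD) drive in pA, calibrated from rheobase."""
    drive: dict[str, tuple[float, float]] = {}
    cache: dict[tuple, float] = {}
    proto = StepProtocol(amplitude=0.0, onset=0.0, duration=300.0,
                         total_time=300.0)
    for p in net.populations:
        params = net.izhikevich[p.type_name]
        key = (params.C, params.k, params.Vr, params.Vt, params.Vpeak,
               params.Vmin, params.a, params.b, params.d)
        if key not in cache:
            cache[key] = rheobase(params, I_hi=5000.0, tol=5.0, protocol=proto)
        mean = factor * cache[key]
        drive[p.type_name] = (mean, noise_fraction * mean)
    return drive


def _resolve_drive(net: NetworkSpec, background_drive) -> tuple[np.ndarray, np.ndarray]:
    n = net.n_neurons
    mean = np.zeros(n)
    sd = np.zeros(n)
    if background_drive is None:
        background_drive = default_background_drive(net)
    if isinstance(background_drive, tuple):
        background_drive = {p.type_name: background_drive
                            for p in net.populations}
    for p in net.populations:
        m, s = background_drive[p.type_name]
        sl = slice(p.first_index, p.first_index + p.size)
        mean[sl] = m
        sd[sl] = s
    return mean, sd


def _gather_edges(indptr: np.ndarray, locals_: np.ndarray) -> np.ndarray:
    """Edge ids (into the group's sorted arrays) for spiking local pre indices.

    Vectorized concatenation of the CSR ranges [indptr[l], indptr[l+1]).
    """
    counts = indptr[locals_ + 1] - indptr[locals_]
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    starts = indptr[locals_]
    idx = np.repeat(starts, counts)
    offsets = np.arange(total) - np.repeat(counts.cumsum() - counts, counts)
    return idx + offsets


def run(net: NetworkSpec, duration: float, dt: float = DEFAULT_DT,
        background_drive=None, seed: int = 0,
        record_traces: Iterable[int] | None = None) -> SimulationResult:
    """Simulate the network for ``duration`` ms; deterministic per seed.

    ``background_drive`` is a mapping ``type_name -> (mean_pA, sd_pA)``, a
    single ``(mean, sd)`` tuple for all populations, or None for the
    rheobase-calibrated default.  ``record_traces`` selects global neuron
    indices (default: the first neuron of every population).
    """
    if dt <= 0 or duration < 0:
        raise ValueError("dt must be positive and duration non-negative")
    n = net.n_neurons
    n_steps = int(round(duration / dt))
    trace_times = (np.arange(n_steps) + 1) * dt
    if n == 0:
        return SimulationResult(
            spike_neurons=np.empty(0, dtype=np.int64),
            spike_times=np.empty(0), trace_times=trace_times, traces={},
            syn_abs={}, populations=[], duration=duration,
            polarity={}, meta={"seed": seed, "dt": dt})

    # --- per-neuron parameter vectors ------------------------------------
    C = np.empty(n); k = np.empty(n); Vr = np.empty(n); Vt = np.empty(n)
    Vpeak = np.empty(n); Vmin = np.empty(n); a = np.empty(n); b = np.empty(n)
    d = np.empty(n)
    pop_of = np.empty(n, dtype=np.int64)
    for pi, p in enumerate(net.populations):
        sl = slice(p.first_index, p.first_index + p.size)
        prm = net.izhikevich[p.type_name]
        C[sl], k[sl], Vr[sl], Vt[sl] = prm.C, prm.k, prm.Vr, prm.Vt
        Vpeak[sl], Vmin[sl], a[sl], b[sl], d[sl] = (
            prm.Vpeak, prm.Vmin, prm.a, prm.b, prm.d)
        pop_of[sl] = pi
    v = Vr.copy()
    u = np.zeros(n)

    mean_drive, sd_drive = _resolve_drive(net, background_drive)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB6]))

    # --- per-group state --------------------------------------------------
    class _G:
        pass

    gs = []
    pops = net.populations
    by_name = {p.type_name: p for p in pops}
    for g in net.groups:
        st = _G()
        pre_pop, post_pop = by_name[g.pre], by_name[g.post]
        order = np.argsort(g.pre_indices, kind="stable")
        st.pre_local = (g.pre_indices[order] - pre_pop.first_index)
        st.post_local = (g.post_indices[order] - post_pop.first_index)
        st.weight = (g.weight_scale[order]).astype(float)
        delay_steps = np.maximum(1, np.rint(g.delays[order] / dt)).astype(np.int64)
        st.delay_steps = delay_steps
        st.indptr = np.searchsorted(st.pre_local,
                                    np.arange(pre_pop.size + 1))
        st.pre_pop, st.post_pop = pre_pop, post_pop
        st.tpm = g.tpm
        st.rev = REVERSAL_POTENTIALS[net.polarity[g.pre]]
        ne = g.n_edges
        st.R = np.ones(ne)
        st.u = np.zeros(ne)
        st.last_t = np.zeros(ne)
        st.g_buf = np.zeros(post_pop.size)
        st.decay = np.exp(-dt / g.tpm.tau_d)
        gs.append(st)

    schedule: dict[int, list[tuple[int, np.ndarray]]] = {}
    trace_ids = (list(record_traces) if record_traces is not None
                 else [p.first_index for p in pops])
    traces = {i: np.empty(n_steps) for i in trace_ids}
    trace_arr = np.asarray(trace_ids, dtype=np.int64)
    syn_abs = {p.type_name: np.zeros(n_steps) for p in pops}

    spike_n: list[np.ndarray] = []
    spike_t: list[float] = []

    for s in range(n_steps):
        t = s * dt
        # synaptic conductance decay, then delayed arrivals for this step
        for st in gs:
            if st.g_buf.size:
                st.g_buf *= st.decay
        for gi, eids in schedule.pop(s, ()):  # arrivals land at time t
            st = gs[gi]
            tpm = st.tpm
            dtv = t - st.last_t[eids]
            R = 1.0 - (1.0 - st.R[eids]) * np.exp(-dtv / tpm.tau_r)
            uu = st.u[eids] * np.exp(-dtv / tpm.tau_f)
            uu = uu + tpm.U * (1.0 - uu)
            rel = R * uu
            st.R[eids] = R - rel
            st.u[eids] = uu
            st.last_t[eids] = t
            np.add.at(st.g_buf, st.post_local[eids],
                      st.weight[eids] * tpm.g * rel)

        # synaptic currents
        I = mean_drive + sd_drive * rng.standard_normal(n)
        for pi_, st in enumerate(gs):
            if not st.g_buf.size:
                continue
            sl = slice(st.post_pop.first_index,
                       st.post_pop.first_index + st.post_pop.size)
            contrib = st.g_buf * (st.rev - v[sl])
            I[sl] += contrib
            syn_abs[st.post_pop.type_name][s] += float(np.abs(contrib).sum())

        # forward Euler + reset (same update order as neuron.step_state);
        # overflow surfaces through the explicit finiteness check below
        v_old = v
        with np.errstate(over="ignore", invalid="ignore"):
            v = v_old + dt * (k * (v_old - Vr) * (v_old - Vt) - u + I) / C
            u = u + dt * a * (b * (v_old - Vr) - u)
        if not np.isfinite(v).all():
            bad = int(np.argmax(~np.isfinite(v)))
            raise RuntimeError(
                f"non-finite membrane potential in population "
                f"{pops[pop_of[bad]].type_name!r} at t = {t:.2f} ms")

        spiking = np.flatnonzero(v >= Vpeak)
        for i in trace_arr:
            traces[int(i)][s] = Vpeak[i] if v[i] >= Vpeak[i] else v[i]
        if spiking.size:
            spike_n.append(spiking.copy())
            spike_t.append((s + 1) * dt)
            u[spiking] += d[spiking]
            v[spiking] = Vmin[spiking]
            # schedule delayed arrivals on outgoing edges
            for gi, st in enumerate(gs):
                p0 = st.pre_pop.first_index
                mask = ((spiking >= p0)
                        & (spiking < p0 + st.pre_pop.size))
                if not mask.any():
                    continue
                eids = _gather_edges(st.indptr, spiking[mask] - p0)
                if eids.size == 0:
                    continue
                steps = s + 1 + st.delay_steps[eids]
                for step in np.unique(steps):
                    if step < n_steps:
                        schedule.setdefault(int(step), []).append(
                            (gi, eids[steps == step]))

    if spike_n:
        spike_neurons = np.concatenate(spike_n)
        spike_times = np.concatenate(
            [np.full(arr.size, tt) for arr, tt in zip(spike_n, spike_t)])
    else:
        spike_neurons = np.empty(0, dtype=np.int64)
        spike_times = np.empty(0)
    return SimulationResult(
        spike_neurons=spike_neurons, spike_times=spike_times,
        trace_times=trace_times, traces=traces, syn_abs=syn_abs,
        populations=list(pops), duration=duration,
        polarity=dict(net.polarity),
        meta={"seed": seed, "dt": dt, "n_neurons": n})


def lfp_proxy(result: SimulationResult,
              population_subset: Sequence[str] | None = None) -> np.ndarray:
    """LFP proxy: summed absolute synaptic currents onto the subset (pA).

    Default subset: the excitatory populations (all populations when no
    polarity information is attached to the result).
    """
    if population_subset is None:
        exc = [p.type_name for p in result.populations
               if result.polarity.get(p.type_name) == "excitatory"]
        population_subset = exc or [p.type_name for p in result.populations]
    subset = list(population_subset)
    if not subset:
        raise ValueError("population subset must not be empty")
    unknown = [nm for nm in subset if nm not in result.syn_abs]
    if unknown:
        raise KeyError(f"unknown populations {unknown}")
    return np.sum([result.syn_abs[nm] for nm in subset], axis=0)


def bandpass(x: np.ndarray, lo: float, hi: float, sample_rate: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass (odd-reflection padding)."""
    nyquist = sample_rate / 2.0
    if not 0 < lo < hi < nyquist:
        raise ValueError(f"invalid band [{lo}, {hi}] Hz at fs = {sample_rate} Hz")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def population_rates(result: SimulationResult) -> dict[str, float]:
    """Mean firing rate per population: spikes / (size x duration), Hz."""
    if result.duration <= 0:
        return {p.type_name: 0.0 for p in result.populations}
    secs = result.duration / 1000.0
    return {p.type_name: result.spikes_of(p).size / (p.size * secs)
            for p in result.populations}
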