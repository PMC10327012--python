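"""Single-compartment Izhikevich neuron dynamics and firing phenotypes.

The hybrid model has quadratic voltage dynamics with a discontinuous
post-spike reset:

    C dv/dt = k (v - Vr)(v - Vt) - u + I
      du/dt = a (b (v - Vr) - u)
    if v >= Vpeak:  v <- Vmin,  u <- u + d

Integration is forward Euler at dt = 0.1 ms by default (the convention of
GPU spiking-network simulators); a spike is recorded at the step where v
crosses Vpeak and the trace shows Vpeak at that step (spike cutoff).

On top of the integrator this module provides step-current protocols,
frequency-current (F-I) curves sampled at 10 pA steps, rheobase by
bisection, and a simplified interspike-interval based classifier into the
firing-pattern vocabulary used for hippocampal neuron phenotypes
(NASP, ASP., TSTUT., PSTUT, SLN, SP and their dot-compositions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .knowledge import IzhikevichParams

DEFAULT_DT = 0.1  # ms

#: Closed vocabulary of firing-pattern labels.
FIRING_PATTERN_LABELS = (
    "NASP", "ASP.", "TSTUT.", "PSTUT", "SLN", "SP",
    "TSTUT.SLN", "TSTUT.PSTUT",
)


@dataclass
class NeuronState:
    """Instantaneous model state: membrane potential v (mV), recovery u (pA)."""

    v: float
    u: float


@dataclass(frozen=True)
class StepProtocol:
    """A square current pulse: amplitude (pA) from onset for duration (ms).

    The default mirrors the standard phenotyping stimulus: a 1 s pulse with
    100 ms of padding on either side.
    """

    amplitude: float
    onset: float = 100.0
    duration: float = 1000.0
    total_time: float = 1200.0

    def __post_init__(self) -> None:
        if self.onset < 0 or self.duration <= 0:
            raise ValueError("onset must be >= 0 and duration > 0")
        if self.onset + self.duration > self.total_time + 1e-9:
            raise ValueError("stimulus extends past total_time")

    def current(self, t: float) -> float:
        on = self.onset <= t < self.onset + self.duration
        return self.amplitude if on else 0.0


@dataclass
class ProtocolResult:
    """Voltage trace and spike times from one protocol run."""

    times: np.ndarray        # ms
    voltage: np.ndarray      # mV, Vpeak at spike steps
    spike_times: np.ndarray  # ms


def step_state(state: NeuronState, params: IzhikevichParams,
               I: float, dt: float) -> tuple[NeuronState, bool]:
    """One forward-Euler update followed by the reset check.

    Returns the new state and a spike flag; on reset v <- Vmin, u <- u + d.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (np.isfinite(state.v) and np.isfinite(state.u)):
        raise FloatingPointError("non-finite neuron state")
    p = params
    v = state.v + dt * (p.k * (state.v - p.Vr) * (state.v - p.Vt)
                        - state.u + I) / p.C
    u = state.u + dt * p.a * (p.b * (state.v - p.Vr) - state.u)
    if v >= p.Vpeak:
        return NeuronState(v=p.Vmin, u=u + p.d), True
    return NeuronState(v=v, u=u), False


def simulate_protocol(params: IzhikevichParams, protocol: StepProtocol,
                      dt: float = DEFAULT_DT) -> ProtocolResult:
    """Deterministic single-neuron response to a step-current protocol."""
    n_steps = int(round(protocol.total_time / dt))
    times = np.arange(n_steps) * dt
    voltage = np.empty(n_steps)
    spikes: list[float] = []
    state = NeuronState(v=params.Vr, u=0.0)
    for i in range(n_steps):
        t = times[i]
        state, spiked = step_state(state, params, protocol.current(t), dt)
        if spiked:
            spikes.append((i + 1) * dt)
            voltage[i] = params.Vpeak
        else:
            voltage[i] = state.v
    return ProtocolResult(times=times, voltage=voltage,
                          spike_times=np.asarray(spikes))


def f_i_curve(params: IzhikevichParams, I_max: float, I_step: float = 10.0,
              protocol: StepProtocol | None = None,
              dt: float = DEFAULT_DT) -> list[tuple[float, float]]:
    """Frequency-current curve sampled at ``I_step`` (default 10 pA) steps.

    Rate (Hz) = spikes during the stimulus / stimulus duration.
    """
    if I_step <= 0:
        raise ValueError("I_step must be positive")
    base = protocol or StepProtocol(amplitude=0.0)
    amplitudes = np.arange(0.0, I_max + I_step / 2, I_step)
    out = []
    for amp in amplitudes:
        proto = StepProtocol(amplitude=float(amp), onset=base.onset,
                             duration=base.duration, total_time=base.total_time)
        res = simulate_protocol(params, proto, dt=dt)
        n = int(np.count_nonzero(
            (res.spike_times >= proto.onset)
            & (res.spike_times <= proto.onset + proto.duration)))
        out.append((float(amp), n / (proto.duration / 1000.0)))
    return out


def rheobase(params: IzhikevichParams, I_hi: float, tol: float = 1.0,
             protocol: StepProtocol | None = None,
             dt: float = DEFAULT_DT) -> float:
    """Minimal spiking amplitude under the standard protocol, by bisection.

    Contract: ``simulate(r - tol)`` is silent and ``simulate(r + tol)``
    spikes.  Raises if even ``I_hi`` does not elicit a spike.
    """
    base = protocol or StepProtocol(amplitude=0.0)

    def spikes_at(amp: float) -> bool:
        proto = StepProtocol(amplitude=amp, onset=base.onset,
                             duration=base.duration, total_time=base.total_time)
        return simulate_protocol(params, proto, dt=dt).spike_times.size > 0

    if not spikes_at(I_hi):
        raise ValueError(f"no spiking at I_hi = {I_hi} pA")
    lo, hi = 0.0, I_hi
    if spikes_at(lo):
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if spikes_at(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Firing-pattern classification
# ---------------------------------------------------------------------------

def classify_firing_pattern(spike_times: Sequence[float],
                            protocol: StepProtocol) -> str:
    """Label a spike train with a firing-pattern phenotype.

    Simplified, deterministic ISI rules (package-defined thresholds, see
    docs/methods.md):

    * no spikes in the stimulus window -> ``SLN`` (silence);
      exactly one -> ``SP`` (single spike);
    * spiking confined to the first third of the stimulus with silence over
      at least its last half -> ``TSTUT.SLN`` (transient activity cut off
      by silence);
    * stuttering (ISI coefficient of variation >= 0.5 and at least one gap
      >= 3x the median ISI): confined to the first third -> ``TSTUT.``,
      gaps both early and late -> ``TSTUT.PSTUT``, otherwise ``PSTUT``;
    * last/first ISI ratio >= 1.5 -> ``ASP.`` (adapting);
    * otherwise ``NASP`` (non-adapting spiking).
    """
    start = protocol.onset
    end = protocol.onset + protocol.duration
    times = np.asarray([t for t in spike_times if start <= t <= end])
    if times.size == 0:
        return "SLN"
    if times.size == 1:
        return "SP"

    duration = protocol.duration
    last = float(times[-1])
    first_third = start + duration / 3.0
    confined_early = last <= first_third
    silent_tail = (end - last) >= duration / 2.0

    if confined_early and silent_tail:
        return "TSTUT.SLN"

    isis = np.diff(times)
    cv = float(np.std(isis) / np.mean(isis)) if np.mean(isis) > 0 else 0.0
    median_isi = float(np.median(isis))
    gap_mask = isis >= 3.0 * median_isi
    stuttering = cv >= 0.5 and bool(gap_mask.any())

    if stuttering:
        if confined_early:
            return "TSTUT."
        gap_starts = times[:-1][gap_mask]
        early_gaps = bool((gap_starts <= first_third).any())
        late_gaps = bool((gap_starts > first_third).any())
        if early_gaps and late_gaps:
            return "TSTUT.PSTUT"
        return "PSTUT"

    if isis[-1] >= 1.5 * isis[0] and isis[0] > 0:
        return "ASP."
    return "NASP"
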