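"""Tsodyks-Pawelzik-Markram (TPM) short-term synaptic plasticity.

Each synapse tracks an available resource fraction R (depression), a
utilization variable u (facilitation) and an instantaneous conductance g_t.
Between presynaptic spikes the state relaxes exponentially in closed form:

    R(t + dt) = 1 - (1 - R) exp(-dt / tau_r)       (recovery)
    u(t + dt) = u exp(-dt / tau_f)                 (facilitation decays)
    g(t + dt) = g_t exp(-dt / tau_d)               (conductance decays)

At a presynaptic spike, facilitation acts before release (the common TPM
convention; u relaxes toward 0 between spikes and the baseline U re-enters
at spike time):

    u+ = u + U (1 - u)
    released = R u+
    R+ = R - released
    g_t <- g_t + g released

With tau_f -> 0 the model reduces to depression-only dynamics (u == U at
every spike).  The synaptic drive onto a postsynaptic neuron at potential v
is the conductance-based current ``I = g_t (E_rev - v)`` in pA for g_t in
nS and potentials in mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .knowledge import TPMParams

#: Default reversal potentials (mV) by presynaptic polarity.
REVERSAL_POTENTIALS = {"excitatory": 0.0, "inhibitory": -70.0}


@dataclass(frozen=True)
class TPMState:
    """Synapse state: resources R, utilization u (both in [0,1]), g_t >= 0 nS."""

    R: float = 1.0
    u: float = 0.0
    g_t: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.R <= 1.0 and 0.0 <= self.u <= 1.0):
            raise ValueError(f"R={self.R}, u={self.u} outside [0, 1]")
        if self.g_t < 0:
            raise ValueError("conductance must be non-negative")


def decay_state(state: TPMState, params: TPMParams, elapsed: float) -> TPMState:
    """Closed-form relaxation over ``elapsed`` ms toward (R=1, u=0, g=0)."""
    if elapsed < 0:
        raise ValueError("elapsed time must be non-negative")
    if elapsed == 0.0:
        return state
    return TPMState(
        R=1.0 - (1.0 - state.R) * math.exp(-elapsed / params.tau_r),
        u=state.u * math.exp(-elapsed / params.tau_f),
        g_t=state.g_t * math.exp(-elapsed / params.tau_d),
    )


def on_presynaptic_spike(state: TPMState,
                         params: TPMParams) -> tuple[TPMState, float]:
    """Apply one presynaptic spike; returns (new state, released fraction).

    From rest (R=1, u=0) the released fraction is exactly U and the
    conductance jumps by g*U.
    """
    u_plus = state.u + params.U * (1.0 - state.u)
    released = state.R * u_plus
    return (
        TPMState(R=state.R - released, u=u_plus, g_t=state.g_t + params.g * released),
        released,
    )


def synaptic_current(g_t: float, v: float, reversal: float) -> float:
    """Conductance-based synaptic current I = g_t (E_rev - v), pA."""
    return g_t * (reversal - v)


def psc_amplitude_train(params: TPMParams,
                        spike_times: Sequence[float]) -> np.ndarray:
    """Per-spike conductance jumps (nS) for a presynaptic spike train.

    Alternates closed-form decay with the spike update.  Depressing pairs
    (large U, fast tau_f) yield decreasing amplitudes; facilitating pairs
    (small U, slow tau_f) yield growing early amplitudes.
    """
    times = np.asarray(list(spike_times), dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("spike times must be strictly increasing")
    state = TPMState()
    last = times[0] if times.size else 0.0
    amps = []
    for t in times:
        state = decay_state(state, params, float(t - last))
        state, released = on_presynaptic_spike(state, params)
        amps.append(params.g * released)
        last = t
    return np.asarray(amps)
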