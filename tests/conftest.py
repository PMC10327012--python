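"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import hippoloom as hl
from hippoloom.knowledge import IzhikevichParams


@pytest.fixture(scope="session")
def toy_kb() -> hl.KnowledgeBase:
    return hl.make_toy_circuit(0)


@pytest.fixture(scope="session")
def ca3_kb() -> hl.KnowledgeBase:
    return hl.make_ca3_demo(seed=0)


@pytest.fixture(scope="session")
def rs_params() -> IzhikevichParams:
    """A regular-spiking reference parameter set (pyramidal-like)."""
    return IzhikevichParams(C=100.0, k=0.7, Vr=-60.0, Vt=-40.0, Vpeak=35.0,
                            Vmin=-50.0, a=0.03, b=-2.0, d=100.0)


@pytest.fixture(scope="session")
def fs_params() -> IzhikevichParams:
    """A fast-spiking reference parameter set (interneuron-like)."""
    return IzhikevichParams(C=20.0, k=1.0, Vr=-55.0, Vt=-40.0, Vpeak=25.0,
                            Vmin=-45.0, a=0.15, b=2.0, d=30.0)


def dense_tpm_released_batch(tau_r: np.ndarray, tau_f: np.ndarray,
                             U: np.ndarray, spike_steps: np.ndarray,
                             dt: float = 0.001) -> np.ndarray:
    """Independent oracle: dense RK4 integration of the TPM ODE form.

    Integrates dR/dt = (1-R)/tau_r and du/dt = -u/tau_f on a fixed time
    grid (vectorized over trains) and applies the spike jump at each
    train's grid spike steps.  Returns the released fraction per spike,
    shape (n_trains, n_spikes).  ``spike_steps`` holds strictly increasing
    integer grid indices per row.
    """
    spike_steps = np.asarray(spike_steps, dtype=int)
    n_trains, n_spikes = spike_steps.shape
    R = np.ones(n_trains)
    u = np.zeros(n_trains)
    released = np.zeros((n_trains, n_spikes))
    next_idx = np.zeros(n_trains, dtype=int)
    rows = np.arange(n_trains)
    n_steps = int(spike_steps.max()) + 1

    def rk4_decay(x, tau, target):
        def f(y):
            return (target - y) / tau
        k1 = f(x)
        k2 = f(x + 0.5 * dt * k1)
        k3 = f(x + 0.5 * dt * k2)
        k4 = f(x + dt * k3)
        return x + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0

    for s in range(n_steps):
        pending = next_idx < n_spikes
        hit = pending & (spike_steps[rows, np.minimum(next_idx, n_spikes - 1)] == s)
        if hit.any():
            u_plus = u[hit] + U[hit] * (1.0 - u[hit])
            rel = R[hit] * u_plus
            released[rows[hit], next_idx[hit]] = rel
            R[hit] -= rel
            u[hit] = u_plus
            next_idx[hit] += 1
        R = rk4_decay(R, tau_r, 1.0)
        u = rk4_decay(u, tau_f, 0.0)
    return released
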