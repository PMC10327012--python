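"""Network co-simulation: equivalence, causality, LFP proxy, band filters."""

import numpy as np
import pytest

import hippoloom as hl
from hippoloom.engine import SimulationResult
from hippoloom.knowledge import TPMParams
from hippoloom.network import NetworkSpec, Population, SynapseGroup
from hippoloom.neuron import StepProtocol


TPM = TPMParams(g=1.0, tau_d=5.0, tau_r=400.0, tau_f=20.0, U=0.5)


def solo_network(params, name="solo", polarity="excitatory"):
    return NetworkSpec(populations=[Population(name, 1, 0)], groups=[],
                       izhikevich={name: params}, polarity={name: polarity},
                       master_seed=0)


def driven_pair_network(params, delay_ms=2.0, weight=1.0):
    """Neuron 0 drives neuron 1 through a single excitatory synapse."""
    pops = [Population("pre", 1, 0), Population("post", 1, 1)]
    grp = SynapseGroup("pre", "post", np.array([0]), np.array([1]),
                       np.array([weight]), np.array([delay_ms]), TPM)
    return NetworkSpec(populations=pops, groups=[grp],
                       izhikevich={"pre": params, "post": params},
                       polarity={"pre": "excitatory", "post": "excitatory"},
                       master_seed=0)


class TestRun:
    def test_empty_network(self):
        net = NetworkSpec(populations=[], groups=[], izhikevich={},
                          polarity={}, master_seed=0)
        res = hl.run(net, duration=10.0, background_drive=(0.0, 0.0))
        assert res.spike_times.size == 0
        assert res.traces == {}

    def test_single_neuron_matches_protocol_simulation(self, rs_params):
        net = solo_network(rs_params)
        res = hl.run(net, duration=500.0, background_drive=(250.0, 0.0),
                     seed=0)
        proto = StepProtocol(amplitude=250.0, onset=0.0, duration=500.0,
                             total_time=500.0)
        ref = hl.simulate_protocol(rs_params, proto)
        assert np.array_equal(res.spike_times, ref.spike_times)
        assert np.array_equal(res.traces[0], ref.voltage)

    def test_determinism_bit_level(self, ca3_kb, tmp_path):
        kb = hl.fill_defaults(ca3_kb)
        results = []
        for _ in range(2):
            net = hl.build_network(kb, scale=0.002, seed=5)
            res = hl.run(net, duration=200.0, seed=5)
            results.append(res)
        a, b = results
        assert np.array_equal(a.spike_neurons, b.spike_neurons)
        assert np.array_equal(a.spike_times, b.spike_times)
        for nm in a.syn_abs:
            assert np.array_equal(a.syn_abs[nm], b.syn_abs[nm])

    def test_psp_onset_at_spike_plus_delay(self, rs_params):
        delay = 2.0
        net = driven_pair_network(rs_params, delay_ms=delay)
        res = hl.run(net, duration=100.0, seed=0,
                     background_drive={"pre": (250.0, 0.0),
                                       "post": (0.0, 0.0)})
        pre_spikes = res.spikes_of(net.populations[0])
        assert pre_spikes.size > 0
        syn = res.syn_abs["post"]
        dt = res.meta["dt"]
        # syn_abs[s] is the synaptic current applied at time s*dt
        first_input_t = np.argmax(syn > 0) * dt
        assert first_input_t == pytest.approx(pre_spikes[0] + delay)
        # causality: strictly nothing before spike + delay
        before = int(round((pre_spikes[0] + delay) / dt))
        assert np.all(syn[:before] == 0.0)

    def test_single_spike_psc_envelope(self, rs_params):
        net = driven_pair_network(rs_params, delay_ms=1.0)
        # drive pre just long enough for exactly one spike
        res = hl.run(net, duration=60.0, seed=0,
                     background_drive={"pre": (90.0, 0.0),
                                       "post": (0.0, 0.0)})
        pre_spikes = res.spikes_of(net.populations[0])
        assert pre_spikes.size >= 1
        syn = res.syn_abs["post"]
        dt = res.meta["dt"]
        s0 = int(round((pre_spikes[0] + 1.0) / dt))
        jump = TPM.g * TPM.U
        decay = np.exp(-dt / TPM.tau_d)
        v_post = res.traces[1]
        upto = min(s0 + 30, len(syn))
        if pre_spikes.size > 1:
            upto = min(upto, int(round((pre_spikes[1] + 1.0) / dt)))
        for s in range(s0, upto):
            g_t = jump * decay ** (s - s0)
            v_before = v_post[s - 1] if s > 0 else rs_params.Vr
            expected = abs(g_t * (0.0 - v_before))
            assert syn[s] == pytest.approx(expected, rel=1e-9)

    def test_nonfinite_dynamics_named(self, rs_params):
        bad = hl.IzhikevichParams(C=0.01, k=50.0, Vr=-60.0, Vt=-40.0,
                                  Vpeak=float("inf"), Vmin=-50.0, a=0.03,
                                  b=-2.0, d=100.0)
        net = solo_network(bad, name="fragile")
        with pytest.raises(RuntimeError, match="fragile"):
            hl.run(net, duration=50.0, background_drive=(1e6, 0.0), seed=0)

    def test_dt_refinement_keeps_spike_counts_close(self, ca3_kb):
        kb = hl.fill_defaults(ca3_kb)
        net = hl.build_network(kb, scale=0.002, seed=4)
        drive = {p.type_name: (150.0, 0.0) for p in net.populations}
        n_coarse = hl.run(net, 300.0, dt=0.1, background_drive=drive,
                          seed=4).spike_times.size
        n_fine = hl.run(net, 300.0, dt=0.05, background_drive=drive,
                        seed=4).spike_times.size
        assert n_coarse > 0
        assert abs(n_fine - n_coarse) / n_coarse < 0.05


class TestLfpProxy:
    def _result(self, syn_abs):
        pops = [Population(nm, 1, i) for i, nm in enumerate(syn_abs)]
        return SimulationResult(
            spike_neurons=np.empty(0, dtype=np.int64),
            spike_times=np.empty(0), trace_times=np.arange(10.0), traces={},
            syn_abs={k: np.asarray(v, dtype=float)
                     for k, v in syn_abs.items()},
            populations=pops, duration=10.0,
            polarity={nm: "excitatory" for nm in syn_abs})

    def test_silent_network_zero_proxy(self):
        res = self._result({"A": np.zeros(10)})
        assert np.all(hl.lfp_proxy(res) == 0.0)

    def test_scaling_currents_scales_proxy(self):
        base = {"A": np.arange(10.0), "B": np.ones(10)}
        doubled = {k: 2 * v for k, v in base.items()}
        assert np.array_equal(hl.lfp_proxy(self._result(doubled)),
                              2 * hl.lfp_proxy(self._result(base)))

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            hl.lfp_proxy(self._result({"A": np.zeros(3)}), [])

    def test_unknown_population_rejected(self):
        with pytest.raises(KeyError):
            hl.lfp_proxy(self._result({"A": np.zeros(3)}), ["B"])


class TestBandpass:
    FS = 10000.0

    def _sine(self, freq, seconds=2.0):
        t = np.arange(int(seconds * self.FS)) / self.FS
        return np.sin(2 * np.pi * freq * t)

    def test_in_band_tone_preserved(self):
        x = self._sine(8.0)
        y = hl.bandpass(x, *hl.BANDS["theta"], sample_rate=self.FS)
        core = slice(len(x) // 4, -len(x) // 4)
        assert np.abs(y[core]).max() == pytest.approx(1.0, rel=0.1)

    def test_out_of_band_tone_attenuated(self):
        x = self._sine(8.0)
        y = hl.bandpass(x, *hl.BANDS["ripple"], sample_rate=self.FS)
        assert np.abs(y).max() < 0.1

    def test_zero_signal(self):
        assert np.all(hl.bandpass(np.zeros(1000), 4, 12, self.FS) == 0.0)

    @pytest.mark.parametrize("lo,hi", [(0.0, 10.0), (12.0, 4.0), (10.0, 6000.0)])
    def test_invalid_bands(self, lo, hi):
        with pytest.raises(ValueError):
            hl.bandpass(np.zeros(100), lo, hi, self.FS)


class TestPopulationRates:
    def test_silent_and_simple_rates(self, rs_params):
        net = solo_network(rs_params)
        res = hl.run(net, duration=1000.0, background_drive=(0.0, 0.0), seed=0)
        assert hl.population_rates(res) == {"solo": 0.0}

    def test_rate_definition(self):
        pop = Population("A", 2, 0)
        res = SimulationResult(
            spike_neurons=np.array([0] * 10), spike_times=np.linspace(0, 900, 10),
            trace_times=np.arange(10.0), traces={}, syn_abs={"A": np.zeros(10)},
            populations=[pop], duration=1000.0)
        assert hl.population_rates(res)["A"] == pytest.approx(5.0)
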