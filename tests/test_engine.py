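"""Engine contracts: determinism, event conservation, conditions."""

import numpy as np
import pytest

from bgdbs.engine import SimulationSpec, run_condition, simulate
from bgdbs.network import NetworkConfig, build_network
from bgdbs.stimulation import DBSProtocol

from conftest import tiny_sizes


def _quiet_d1_net():
    cfg = NetworkConfig(sizes=tiny_sizes(D1=50), seed_network=1,
                        seed_noise=1)
    net = build_network(cfg)
    net.ext_rate[:] = 0.0
    return net


class TestSimulate:
    def test_quiescent_network_stays_silent(self):
        # quadratic neurons without drive relax to the leak potential
        spec = SimulationSpec(duration=500, discard=100, n_realizations=1)
        sd = simulate(_quiet_d1_net(), spec=spec)
        assert sd.neuron.size == 0

    def test_byte_identical_given_seeds(self):
        cfg = NetworkConfig(sizes=tiny_sizes(GPe_TI=30, STN=30),
                            seed_network=4, seed_noise=9)
        spec = SimulationSpec(duration=400, discard=100, n_realizations=1)
        a = simulate(build_network(cfg), spec=spec)
        b = simulate(build_network(cfg), spec=spec)
        assert np.array_equal(a.neuron, b.neuron)
        assert np.array_equal(a.time, b.time)

    def test_noise_seed_changes_spikes(self):
        cfg = NetworkConfig(sizes=tiny_sizes(GPe_TI=30, STN=30),
                            seed_network=4, seed_noise=9)
        spec = SimulationSpec(duration=400, discard=100, n_realizations=1)
        a = simulate(build_network(cfg), spec=spec)
        b = simulate(build_network(cfg), spec=spec, seed_noise=10)
        assert not (a.time.size == b.time.size
                    and np.array_equal(a.time, b.time))

    def test_every_spike_delivered_once_per_synapse(self):
        # two-neuron chain with a static synapse: conductance jumps at the
        # target must match presynaptic spikes one-to-one after the delay
        cfg = NetworkConfig(sizes=tiny_sizes(GPe_TI=1, STN=1),
                            seed_network=5, seed_noise=5,
                            plasticity_mode="none")
        net = build_network(cfg)
        net.ext_rate[:] = 0.0
        net.syn_pre = np.array([1], dtype=np.int32)
        net.syn_post = np.array([0], dtype=np.int32)
        net.syn_weight = np.array([0.3])
        net.syn_delay = np.array([2.0])
        net.syn_chan = np.array([0], dtype=np.int8)
        net.syn_stp_class = np.array([-1], dtype=np.int8)
        net.neuron_params["Ie"][1] = 40.0
        net.neuron_params["Ie"][0] = 0.0
        spec = SimulationSpec(duration=500, discard=100, n_realizations=1)
        sd = simulate(net, spec=spec, record_neurons=[0])
        idx, t_sp = sd.population("STN")
        g = sd.rec["g_ex"][:, 0]
        jump_times = sd.rec["t"][np.nonzero(np.diff(g) > 0.1)[0] + 1]
        assert jump_times.size == t_sp.size
        assert np.allclose(np.sort(jump_times) - np.sort(t_sp), 2.0,
                           atol=0.05)

    def test_rate_increases_with_external_drive(self):
        rates = []
        for factor in (1.0, 2.0):
            cfg = NetworkConfig(sizes=tiny_sizes(STN=40), seed_network=2,
                                seed_noise=3)
            net = build_network(cfg)
            net.ext_rate *= factor
            spec = SimulationSpec(duration=1000, discard=200,
                                  n_realizations=1)
            sd = simulate(net, spec=spec)
            rates.append(sd.mean_rate("STN", (200, 1000)))
        assert rates[1] > rates[0]

    def test_mean_rate_window_accounting(self):
        cfg = NetworkConfig(sizes=tiny_sizes(STN=10), seed_network=2,
                            seed_noise=3)
        spec = SimulationSpec(duration=1000, discard=200, n_realizations=1)
        sd = simulate(build_network(cfg), spec=spec)
        sl = sd.pop_slices["STN"]
        in_window = np.sum((sd.time > 200) & (sd.time <= 1000))
        assert sd.mean_rate("STN", (200, 1000)) == pytest.approx(
            in_window / 10 / 0.8)


class TestTimeStepRobustness:
    def test_halved_step_preserves_rates_on_reduced_network(self):
        sizes = dict(D1=1500, D2=1500, FSN=105, GPe_TA=66, GPe_TI=195,
                     STN=102)
        rates = {}
        for dt in (0.04, 0.02):
            cfg = NetworkConfig(sizes=sizes, seed_network=11, seed_noise=11)
            spec = SimulationSpec(duration=2000, discard=500,
                                  n_realizations=1, dt=dt)
            sd = simulate(build_network(cfg), spec=spec)
            rates[dt] = np.array([sd.mean_rate(p, (500, 2000))
                                  for p in ("FSN", "GPe_TI", "STN")])
        rel = np.abs(rates[0.02] - rates[0.04]) / rates[0.04]
        assert np.all(rel < 0.05)


class TestRunCondition:
    def test_conditions_share_wiring(self):
        spec = SimulationSpec(duration=300, discard=100, n_realizations=1)
        cfg = NetworkConfig(sizes=tiny_sizes(GPe_TI=20, STN=20, D2=50))
        h = run_condition("healthy", spec=spec, config=cfg)
        p = run_condition("pd", spec=spec, config=cfg)
        assert h[0].meta["seed_network"] == p[0].meta["seed_network"]
        assert h[0].meta["Dd"] == 0.166 and p[0].meta["Dd"] == 0.5

    def test_dbs_alpha_zero_equals_pd(self):
        spec = SimulationSpec(duration=300, discard=100, n_realizations=1)
        cfg = NetworkConfig(sizes=tiny_sizes(GPe_TI=20, STN=20))
        pd = run_condition("pd", spec=spec, config=cfg)
        dbs0 = run_condition("pd_dbs", spec=spec, config=cfg,
                             protocol=DBSProtocol(mode="regular",
                                                  fraction=0.0))
        assert np.array_equal(pd[0].time, dbs0[0].time)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            run_condition("lesioned")

    def test_realization_count(self):
        spec = SimulationSpec(duration=300, discard=100, n_realizations=3)
        cfg = NetworkConfig(sizes=tiny_sizes(STN=5))
        assert len(run_condition("healthy", spec=spec, config=cfg)) == 3
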