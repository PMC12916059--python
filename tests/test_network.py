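"""Network realization: sizes, wiring statistics, depletion models."""

import numpy as np
import pytest

from bgdbs.network import (
    NetworkConfig, apply_synaptic_alterations, build_network,
    dopamine_input_rate, external_poisson_increments, _wire_projection,
)
from bgdbs.params import PROJECTIONS, POPULATION_SIZES, ProjectionSpec


@pytest.fixture(scope="module")
def default_net():
    return build_network(NetworkConfig(seed_network=7, seed_noise=7))


class TestBuild:
    def test_population_sizes(self, default_net):
        for name, size in POPULATION_SIZES.items():
            sl = default_net.population_of(name)
            assert sl.stop - sl.start == size

    def test_stn_gpe_ti_synapse_count_binomial(self, default_net):
        m = default_net.synapse_mask("STN", "GPe_TI")
        n_pairs = 408 * 780
        p = 0.0735
        mean, sd = n_pairs * p, np.sqrt(n_pairs * p * (1 - p))
        assert abs(m.sum() - mean) < 4 * sd

    def test_all_projection_counts_within_4_sigma(self, default_net):
        for proj in PROJECTIONS:
            n_src = POPULATION_SIZES[proj.source]
            n_tgt = POPULATION_SIZES[proj.target]
            pairs = n_src * n_tgt - (n_src if proj.source == proj.target else 0)
            mean = pairs * proj.probability
            sd = np.sqrt(pairs * proj.probability * (1 - proj.probability))
            count = default_net.synapse_mask(proj.source, proj.target).sum()
            assert abs(count - mean) < 4 * sd, (proj.source, proj.target)

    def test_no_autapses(self, default_net):
        assert np.all(default_net.syn_pre != default_net.syn_post)

    def test_zero_probability_gives_no_synapses(self, rng):
        proj = ProjectionSpec("D1", "D1", 0.0, 1.0, "inhibitory", 1.0)
        pre, post = _wire_projection(rng, proj, slice(0, 100), slice(0, 100))
        assert pre.size == 0

    def test_wiring_reproducible_given_seed(self):
        a = build_network(NetworkConfig(seed_network=3))
        b = build_network(NetworkConfig(seed_network=3))
        assert np.array_equal(a.syn_pre, b.syn_pre)
        assert np.array_equal(a.syn_post, b.syn_post)
        assert np.array_equal(a.syn_stp_class, b.syn_stp_class)

    def test_plastic_synapses_only_on_stn_gpe(self, default_net):
        plastic = default_net.syn_stp_class >= 0
        stn_gpe = (default_net.synapse_mask("STN", "GPe_TI")
                   | default_net.synapse_mask("STN", "GPe_TA"))
        assert np.array_equal(plastic, stn_gpe)

    def test_plasticity_mode_none_disables_all(self):
        net = build_network(NetworkConfig(plasticity_mode="none",
                                          seed_network=3))
        assert np.all(net.syn_stp_class == -1)

    def test_single_class_mode(self):
        net = build_network(NetworkConfig(
            plasticity_mode="single_class:depression_dominant",
            seed_network=3))
        plastic = net.syn_stp_class[net.syn_stp_class >= 0]
        assert plastic.size > 0
        assert np.all(plastic == 1)  # class index of depression_dominant

    def test_recurrent_channel_only_gpe_ti_self(self, default_net):
        rec = default_net.syn_chan == 2
        assert np.array_equal(rec,
                              default_net.synapse_mask("GPe_TI", "GPe_TI"))

    def test_unknown_population_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(sizes={"CTX": 10})


class TestDopamineDepletion:
    def test_input_rate_formula(self):
        assert dopamine_input_rate(0.166, 1.08) == pytest.approx(
            1.08 * 0.7998)
        assert dopamine_input_rate(0.5, 1.08) == pytest.approx(1.08 * 0.90)

    def test_identity_point(self):
        assert dopamine_input_rate(5.0 / 6.0, 2.0) == pytest.approx(2.0)

    def test_pd_raises_d2_drive_only(self):
        healthy = build_network(NetworkConfig(Dd=0.166, seed_network=5))
        pd = build_network(NetworkConfig(Dd=0.5, seed_network=5))
        d2 = healthy.population_of("D2")
        assert np.all(pd.ext_rate[d2] > healthy.ext_rate[d2])
        others = np.ones(healthy.n_neurons, bool)
        others[d2] = False
        assert np.array_equal(pd.ext_rate[others], healthy.ext_rate[others])
        # wiring identical: the depletion scalar only touches the drive
        assert np.array_equal(pd.syn_pre, healthy.syn_pre)


class TestSynapticAlterations:
    def test_phi_zero_is_identity(self):
        assert apply_synaptic_alterations(PROJECTIONS, 0.0) == PROJECTIONS

    def _find(self, projs, src, tgt):
        return next(p for p in projs if p.source == src and p.target == tgt)

    def test_stn_gpe_weight_scaling(self):
        out = apply_synaptic_alterations(PROJECTIONS, -0.4)
        for tgt in ("GPe_TI", "GPe_TA"):
            base = self._find(PROJECTIONS, "STN", tgt).weight
            assert self._find(out, "STN", tgt).weight == pytest.approx(
                base * (1 + 0.18))

    def test_fsn_d2_probability_scaling(self):
        out = apply_synaptic_alterations(PROJECTIONS, -0.4)
        assert self._find(out, "FSN", "D2").probability == pytest.approx(
            0.0262 * 1.36)

    def test_msn_rows_use_positive_beta(self):
        # the two striato-striatal rows carry +0.88, so depletion weakens them
        out = apply_synaptic_alterations(PROJECTIONS, -0.4)
        base = self._find(PROJECTIONS, "D1", "D2")
        assert self._find(out, "D1", "D2").weight == pytest.approx(
            base.weight * (1 - 0.88 * 0.4))
        assert self._find(out, "D1", "D2").probability == pytest.approx(
            base.probability * (1 - 0.88 * 0.4))

    def test_positive_phi_rejected(self):
        with pytest.raises(ValueError):
            apply_synaptic_alterations(PROJECTIONS, 0.1)


class TestExternalDrive:
    def test_zero_rate_no_events(self, rng):
        counts = external_poisson_increments(0.0, 0.04, 1000, rng, size=3)
        assert counts.sum() == 0

    def test_poisson_mean_matches(self, rng):
        counts = external_poisson_increments(1.12, 0.04, 10**6, rng)
        assert counts.mean() == pytest.approx(0.0448, rel=0.01)

    def test_counting_statistics_over_window(self, rng):
        total = external_poisson_increments(0.5, 1.0, 1000, rng).sum()
        assert abs(total - 500) < 3 * np.sqrt(500)
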