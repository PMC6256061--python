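"""LIF dynamics, offsets, routing, timers, and P-invariance."""

import numpy as np
import pytest

from spikecore import Core, CoreConfig, TIMER_MAX

from conftest import make_pair


def quiet_core(**kw):
    defaults = dict(n_axons=8, n_neurons=8, n_fanout=4, p=2, alpha=0.0, theta=10.0)
    defaults.update(kw)
    cfg_keys = CoreConfig.__dataclass_fields__
    cfg = CoreConfig(**{k: v for k, v in defaults.items() if k in cfg_keys})
    return Core(cfg, **{k: v for k, v in defaults.items() if k not in cfg_keys})


class TestIntegrate:
    def test_no_spikes_leaves_potentials_unchanged(self):
        core = quiet_core()
        core.step(np.zeros(8, dtype=bool))
        assert np.all(core.V == 0.0)

    def test_single_spike_scaled_contribution(self):
        codes = np.zeros((8, 4), dtype=np.int64)
        codes[0] = 6
        core = quiet_core(
            weight_codes=codes, weight_step=1.0, scale_codes=np.full(8, 2),
            scale_step=0.25, axonal_offsets=0,
        )
        spikes = np.zeros(8, dtype=bool)
        spikes[0] = True
        core.step(spikes)
        # scale value 0.5 x weight 6 = 3 inside the fan-out window
        assert np.allclose(core.V[:4], 3.0)
        assert np.all(core.V[4:] == 0.0)

    def test_disjoint_offset_windows_do_not_interact(self):
        codes = np.ones((8, 4), dtype=np.int64)
        offs = np.zeros(8, dtype=np.int64)
        offs[1] = 4
        core = quiet_core(weight_codes=codes, axonal_offsets=offs)
        spikes = np.zeros(8, dtype=bool)
        spikes[[0, 1]] = True
        core.step(spikes)
        assert np.allclose(core.V[:4], 1.0) and np.allclose(core.V[4:], 1.0)

    def test_refractory_neuron_receives_no_input(self):
        codes = np.full((8, 4), 7, dtype=np.int64)
        core = quiet_core(weight_codes=codes, theta=5.0, refractory_steps=3)
        spikes = np.zeros(8, dtype=bool)
        spikes[0] = True
        core.step(spikes)  # neurons 0..3 fire, enter refractory
        core.step(spikes)
        assert np.all(core.V[:4] == 0.0)


class TestLeakAndFire:
    def test_rest_is_a_fixed_point(self):
        core = quiet_core(alpha=0.5, v_rest=-1.0)
        core.V[:] = -1.0
        core.leak()
        assert np.allclose(core.V, -1.0)

    def test_leak_hand_value(self):
        core = quiet_core(alpha=0.25)
        core.V[0] = 16.0
        core.leak()
        assert core.V[0] == pytest.approx(12.0)

    def test_alpha_zero_is_pure_integrator(self):
        codes = np.ones((8, 4), dtype=np.int64)
        core = quiet_core(weight_codes=codes, alpha=0.0)
        spikes = np.zeros(8, dtype=bool)
        spikes[0] = True
        for _ in range(3):
            core.step(spikes)
        assert np.allclose(core.V[:4], 3.0)

    def test_threshold_comparison_is_inclusive(self):
        core = quiet_core(theta=1.0)
        core.V[0] = 1.0
        core.V[1] = 1.0 - 1e-9
        fired = core.fire()
        assert fired[0] and not fired[1]

    def test_fire_resets_and_blocks_for_refractory_period(self):
        codes = np.full((8, 4), 7, dtype=np.int64)
        core = quiet_core(weight_codes=codes, theta=5.0, refractory_steps=2)
        spikes = np.zeros(8, dtype=bool)
        spikes[0] = True
        assert core.step(spikes)[:4].all()  # fires
        assert not core.step(spikes)[:4].any()  # refractory step 1
        assert not core.step(spikes)[:4].any()  # refractory step 2
        assert core.step(spikes)[:4].all()  # integrates again


class TestRouting:
    def test_no_recurrence_without_neuronal_offset(self):
        core = quiet_core(neuronal_offset=0)
        fired = np.ones(8, dtype=bool)
        assert not core.route_spikes(fired).any()

    def test_routed_axon_index_arithmetic(self):
        core, _ = make_pair(n_axons=16, n_neurons=16, n_fanout=8, neuronal_offset=4)
        fired = np.zeros(16, dtype=bool)
        fired[0] = True
        routed = core.route_spikes(fired)
        assert routed[16 - 4 + 0] and routed.sum() == 1

    def test_neuron_at_offset_boundary_routes_nowhere(self):
        core, _ = make_pair(n_axons=16, n_neurons=16, n_fanout=8, neuronal_offset=4)
        fired = np.zeros(16, dtype=bool)
        fired[4] = True  # first neuron outside the routed range
        assert not core.route_spikes(fired).any()

    def test_recurrent_spike_arrives_next_step_ored_with_external(self):
        core = quiet_core(neuronal_offset=2, theta=0.5,
                          weight_codes=np.ones((8, 4), dtype=np.int64))
        spikes = np.zeros(8, dtype=bool)
        spikes[0] = True
        fired = core.step(spikes)
        assert fired[:4].all()
        core.step(np.zeros(8, dtype=bool))
        # neurons 0,1 fired -> axons 6,7 spike this step
        assert core.axon_spikes[6] and core.axon_spikes[7]


class TestTimers:
    def test_timers_start_saturated(self):
        core = quiet_core()
        assert np.all(core.axon_timer == TIMER_MAX)
        assert np.all(core.neuron_timer == TIMER_MAX)

    def test_axon_timer_counts_steps_since_spike(self):
        core = quiet_core()
        spikes = np.zeros(8, dtype=bool)
        spikes[3] = True
        core.step(spikes)
        for k in range(1, 20):
            core.step(np.zeros(8, dtype=bool))
            assert core.axon_timer[3] == min(TIMER_MAX, k + 1)

    def test_timers_never_exceed_saturation_under_random_raster(self):
        core, oracle = make_pair(learn=False, seed=11)
        rng = np.random.default_rng(11)
        for _ in range(100):
            core.step(rng.random(16) < 0.3)
            assert core.axon_timer.max() <= TIMER_MAX
            assert core.neuron_timer.max() <= TIMER_MAX


class TestStepSemantics:
    def test_quiescent_core_stays_quiescent(self):
        core = quiet_core()
        for _ in range(20):
            fired = core.step(np.zeros(8, dtype=bool))
        assert not fired.any()
        assert np.all(core.axon_timer == TIMER_MAX)
        assert np.all(core.memory.to_dense() == 0)

    def test_three_step_hand_trace(self):
        """4x4 toy: known weights, alpha=0.5, theta=2; potentials computed by hand."""
        codes = np.array([[2, 0, 0, 0], [0, 2, 0, 0], [1, 1, 1, 1], [0, 0, 0, 2]])
        cfg = CoreConfig(n_axons=4, n_neurons=4, n_fanout=4, p=2, alpha=0.5, theta=2.0)
        core = Core(cfg, weight_codes=codes, weight_step=1.0, axonal_offsets=0)
        # t=0: axon 0 spikes -> V = [2,0,0,0] -> leak [1,0,0,0]; no fire
        fired = core.step(np.array([1, 0, 0, 0], dtype=bool))
        assert not fired.any() and np.allclose(core.V, [1, 0, 0, 0])
        # t=1: axon 2 spikes -> V = [2,1,1,1] -> leak [1,.5,.5,.5]; no fire
        fired = core.step(np.array([0, 0, 1, 0], dtype=bool))
        assert not fired.any() and np.allclose(core.V, [1.0, 0.5, 0.5, 0.5])
        # t=2: axons 0,2 spike -> V=[4,1.5,1.5,1.5] -> leak [2,...]; neuron 0 fires
        fired = core.step(np.array([1, 0, 1, 0], dtype=bool))
        assert fired.tolist() == [True, False, False, False]
        assert core.V[0] == 0.0

    def test_membrane_bound_with_leak(self):
        """|V - V_rest| stays under max step input / alpha for alpha > 0."""
        core, _ = make_pair(alpha=0.25, theta=1e9, refractory_steps=0, seed=13)
        max_in = np.abs(
            core.scale_values[:, None] * core.memory.to_dense() * core.weight_step
        ).sum(axis=0).max()
        rng = np.random.default_rng(13)
        for _ in range(200):
            core.step(rng.random(16) < 0.5)
        assert np.max(np.abs(core.V)) <= max_in / 0.25 + 1e-9


class TestPInvariance:
    @pytest.mark.parametrize("learn", [False, True])
    def test_outputs_identical_across_p(self, learn):
        rasters, finals = [], []
        rng = np.random.default_rng(17)
        raster = rng.random((80, 16)) < 0.25
        for p in (1, 2, 4, 8):
            core, _ = make_pair(p=p, learn=learn, neuronal_offset=4, seed=17)
            out = core.run(raster)
            rasters.append(out)
            finals.append(core.memory.to_dense())
        for out, w in zip(rasters[1:], finals[1:]):
            assert np.array_equal(out, rasters[0])
            assert np.array_equal(w, finals[0])


class TestConfigValidation:
    def test_p_must_divide_dimensions(self):
        with pytest.raises(ValueError):
            CoreConfig(n_axons=8, n_neurons=8, n_fanout=6, p=4)

    def test_offsets_bounded(self):
        cfg = CoreConfig(n_axons=8, n_neurons=8, n_fanout=4, p=2)
        with pytest.raises(ValueError):
            Core(cfg, axonal_offsets=5)  # max is n_neurons - n_fanout = 4

    def test_neuronal_offset_bounded(self):
        with pytest.raises(ValueError):
            CoreConfig(n_axons=4, n_neurons=8, n_fanout=4, p=2, neuronal_offset=5)

    def test_alpha_range(self):
        with pytest.raises(ValueError):
            CoreConfig(n_axons=4, n_neurons=4, n_fanout=4, p=1, alpha=1.5)
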