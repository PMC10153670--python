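"""SpikeProp learning rules against hand values and the finite-difference
oracle."""

import numpy as np
import pytest

import stnet as st
from stnet import learning as L

CFG = st.CodingConfig(t_early=3.0, t_late=10.0)
LCFG = st.LearningConfig(eta=0.03)


class TestLoss:
    def test_exact_match_is_zero(self):
        sv = st.SpikeVector.all_fired([3.0, 10.0])
        assert st.loss(sv, st.encode_labels(0, 2, CFG)) == 0.0

    def test_hand_value(self):
        sv = st.SpikeVector.all_fired([4.0, 10.0])
        assert st.loss(sv, st.encode_labels(0, 2, CFG)) == pytest.approx(0.5)

    def test_permutation_symmetry(self, rng):
        t = rng.uniform(0, 10, 5)
        d = rng.uniform(0, 10, 5)
        p = rng.permutation(5)
        a = st.loss(st.SpikeVector.all_fired(t), st.ExpectedSpikes(times=d))
        b = st.loss(st.SpikeVector.all_fired(t[p]),
                    st.ExpectedSpikes(times=d[p]))
        assert a == pytest.approx(b)


class TestOutputDelta:
    def _setup(self, rng, times=None):
        layer = st.SRMLayer(weights=rng.uniform(0.1, 0.6, (3, 2, 2)),
                            delays=np.array([1.0, 2.0]))
        coding = st.SpikeVector.all_fired([1.0, 1.5, 2.0])
        actual = st.SpikeVector.all_fired(times if times is not None
                                          else [5.0, 6.0])
        return layer, coding, actual

    def test_zero_error_gives_zero_delta(self, rng):
        layer, coding, actual = self._setup(rng, times=[3.0, 10.0])
        deltas = L.output_delta(actual, st.encode_labels(0, 2, CFG),
                                coding, layer, LCFG)
        np.testing.assert_allclose(deltas, 0.0)

    def test_small_denominator_is_floored(self):
        layer = st.SRMLayer(weights=np.array([[[1e-6]]]),
                            delays=np.array([1.0]))
        coding = st.SpikeVector.all_fired([1.0])
        actual = st.SpikeVector.all_fired([5.0])
        deltas = L.output_delta(actual, st.ExpectedSpikes(times=[4.0]),
                                coding, layer, LCFG)
        # denominator ~1e-6 floored to 0.1: delta = (4-5)/0.1 = -10
        assert deltas[0] == pytest.approx(-10.0, rel=1e-3)

    def test_unfired_output_gets_positive_push(self):
        """A silent output's update must increase its drive to fire."""
        layer = st.SRMLayer(weights=np.array([[[0.1]]]),
                            delays=np.array([1.0]))
        coding = st.SpikeVector.all_fired([1.0])
        actual = st.SpikeVector(times=[10.0], fired=[False])
        deltas = L.output_delta(actual, st.ExpectedSpikes(times=[3.0]),
                                coding, layer, LCFG)
        dv = L.output_weight_update(deltas, coding, actual, layer, LCFG.eta)
        assert dv[0, 0, 0] > 0  # weight grows -> earlier firing


class TestOutputWeightUpdate:
    def test_zero_delta_zero_update(self, rng):
        layer = st.SRMLayer(weights=rng.uniform(0, 1, (2, 2, 2)),
                            delays=np.array([1.0, 2.0]))
        coding = st.SpikeVector.all_fired([1.0, 2.0])
        actual = st.SpikeVector.all_fired([5.0, 6.0])
        dv = L.output_weight_update(np.zeros(2), coding, actual, layer, 0.03)
        np.testing.assert_array_equal(dv, 0.0)

    def test_acausal_synapse_untouched(self):
        """A synapse whose PSP starts after the output spike gets no update."""
        layer = st.SRMLayer(weights=np.array([[[0.5]]]),
                            delays=np.array([3.0]))
        coding = st.SpikeVector.all_fired([4.0])  # arrives at 7
        actual = st.SpikeVector.all_fired([6.0])  # fired before arrival
        dv = L.output_weight_update(np.array([1.0]), coding, actual, layer,
                                    0.03)
        assert dv[0, 0, 0] == 0.0


class TestHiddenTimeGradient:
    def test_zero_deltas_zero_gradient(self, rng):
        layer = st.SRMLayer(weights=rng.uniform(0, 1, (3, 2, 2)),
                            delays=np.array([1.0, 2.0]))
        g = L.hidden_time_gradient(np.zeros(2), st.SpikeVector.all_fired([5., 6.]),
                                   st.SpikeVector.all_fired([1., 2., 3.]), layer)
        np.testing.assert_array_equal(g, 0.0)

    def test_kernel_peak_contributes_zero(self):
        # single path at its kernel peak: t_j - t_q - d = tau -> eps' = 0
        layer = st.SRMLayer(weights=np.array([[[1.0]]]),
                            delays=np.array([1.0]))
        g = L.hidden_time_gradient(np.array([1.0]),
                                   st.SpikeVector.all_fired([9.0]),
                                   st.SpikeVector.all_fired([1.0]), layer)
        assert g[0] == pytest.approx(0.0, abs=1e-14)


class TestAnnUpdate:
    def test_zero_time_gradient_zero_update(self, rng):
        cs = st.reciprocal_encode(np.array([0.5, 0.4]), CFG)
        dw = L.cstnet_ann_update(np.array([0.2, 1.0]), np.array([0.5, 0.4]),
                                 np.zeros(2), cs, 0.03, 1.0)
        np.testing.assert_array_equal(dw, 0.0)

    def test_clamped_column_zeroed(self):
        R = np.array([0.5, 0.05])  # second clamps (t = 20 -> T)
        cs = st.reciprocal_encode(R, CFG)
        dw = L.cstnet_ann_update(np.array([1.0, 1.0]), R, np.ones(2), cs,
                                 0.03, 1.0)
        assert np.all(dw[:, 1] == 0.0)
        assert np.all(dw[:, 0] != 0.0)


class TestFiniteDifferenceOracle:
    def test_zero_effect_parameter(self):
        params = np.array([1.0, 2.0])
        fd = L.finite_difference_oracle(lambda: 42.0, params, 0)
        assert fd == 0.0
        assert params[0] == 1.0  # restored

    def test_matches_analytic_chain_on_quadratic(self):
        params = np.array([3.0])
        fd = L.finite_difference_oracle(lambda: 0.5 * params[0] ** 2,
                                        params, 0)
        assert fd == pytest.approx(3.0, rel=1e-8)

    def test_central_difference_order(self):
        params = np.array([2.0])
        f = lambda: params[0] ** 3
        e1 = abs(L.finite_difference_oracle(f, params, 0, h=1e-2) - 12.0)
        e2 = abs(L.finite_difference_oracle(f, params, 0, h=5e-3) - 12.0)
        assert e2 < e1 / 3.0  # O(h^2) halving of h -> ~quartering of error


class TestGradientAgreement:
    """Analytic updates / (-eta) agree with full-resimulation central
    differences on random small networks (the deep correctness check runs
    in the acceptance suite with 20 networks per architecture)."""

    def test_cstnet_small_sample(self):
        res = st.gradient_check_cstnet(n_networks=3, seed=7)
        assert res.median <= 1e-2
        assert len(res.errors) > 50

    def test_pstnet_small_sample(self):
        res = st.gradient_check_pstnet(n_networks=2, seed=7)
        assert res.median <= 1e-2
        assert len(res.errors) > 30


class TestDescentAndDecay:
    def test_one_step_decreases_loss_on_fixed_sample(self):
        """A small SpikeProp step reduces E for >= 90% of random nets."""
        wins = trials = 0
        master = np.random.default_rng(99)
        sim = st.SimulationConfig(dt=1e-3, refine=True)
        lcfg = st.LearningConfig(eta=0.005)
        while trials < 20:
            rng = np.random.default_rng(master.integers(2 ** 31))
            m = st.build_cstnet(3, 2, 4, 3, sim=sim, rng=rng)
            x = rng.uniform(0.2, 0.8, 3)
            y_enc = st.encode_labels(int(rng.integers(2)), 2, m.coding)
            _, cs, out = st.cstnet_forward(x, m)
            if not out.fired.all():
                continue
            e0 = st.loss(out, y_enc)
            if e0 < 1e-6:
                continue
            deltas = L.output_delta(out, y_enc, cs, m.out, lcfg)
            m.out.weights += L.output_weight_update(deltas, cs, out, m.out,
                                                    lcfg.eta)
            e1 = st.loss(st.cstnet_forward(x, m)[2], y_enc)
            trials += 1
            wins += e1 < e0
        assert wins >= 18

    def test_learning_rate_decay_schedule(self):
        lc = st.LearningConfig(eta=0.1, decay=0.95)
        assert lc.rate_at(0) == pytest.approx(0.1)
        assert lc.rate_at(3) == pytest.approx(0.1 * 0.95 ** 3)
        assert st.LearningConfig(eta=0.03).rate_at(50) == pytest.approx(0.03)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            st.LearningConfig(eta=1.5)
        with pytest.raises(ValueError):
            st.LearningConfig(decay=0.0)
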