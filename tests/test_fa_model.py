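"""FA spring-network: solves, conservation laws, control regimes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsmod.errors import InvalidInputError, ParameterError
from tsmod.fa_model import (ControlClassification, Element, FaNetwork,
                            LoadInput, build_network, ensemble_classify,
                            solve_load, stiffness_force_relation)


class TestBuildNetwork:
    def test_forced_placement_two_sensors_two_layers(self):
        net = build_network(2, 0, 1.0, 1.0, n_layers=2, seed=0)
        assert [len(layer) for layer in net.layers] == [1, 1]

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_composition_conserved(self, seed):
        net = build_network(7, 13, 0.5, 2.0, seed=seed)
        assert net.counts() == {"S": 7, "L": 13}

    def test_seed_determinism(self):
        a = build_network(5, 15, 1.0, 2.0, seed=42)
        b = build_network(5, 15, 1.0, 2.0, seed=42)
        assert a.layers == b.layers

    def test_stratified_pins_sensors_to_first_layer(self):
        net = build_network(4, 10, 1.0, 1.0, seed=1, stratified=True)
        assert sum(e.kind == "S" for e in net.layers[0]) == 4
        assert all(e.kind == "L" for e in net.layers[1])

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            build_network(0, 1, 1.0, 1.0, n_layers=2, seed=0)
        with pytest.raises(ParameterError):
            build_network(2, 2, -1.0, 1.0, seed=0)


class TestSolveLoad:
    def test_series_layers_share_extension_equally(self):
        net = FaNetwork([[Element("S", 2.0)], [Element("L", 2.0)]])
        res = solve_load(net, LoadInput("extension", 3.0))
        np.testing.assert_allclose(res.layer_extension, [1.5, 1.5])
        np.testing.assert_allclose(res.element_force, [3.0, 3.0])

    def test_parallel_layer_shares_force_equally(self):
        net = FaNetwork([[Element("S", 1.0)] * 4])
        res = solve_load(net, LoadInput("force", 8.0))
        np.testing.assert_allclose(res.element_force, 2.0)

    def test_parallel_extension_sharing_mechanism(self):
        # equal extensions, stiffness-proportional forces: the seed of
        # extension-control
        net = FaNetwork([[Element("S", 1.0), Element("L", 3.0)]])
        res = solve_load(net, LoadInput("extension", 2.0))
        np.testing.assert_allclose(res.element_extension, 2.0)
        np.testing.assert_allclose(res.element_force, [2.0, 6.0])

    @given(seed=st.integers(0, 10_000),
           mode=st.sampled_from(["force", "extension"]))
    @settings(max_examples=40, deadline=None)
    def test_balance_and_energy(self, seed, mode):
        net = build_network(6, 14, 0.7, 2.5, seed=seed)
        res = solve_load(net, LoadInput(mode, 5.0))
        # every layer transmits the full force
        for j in range(net.n_layers):
            sel = res.element_layer == j
            assert res.element_force[sel].sum() == pytest.approx(
                res.total_force, rel=1e-9)
        # elastic energy equals the work of the bulk input
        energy = 0.5 * np.sum(res.element_stiffness
                              * res.element_extension ** 2)
        if mode == "extension":
            assert energy == pytest.approx(
                0.5 * res.total_force * res.total_extension, rel=1e-9)
        else:
            assert energy == pytest.approx(
                0.5 * np.sum(res.element_force * res.element_extension),
                rel=1e-9)

    def test_one_layer_extension_input_uniform(self):
        net = build_network(3, 9, 0.5, 5.0, n_layers=1, seed=3)
        res = solve_load(net, LoadInput("extension", 4.0))
        assert np.ptp(res.element_extension) == 0.0


class TestClassification:
    def test_force_input_always_force_controlled(self):
        comps = [dict(n_sensor=s, n_linker=60 - s, k_sensor=r, k_linker=1.0)
                 for s in (6, 30, 54) for r in (0.1, 1.0, 10.0)]
        rows = ensemble_classify(comps, LoadInput("force", 10.0),
                                 n_realizations=60, seed=5)
        assert all(r["regime"] == "force-controlled" for r in rows)

    def test_extension_input_regime_corners(self):
        soft_rare = dict(n_sensor=6, n_linker=54, k_sensor=0.1, k_linker=1.0)
        stiff_abundant = dict(n_sensor=54, n_linker=6, k_sensor=10.0,
                              k_linker=1.0)
        rows = ensemble_classify([soft_rare, stiff_abundant],
                                 LoadInput("extension", 10.0),
                                 n_realizations=100, seed=6)
        assert rows[0]["regime"] == "extension-controlled"
        assert rows[1]["regime"] == "force-controlled"

    def test_sensorless_compositions_skipped(self):
        with pytest.warns(UserWarning):
            rows = ensemble_classify(
                [dict(n_sensor=0, n_linker=10, k_sensor=1.0, k_linker=1.0)],
                LoadInput("force", 1.0), n_realizations=5, seed=0)
        assert rows == []

    def test_margin_boundary_gives_mixed(self):
        cls = ControlClassification.from_variant_means(
            [1.0, 1.2, 1.4], [1.0, 1.2, 1.4], n_sensors=3)
        assert cls.regime == "mixed"


class TestStiffnessForceRelation:
    def test_linear_in_deep_extension_control(self):
        rel = stiffness_force_relation(
            [1.0, 2.0, 3.0], LoadInput("extension", 10.0), n_sensor=3,
            n_linker=57, k_linker=10.0, n_realizations=150, seed=9)
        assert rel["r_squared"] > 0.99
        # slope estimates the shared extension; forces ~ k * delta
        ratios = rel["mean_force_pN"] / rel["stiffness_pN_per_nm"]
        assert np.ptp(ratios) / ratios.mean() < 0.05

    def test_equal_stiffness_equal_force(self):
        rel = stiffness_force_relation(
            [2.0, 2.0, 2.0], LoadInput("extension", 5.0), n_sensor=2,
            n_linker=38, k_linker=4.0, n_realizations=150, seed=1)
        f = rel["mean_force_pN"]
        assert np.ptp(f) / f.mean() < 0.05

    def test_force_mode_rejected(self):
        with pytest.raises(InvalidInputError):
            stiffness_force_relation([1.0, 2.0], LoadInput("force", 5.0),
                                     n_sensor=2, n_linker=8, k_linker=1.0)
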