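"""Topology invariants and the deterministic rate law."""

import numpy as np
import pytest
from scipy.optimize import brentq

import panfate as pf
from panfate.network import GENE_INDEX, N_STATE, N_TF


class TestTopology:
    def test_state_dimension(self, network):
        assert len(network.gene_names) == 10
        assert network.n_state == 11

    def test_nothing_regulates_hnf6(self, network):
        assert all(e.target != "Hnf6" for e in network.edges)

    @pytest.mark.parametrize("a,b", [("Ptf1a", "Ngn3"), ("Pax4", "Arx"), ("MafA", "DeltaGene")])
    def test_cross_inhibition_pairs_are_mutual(self, network, a, b):
        assert network.has_edge(a, b, -1) and network.has_edge(b, a, -1)

    def test_table_edges_present(self, network):
        assert network.has_edge("Pax4", "Arx", -1)
        assert network.has_edge("Hnf6", "Ngn3", +1)
        assert network.has_edge("Arx", "Brn4", +1)
        assert network.has_edge("Pdx1", "MafA", +1)

    def test_no_duplicate_edges(self, network):
        keys = [(e.source, e.target) for e in network.edges]
        assert len(keys) == len(set(keys))

    def test_self_loop_roster(self, network):
        selfed = {e.source for e in network.edges if e.is_self}
        assert selfed == {"Ptf1a", "MafA", "DeltaGene", "Pax6", "Brn4"}

    def test_alternative_is_strict_superset(self, network):
        alt = pf.build_alternative_network()
        master_set = network.edge_set()
        alt_set = alt.edge_set()
        assert master_set < alt_set
        assert alt_set - master_set == {("Pdx1", "Ptf1a", -1), ("Pdx1", "Ngn3", -1)}
        assert alt.in_degree("Ngn3") == network.in_degree("Ngn3") + 1
        assert alt.variant == "alternative"

    def test_network_dict_round_trip(self, network):
        clone = pf.GeneNetwork.from_dict(network.to_dict())
        assert clone.edge_set() == network.edge_set()
        assert clone.variant == network.variant


class TestProductionRate:
    def test_zero_inputs_give_zero_production(self, network, params):
        x = np.zeros(N_STATE)
        for gene in ("Ngn3", "Pax4", "Arx"):  # no basal drive, no self loop
            assert pf.production_rate(gene, x, network, params) == 0.0

    def test_bounded_by_a(self, network, params, kernel):
        rng = np.random.default_rng(0)
        states = rng.uniform(0, 8, size=(200, N_STATE))
        S = kernel.sigmoid(states)
        assert np.all(S >= 0) and np.all(S <= 1)

    def test_self_latch_fixed_point_matches_bisection_oracle(self, params):
        # an isolated self-activating gene (a=4, k=1): the root of
        # a * u/(1+u) - x with u = (x/x0)^m, found independently by brentq
        a, x0, m = 4.0, params.self_scale, params.self_hill
        f = lambda x: a * (x / x0) ** m / (1 + (x / x0) ** m) - x
        root = brentq(f, 3.0, a)
        # relax the map numerically from above the ignition threshold
        x = 3.0
        for _ in range(500):
            x = x + 0.05 * f(x)
        assert x == pytest.approx(root, abs=1e-6)
        assert root > 3.5  # the latch sustains a high on-state

    def test_inhibitor_monotonicity(self, network, params):
        # raising Ngn3 (an inhibitor of Ptf1a) never increases Ptf1a production
        base = np.zeros(N_STATE)
        base[GENE_INDEX["Hnf6"]] = 2.2
        prev = np.inf
        for ngn3 in (0.0, 0.5, 1.0, 2.0, 4.0):
            x = base.copy()
            x[GENE_INDEX["Ngn3"]] = ngn3
            p = pf.production_rate("Ptf1a", x, network, params)
            assert p <= prev + 1e-12
            prev = p

    def test_unknown_gene_rejected(self, network, params):
        with pytest.raises(KeyError):
            pf.production_rate("Foo", np.zeros(N_STATE), network, params)


class TestDrift:
    def test_pure_decay_matches_closed_form(self, network, params):
        # a gene with zero production decays as e^{-k t}
        x = np.zeros(N_STATE)
        x[GENE_INDEX["Ngn3"]] = 1.0
        x[-1] = 5.0  # matured tissue: Hnf6 (Ngn3's only driver) stays off
        d = pf.drift(x, network, params)
        assert d[GENE_INDEX["Ngn3"]] == pytest.approx(-1.0)
        tr = pf.simulate_cell(
            network, params.with_(D=0.0), initial=x, t_end=5.0)
        expect = np.exp(-tr.times)
        assert np.allclose(tr.gene("Ngn3"), expect, atol=5e-3)

    def test_only_hnf6_drives_from_zero_state(self, network, params):
        d = pf.drift(np.zeros(N_STATE), network, params)
        assert d[GENE_INDEX["Hnf6"]] > 0
        others = np.delete(d[:N_TF], GENE_INDEX["Hnf6"])
        assert np.allclose(others, 0.0)

    def test_attractor_residuals_below_tolerance(self, network, params, attractors):
        for state in attractors.values():
            d = pf.drift(state, network, params)
            assert np.max(np.abs(d[:N_TF])) < 1e-6


class TestMaturity:
    def test_zero_markers_zero_input(self, params):
        assert pf.maturity_input(np.zeros(N_STATE), params) == 0.0

    def test_saturating_bound(self, network, params):
        x = np.zeros(N_STATE)
        for g in pf.MARKER_GENES:
            x[GENE_INDEX[g]] = 50.0
        v = pf.maturity_input(x, params)
        assert v == pytest.approx(4 * params.lambda_mat, rel=1e-4)
        assert v <= 4 * params.lambda_mat

    def test_maturity_only_affects_hnf6(self, network, params):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 4, N_STATE)
        x2 = x.copy()
        x2[N_TF] += 1.5
        d1 = pf.drift(x, network, params)
        d2 = pf.drift(x2, network, params)
        changed = np.flatnonzero(~np.isclose(d1[:N_TF], d2[:N_TF]))
        assert set(changed) <= {GENE_INDEX["Hnf6"]}


class TestParameterDefaults:
    def test_printed_values(self, params):
        assert params.a["Pdx1"] == params.a["Hnf6"] == 2.2
        assert params.a["Pax4"] == params.a["Arx"] == 6.0
        assert params.a["MafA"] == 4.0
        assert params.k == 1.0
        assert (params.eta_single, params.eta_multi) == (0.25, 0.125)
        assert params.n == 4
        assert params.lambda_mat == 0.01

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            pf.ParameterSet(dt=0.0)
        with pytest.raises(ValueError):
            pf.ParameterSet(k=-1.0)
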