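import math

import numpy as np
import pytest

from appki.reaction_core import (
    ENZYME_TOTAL,
    IntegrationError,
    NetworkError,
    Reaction,
    ReactionNetwork,
    Species,
    build_network,
    instantaneous_rate,
    integrate,
)

UM = 1e-6
NM = 1e-9


def case_i_network(S0=10 * UM, I0=0.0, Ki=0.01 * NM, kon=1e8):
    return build_network(
        [
            Species("E", "enzyme_form", 1 * NM),
            Species("S", "substrate", S0),
            Species("ES", "complex"),
            Species("P", "product"),
            Species("I", "inhibitor", I0),
            Species("EI", "complex"),
        ],
        [
            Reaction(("E", "S"), ("ES",), 2e7),
            Reaction(("ES",), ("E", "S"), 50.0),
            Reaction(("ES",), ("E", "P"), 50.0),
            Reaction(("E", "I"), ("EI",), kon),
            Reaction(("EI",), ("E", "I"), Ki * kon),
        ],
    )


class TestBuildNetwork:
    def test_empty_reactions_zero_derivative(self):
        net = build_network(
            [Species("A", "substrate", 1 * UM), Species("B", "substrate", 2 * UM)], []
        )
        assert np.all(net.rhs(0.0, net.initial_state()) == 0)

    def test_case_i_conservation_group(self):
        net = case_i_network()
        assert set(net.enzyme_conservation_group()) == {"E", "ES", "EI"}

    def test_duplicate_name_rejected(self):
        with pytest.raises(NetworkError, match="duplicate"):
            build_network([Species("E"), Species("E")], [])

    def test_undeclared_species_rejected(self):
        with pytest.raises(NetworkError, match="undeclared"):
            build_network([Species("E")], [Reaction(("E", "X"), (), 1.0)])

    def test_molecularity_above_two_rejected(self):
        with pytest.raises(NetworkError, match="molecularity"):
            Reaction(("A", "B", "C"), (), 1.0)

    def test_negative_rate_const_rejected(self):
        with pytest.raises(NetworkError):
            Reaction(("A",), (), -1.0)

    def test_negative_conc0_rejected(self):
        with pytest.raises(NetworkError):
            Species("A", "substrate", -1.0)


class TestIntegrate:
    def test_no_reactions_constant(self):
        net = build_network(
            [Species("A", "substrate", 1 * UM), Species("B", "substrate", 2 * UM)], []
        )
        traj = integrate(net, 100.0, t_eval=[0.0, 50.0, 100.0])
        assert np.allclose(traj.concs, traj.concs[0], rtol=0, atol=0)

    def test_pseudo_first_order_decay(self):
        # E + S -> ES with S >> E: [E](t) = E0 * exp(-k1*S*t)
        k1, S0, E0 = 1e6, 100 * UM, 0.1 * NM
        net = build_network(
            [
                Species("E", "enzyme_form", E0),
                Species("S", "substrate", S0),
                Species("ES", "complex"),
            ],
            [Reaction(("E", "S"), ("ES",), k1)],
        )
        t_star = 3.0 / (k1 * S0)
        traj = integrate(net, 2 * t_star, t_eval=[t_star])
        expected = E0 * math.exp(-k1 * S0 * t_star)
        assert traj.state_at(t_star)[net.index("E")] == pytest.approx(expected, rel=0.01)

    def test_case_i_uninhibited_matches_mm(self):
        # in the initial-rate regime d[P]/dt at 60 s follows Michaelis-Menten
        # with Km = (k-1+k2)/k1 = 5 uM (enzyme load small enough that
        # substrate consumption is negligible)
        E0 = 1e-12
        net = case_i_network(S0=10 * UM).with_conc0(E=E0)
        traj = integrate(net, 60.0)
        v = instantaneous_rate(net, traj, "P", 60.0)
        km = (50.0 + 50.0) / 2e7
        expected = 50.0 * E0 * 10 * UM / (km + 10 * UM)
        assert v == pytest.approx(expected, rel=0.01)

    def test_enzyme_conservation(self):
        net = case_i_network(I0=0.1 * NM)
        traj = integrate(net, 60.0, t_eval=np.linspace(0, 60, 25))
        idx = [net.index(n) for n in net.enzyme_conservation_group()]
        totals = traj.concs[:, idx].sum(axis=1)
        assert np.max(np.abs(totals - totals[0])) / totals[0] < 1e-6

    def test_non_negativity(self):
        net = case_i_network(I0=0.1 * NM)
        traj = integrate(net, 60.0)
        assert traj.concs.min() >= -10 * 1e-15

    def test_deterministic_bit_identical(self):
        net = case_i_network(I0=0.1 * NM)
        t_eval = np.linspace(0, 60, 13)
        a = integrate(net, 60.0, t_eval=t_eval)
        b = integrate(net, 60.0, t_eval=t_eval)
        assert np.array_equal(a.concs, b.concs)
        assert np.array_equal(a.times, b.times)

    def test_t_end_validation(self):
        net = case_i_network()
        with pytest.raises(ValueError):
            integrate(net, -1.0)
        with pytest.raises(ValueError):
            integrate(net, 10.0, t_eval=[20.0])


class TestInstantaneousRate:
    def test_zero_for_no_reactions(self):
        net = build_network([Species("A", "substrate", 1 * UM)], [])
        traj = integrate(net, 10.0)
        assert instantaneous_rate(net, traj, "A", 5.0) == 0.0

    def test_product_rate_equals_rate_law(self):
        net = case_i_network(S0=10 * UM)
        traj = integrate(net, 60.0)
        es = traj.state_at(42.0)[net.index("ES")]
        assert instantaneous_rate(net, traj, "P", 42.0) == pytest.approx(50.0 * es, rel=1e-12)

    def test_conserved_total_rate_is_zero(self):
        net = case_i_network(S0=10 * UM, I0=0.1 * NM)
        traj = integrate(net, 60.0)
        rate = instantaneous_rate(net, traj, ENZYME_TOTAL, 30.0)
        scale = 50.0 * traj.state_at(30.0)[net.index("ES")]  # product flux
        assert abs(rate) <= 1e-9 * scale

    def test_unknown_species_and_range_errors(self):
        net = case_i_network()
        traj = integrate(net, 60.0)
        with pytest.raises(NetworkError):
            instantaneous_rate(net, traj, "Z", 10.0)
        with pytest.raises(ValueError):
            instantaneous_rate(net, traj, "P", 61.0)


class TestSerialization:
    def test_round_trip_dict_yaml_json(self):
        net = case_i_network(I0=0.5 * NM)
        assert ReactionNetwork.from_dict(net.to_dict()) == net
        assert ReactionNetwork.from_yaml(net.to_yaml()) == net
        assert ReactionNetwork.from_json(net.to_json()) == net

    def test_unit_tagged_input(self):
        doc = {
            "species": [
                {"name": "E", "role": "enzyme_form", "conc0": 1, "unit": "nM"},
                {"name": "S", "role": "substrate", "conc0": 10, "unit": "uM"},
            ],
            "reactions": [{"reactants": ["E", "S"], "products": [], "k": 1e5}],
        }
        net = ReactionNetwork.from_dict(doc)
        assert net.initial_state()[net.index("E")] == pytest.approx(1e-9)
        assert net.initial_state()[net.index("S")] == pytest.approx(1e-5)

    def test_trajectory_csv_export(self, tmp_path):
        net = case_i_network()
        traj = integrate(net, 10.0, t_eval=np.linspace(0, 10, 5))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header.split(",") == ["time_s", *net.names]
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        assert data.shape == (5, 1 + len(net.names))
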