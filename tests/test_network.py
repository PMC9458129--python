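"""Reaction-network core: stoichiometry, mass-action rates, conservation, IO."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from catrail.network import (
    NetworkValidationError,
    Reaction,
    ReactionNetwork,
    Species,
    build_jacobian_function,
    build_rate_function,
    compile_network,
    conserved_moieties,
    read_network,
    stoichiometry_matrix,
    validate_network,
    write_network,
)


def net(species, reactions):
    return ReactionNetwork(
        species=[Species(n, a) for n, a in species],
        reactions=[Reaction.parse(f"r{i}", lhs, rhs, k) for i, (lhs, rhs, k) in enumerate(reactions)],
    )


class TestStoichiometry:
    @pytest.mark.parametrize(
        "species, reaction, expected",
        [
            ([("A", 1), ("B", 0)], ("A", "B", 1.0), [-1, 1]),
            ([("A", 1), ("B", 1), ("C", 0)], ("A + B", "C", 1.0), [-1, -1, 1]),
            ([("A", 2), ("B", 0)], ("A + A", "B", 1.0), [-2, 1]),
        ],
        ids=["conversion", "bimolecular", "homodimerization"],
    )
    def test_single_reaction_columns(self, species, reaction, expected):
        S = stoichiometry_matrix(net(species, [reaction]))
        assert S[:, 0].tolist() == expected

    def test_unknown_species_raises_with_label(self):
        bad = ReactionNetwork(
            species=[Species("A")], reactions=[Reaction.parse("rx9", "A", "X", 1.0)]
        )
        with pytest.raises(NetworkValidationError, match="rx9"):
            stoichiometry_matrix(bad)


class TestRateFunction:
    def test_empty_network_zero_derivative(self):
        n = net([("A", 5)], [])
        assert build_rate_function(n)(0.0, np.array([5.0])).tolist() == [0.0]

    def test_first_order_decay_derivative(self):
        n = net([("A", 100)], [("A", "", 0.1)])
        assert build_rate_function(n)(0.0, np.array([100.0]))[0] == pytest.approx(-10.0)

    def test_bimolecular_mass_action(self):
        n = net([("A", 3), ("B", 4), ("C", 0)], [("A + B", "C", 2.0)])
        dy = build_rate_function(n)(0.0, np.array([3.0, 4.0, 0.0]))
        assert dy.tolist() == [-24.0, -24.0, 24.0]

    def test_zeroth_order_constant_rate(self):
        n = net([("A", 0)], [("", "A", 0.7)])
        assert build_rate_function(n)(0.0, np.array([123.0]))[0] == pytest.approx(0.7)

    def test_rhs_matches_loop_oracle_on_random_networks(self, rng):
        """f(y) == S·v(y) with v computed by an independent per-reaction loop."""
        for _ in range(20):
            ns = rng.integers(2, 6)
            nr = rng.integers(1, 8)
            names = [f"S{i}" for i in range(ns)]
            reactions = []
            for j in range(nr):
                order = rng.integers(0, 3)
                lhs = [names[rng.integers(ns)] for _ in range(order)]
                rhs = [names[rng.integers(ns)] for _ in range(rng.integers(0, 3))]
                if not lhs and not rhs:
                    rhs = [names[0]]
                reactions.append(
                    Reaction.parse(f"r{j}", " + ".join(lhs), " + ".join(rhs), float(rng.uniform(0, 2)))
                )
            network = ReactionNetwork([Species(n, 1.0) for n in names], reactions)
            f = build_rate_function(network)
            S = stoichiometry_matrix(network)
            for _ in range(100):
                y = rng.uniform(0, 10, ns)
                v = np.empty(len(reactions))
                for j, rxn in enumerate(network.reactions):
                    rate = rxn.rate_constant
                    for name in rxn.reactants:
                        rate *= y[names.index(name)]
                    v[j] = rate
                np.testing.assert_allclose(f(0.0, y), S @ v, rtol=1e-12, atol=1e-12)

    def test_jacobian_matches_finite_differences(self, rng):
        n = net(
            [("A", 3), ("B", 4), ("C", 1)],
            [("A + B", "C", 2.0), ("A + A", "B", 0.5), ("C", "A", 1.0), ("", "B", 0.3)],
        )
        f = build_rate_function(n)
        jac = build_jacobian_function(n)
        for _ in range(20):
            y = rng.uniform(0.1, 5.0, 3)
            J = jac(0.0, y)
            eps = 1e-7
            for l in range(3):
                dy = np.zeros(3)
                dy[l] = eps
                fd = (f(0.0, y + dy) - f(0.0, y - dy)) / (2 * eps)
                np.testing.assert_allclose(J[:, l], fd, rtol=1e-5, atol=1e-6)


class TestValidation:
    def test_well_formed_network_empty_report(self):
        assert validate_network(net([("A", 1), ("B", 0)], [("A", "B", 1.0)])) == []

    def test_dangling_reference_reported(self):
        bad = ReactionNetwork([Species("A")], [Reaction.parse("r", "A", "X", 1.0)])
        report = validate_network(bad)
        assert [i.kind for i in report] == ["dangling-reference"]

    def test_negative_rate_reported(self):
        bad = net([("A", 1), ("B", 0)], [("A", "B", -1.0)])
        assert [i.kind for i in validate_network(bad)] == ["negative-rate"]

    def test_duplicate_species_and_negative_initial(self):
        bad = ReactionNetwork([Species("A", 1.0), Species("A", -2.0)], [])
        kinds = sorted(i.kind for i in validate_network(bad))
        assert kinds == ["duplicate-species", "negative-initial"]


class TestConservedMoieties:
    def test_reversible_pair_conserved(self):
        n = net([("A", 80), ("B", 20)], [("A", "B", 0.2), ("B", "A", 0.1)])
        vectors = conserved_moieties(n)
        assert any(v.tolist() == [1, 1] for v in vectors)

    def test_pure_decay_has_no_conservation(self):
        assert conserved_moieties(net([("A", 100)], [("A", "", 0.1)])) == []

    def test_vectors_annihilate_stoichiometry(self, network):
        S = stoichiometry_matrix(network)
        vectors = conserved_moieties(network)
        assert vectors, "packaged network should have conserved pools"
        for v in vectors:
            assert (v >= 0).all() and v.any()
            assert (v @ S == 0).all()

    def test_parp_pool_is_conserved_in_packaged_model(self, network):
        names = network.species_names
        target = np.zeros(len(names), dtype=np.int64)
        for s in ("PARP", "C3_PARP", "cPARP"):
            target[names.index(s)] = 1
        assert any(np.array_equal(v, target) for v in conserved_moieties(network))


class TestSerialization:
    def test_round_trip_is_lossless(self, tmp_path, network):
        sp, rx = tmp_path / "s.tsv", tmp_path / "r.tsv"
        write_network(network, sp, rx)
        again = read_network(sp, rx)
        assert again == network

    @settings(max_examples=25, deadline=None)
    @given(
        amounts=st.lists(st.floats(0, 1e7, allow_nan=False), min_size=1, max_size=5),
        k=st.floats(0, 1e3, allow_nan=False),
    )
    def test_round_trip_arbitrary_amounts(self, tmp_path_factory, amounts, k):
        tmp = tmp_path_factory.mktemp("roundtrip")
        names = [f"X{i}" for i in range(len(amounts))]
        n = ReactionNetwork(
            [Species(nm, a) for nm, a in zip(names, amounts)],
            [Reaction.parse("r0", names[0], "", k)],
        )
        write_network(n, tmp / "s.csv", tmp / "r.csv")
        assert read_network(tmp / "s.csv", tmp / "r.csv") == n
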