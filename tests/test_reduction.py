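"""Schur deletion of complexes: structure, dynamics, symbolic collapse."""

import numpy as np
import pytest

from crnreduce import (
    ReductionError,
    classify_deletion,
    delete_complexes,
    eliminated_species,
    full_rhs,
    find_steady_state,
    reduced_rhs,
    schur_complement,
    symbolic_chain_collapse,
    weighted_laplacian,
)
from crnreduce import fixtures as fx

FROZEN = {"X3": 0.1, "X4": 0.1}


class TestSchurComplement:
    def test_mass_action_chain_closed_form(self):
        k1f, k1r, k2f, k2r = 1.3, 0.7, 2.1, 0.4
        L = np.array([[k1f, -k1r, 0.0],
                      [-k1f, k1r + k2f, -k2r],
                      [0.0, -k2f, k2r]])
        s = k1r + k2f
        expected = np.array([[k1f * k2f / s, -k1r * k2r / s],
                             [-k1f * k2f / s, k1r * k2r / s]])
        assert np.allclose(schur_complement(L, [1]), expected)

    def test_unit_path_graph_series_conductance(self):
        # two unit resistors in series have conductance 1/2
        L = np.array([[1.0, -1.0, 0.0], [-1.0, 2.0, -1.0], [0.0, -1.0, 1.0]])
        assert np.allclose(schur_complement(L, [1]),
                           [[0.5, -0.5], [-0.5, 0.5]])

    def test_empty_deletion_is_identity(self):
        L = np.array([[1.0, -2.0], [-1.0, 2.0]])
        assert np.array_equal(schur_complement(L, []), L)

    def test_singular_block_rejected(self):
        # complex 1 with no outflow: L22 = 0
        L = np.array([[1.0, 0.0], [-1.0, 0.0]])
        with pytest.raises(ReductionError, match="singular|ill-conditioned"):
            schur_complement(L, [1])

    def test_laplacian_properties_on_random_networks(self, rng):
        # positive diagonal, nonpositive off-diagonal, zero column sums
        trials = 0
        for seed in range(50):
            net = fx.random_enzymatic_network(6, 5, seed=seed)
            for _ in range(4):
                x = 10.0 ** rng.uniform(-1, 1, net.m)
                L = weighted_laplacian(net, x).L
                k = int(rng.integers(0, net.c))
                Lh = schur_complement(L, [k])
                off = Lh - np.diag(np.diag(Lh))
                assert np.all(np.diag(Lh) > 0)
                assert np.max(off) <= 1e-12
                assert np.max(np.abs(Lh.sum(axis=0))) < 1e-10
                trials += 1
        assert trials == 200

    def test_order_independence_of_deletion(self, rng):
        # batch Schur deletion equals sequential deletion (quotient property)
        for seed in range(20):
            net = fx.random_enzymatic_network(6, 5, seed=seed)
            x = 10.0 ** rng.uniform(-1, 1, net.m)
            L = weighted_laplacian(net, x).L
            a, b = rng.choice(net.c, size=2, replace=False)
            batch = schur_complement(L, [a, b])
            first = schur_complement(L, [a])
            remaining = [i for i in range(net.c) if i != a]
            seq = schur_complement(first, [remaining.index(b)])
            assert np.max(np.abs(batch - seq)) < 1e-10 * max(1.0, np.max(np.abs(batch)))


class TestDeleteComplexes:
    def test_chain_interior_deletion_collapses_to_one_reaction(self, example1):
        red = delete_complexes(example1, [1], FROZEN)
        assert red.retained == [0, 2]
        assert sorted(red.eliminated) == ["X3", "X4"]
        assert red.n_state_variables == 4
        assert red.reaction_counts() == (1, 0)

    def test_type1_chain_topology(self):
        net = fx.chain_network(5)
        red = delete_complexes(net, [1], {"S2": 1.0})
        edges = red.structural_edges()
        assert (0, 2) in edges and (2, 0) in edges
        # downstream chain untouched
        assert (2, 3) in edges and (3, 2) in edges and (3, 4) in edges
        assert red.reaction_counts() == (3, 0)

    def test_type3_hub_deletion_couples_all_leaves(self):
        net = fx.type3_star()
        red = delete_complexes(net, [1], {"B": 1.0})
        rev, irr = red.reaction_counts()
        assert rev == 3 and irr == 0  # complete coupling of C1, C3, C4

    def test_cannot_delete_everything(self, example1):
        with pytest.raises(ReductionError):
            delete_complexes(example1, [0, 1, 2], FROZEN)

    def test_protected_complex_refused(self, example1):
        with pytest.raises(ReductionError, match="protected"):
            delete_complexes(example1, [1], FROZEN, protected=[1])

    def test_missing_freeze_value_rejected(self, example1):
        with pytest.raises(ReductionError, match="freeze"):
            delete_complexes(example1, [1], {"X3": 0.1})


class TestEliminatedSpecies:
    def test_chain_interior(self, example1):
        assert eliminated_species(example1, [1]) == {"X3", "X4"}

    def test_unimolecular_chain(self):
        net = fx.chain_network(4)
        assert eliminated_species(net, [1]) == {"S2"}

    def test_shared_species_not_eliminated(self):
        net = fx.disconnecting_triple()
        # deleting X3+X4 keeps X4 (it also sits in X4+X5)
        idx = [i for i, c in enumerate(net.complexes) if c.label() == "X3+X4"][0]
        assert eliminated_species(net, [idx]) == {"X3"}


class TestReducedDynamics:
    def test_moiety_conservation_in_reduced_model(self, example1):
        red = delete_complexes(example1, [1], FROZEN)
        x = np.array([2.0, 1.5, 0.5, 0.7])  # X1, X2, X5, X6
        dx = reduced_rhs(red, x)
        # d(x1 + x5)/dt = 0 and d(x2 + x6)/dt = 0
        assert abs(dx[0] + dx[2]) < 1e-12
        assert abs(dx[1] + dx[3]) < 1e-12

    def test_complex_balancing_is_imposed(self, example1):
        # implied w2 makes the deleted rows of the auxiliary system vanish
        red = delete_complexes(example1, [1], FROZEN)
        x = np.array([2.0, 1.5, 0.5, 0.7])
        xf = red.augment(x)
        L = weighted_laplacian(example1, xf).L
        w = example1.complex_monomials(xf)
        w1 = w[red.retained]
        # vb = 0 here; balancing fixes w2 = L22^-1 (vb2 - L21 w1)
        w2 = np.linalg.solve(L[np.ix_(red.deleted, red.deleted)],
                             -L[np.ix_(red.deleted, red.retained)] @ w1)
        y2dot = -(L[np.ix_(red.deleted, red.retained)] @ w1
                  + L[np.ix_(red.deleted, red.deleted)] @ w2)
        assert np.max(np.abs(y2dot)) < 1e-12

    def test_reduced_rhs_vanishes_at_full_steady_state(self):
        net = fx.example1_driven()
        x_ss = find_steady_state(net)
        freeze = {s.id: x_ss[i] for i, s in enumerate(net.species)}
        red = delete_complexes(net, [1], freeze)
        dx = reduced_rhs(red, x_ss[red.retained_species])
        assert np.max(np.abs(dx)) < 1e-10


class TestClassifyDeletion:
    @pytest.mark.parametrize("maker,idx,expected", [
        (lambda: fx.chain_network(4), 1, "type1"),
        (fx.type2_chain, 1, "type2"),
        (fx.type3_star, 1, "type3"),
        (fx.two_state, 1, "linkage_removal"),
    ])
    def test_archetypes(self, maker, idx, expected):
        assert classify_deletion(maker(), idx) == expected

    def test_species_bridge_deletion_is_disconnecting(self):
        net = fx.disconnecting_triple()
        idx = [i for i, c in enumerate(net.complexes) if c.label() == "X4+X5"][0]
        assert classify_deletion(net, idx) == "disconnecting"

    def test_chain_interior_is_not_disconnecting(self, example1):
        assert classify_deletion(example1, 1) == "type1"


class TestSymbolicChainCollapse:
    def test_equilibrium_constant_composes(self, example1):
        col = symbolic_chain_collapse(example1, 1, FROZEN)
        assert col.keq == pytest.approx((1.0 / 0.5) * (50.0 / 25.0), rel=1e-12)

    def test_parameter_count_eight_vs_twelve(self, example1):
        col = symbolic_chain_collapse(example1, 1, FROZEN)
        assert col.n_parameters == 8
        assert example1.n_parameters() == 12

    def test_substitution_oracle_fifty_random_parameter_sets(self):
        # direct implementation of the balancing substitution:
        # v = (kfI kfII x1 x2 - krI krII x5 x6)/(kfII p1 + krI p2), p1 and p2
        # with intermediates frozen
        rng = np.random.default_rng(7)
        for _ in range(50):
            kfI, krI, kfII, krII = 10.0 ** rng.uniform(-1, 1, 4)
            KmI = tuple(10.0 ** rng.uniform(-1, 1, 4))
            KmII = tuple(10.0 ** rng.uniform(-1, 1, 4))
            x3f, x4f = 10.0 ** rng.uniform(-1, 1, 2)
            net = fx.example1_network(kfI, krI, kfII, krII, KmI, KmII)
            col = symbolic_chain_collapse(net, 1, {"X3": x3f, "X4": x4f})
            x = 10.0 ** rng.uniform(-1, 1, 6)
            p1 = (1 + x[0] / KmI[0] + x3f / KmI[2]) * (1 + x[1] / KmI[1] + x4f / KmI[3])
            p2 = (1 + x3f / KmII[0] + x[4] / KmII[2]) * (1 + x4f / KmII[1] + x[5] / KmII[3])
            v_oracle = (kfI * kfII * x[0] * x[1] - krI * krII * x[4] * x[5]) / (
                kfII * p1 + krI * p2)
            v_col = col.rate(x, net.species_index)
            assert v_col == pytest.approx(v_oracle, rel=1e-10, abs=1e-12)

    def test_collapsed_net_flux_matches_chain_at_steady_state(self):
        # at the full model's steady state the collapsed reaction carries the
        # chain's common net flux
        net = fx.example1_driven()
        x_ss = find_steady_state(net)
        v = net.reaction_rates(x_ss)
        net_flux_step1 = v[0] - v[1]
        col = symbolic_chain_collapse(net, 1, {"X3": x_ss[2], "X4": x_ss[3]})
        assert col.rate(x_ss, net.species_index) == pytest.approx(net_flux_step1, rel=1e-9)

    def test_non_mm_input_rejected(self):
        net = fx.chain_network(3)  # reversible mass action: empty-site denominators
        col = symbolic_chain_collapse(net, 1, {"S2": 1.0})
        # empty-site product denominators are legal (mass action limit) ...
        assert col.n_parameters == 2
        # ... but an irreversible interior is not collapsible
        with pytest.raises(ReductionError):
            symbolic_chain_collapse(fx.type2_chain(), 1, {"B": 1.0})
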