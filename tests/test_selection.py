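"""Steady states, error integrals, ranking and the greedy procedure."""

import numpy as np
import pytest

from crnreduce import (
    Scenario,
    convergence_times,
    error_integral,
    find_steady_state,
    full_rhs,
    greedy_reduce,
    rank_candidates,
    simulation_count,
)
from crnreduce import fixtures as fx
from crnreduce.fixtures import _rev_mass_action
from crnreduce.network import Species, build_complexes
from crnreduce.simulate import Trajectory


def make_traj(times, cols: dict[str, np.ndarray]) -> Trajectory:
    ids = list(cols)
    states = np.column_stack([cols[s] for s in ids])
    return Trajectory(np.asarray(times, float), states, ids)


class TestFindSteadyState:
    def test_two_state_detailed_balance(self, two_state):
        # kf a = kr b with a + b = 3 gives (1, 2)
        x_ss = find_steady_state(two_state)
        assert x_ss == pytest.approx([1.0, 2.0], rel=1e-8)

    def test_postcondition_on_driven_network(self):
        net = fx.example1_driven()
        x_ss = find_steady_state(net)
        assert np.max(np.abs(full_rhs(net, x_ss))) <= 1e-9 * max(1.0, np.max(np.abs(x_ss)))

    def test_conserved_moiety_respected(self, example1):
        x_ss = find_steady_state(example1)
        x0 = example1.x0
        # x1 + x3 + x5 and x2 + x4 + x6 are conserved from the initial state
        assert x_ss[0] + x_ss[2] + x_ss[4] == pytest.approx(x0[0] + x0[2] + x0[4], rel=1e-7)
        assert x_ss[1] + x_ss[3] + x_ss[5] == pytest.approx(x0[1] + x0[3] + x0[5], rel=1e-7)


class TestErrorIntegral:
    def test_identical_trajectories_give_zero(self):
        t = np.linspace(0, 2, 50)
        xf = 1.0 + t
        rep = error_integral(make_traj(t, {"A": xf}), make_traj(t, {"A": xf.copy()}),
                             ["A"], T=2.0)
        assert rep.I == 0.0

    def test_constant_ratio_single_species(self):
        t = np.linspace(0, 3, 40)
        xf = 2.0 + np.sin(t)
        rep = error_integral(make_traj(t, {"A": xf}), make_traj(t, {"A": 0.9 * xf}),
                             ["A"], T=3.0)
        assert rep.I == pytest.approx(0.1, rel=1e-12)

    def test_two_species_average(self):
        t = np.linspace(0, 1, 30)
        xf = np.full_like(t, 2.0)
        full = make_traj(t, {"A": xf, "B": xf})
        red = make_traj(t, {"A": 0.9 * xf, "B": 1.2 * xf})
        rep = error_integral(full, red, ["A", "B"], T=1.0)
        assert rep.I == pytest.approx(0.15, rel=1e-12)
        assert rep.per_species["A"] == pytest.approx(0.1)
        assert rep.I == pytest.approx(np.mean(list(rep.per_species.values())))

    def test_unit_rescaling_invariance(self):
        # I depends on ratios only
        t = np.linspace(0, 1, 30)
        xf = 2.0 + t
        xr = 1.8 + 0.5 * t
        I1 = error_integral(make_traj(t, {"A": xf}), make_traj(t, {"A": xr}), ["A"], 1.0).I
        I2 = error_integral(make_traj(t, {"A": 1e3 * xf}), make_traj(t, {"A": 1e3 * xr}),
                            ["A"], 1.0).I
        assert I1 == pytest.approx(I2, rel=1e-12)

    def test_vanishing_full_concentration_rejected(self):
        t = np.linspace(0, 1, 10)
        with pytest.raises(ValueError, match="reaches 0"):
            error_integral(make_traj(t, {"A": t}), make_traj(t, {"A": t + 1}), ["A"], 1.0)


SCN = dict(perturbation={"G": 1.0}, T=5.0, significant=["X1", "X2", "X5", "X6"])


class TestRankCandidates:
    def test_single_unprotected_candidate(self):
        net = fx.example1_driven()
        x_ss = find_steady_state(net)
        ranking = rank_candidates(net, Scenario(**SCN), x_ss)
        assert [alpha for alpha, _ in ranking] == [1]
        assert ranking[0][1] >= 0.0

    def test_significant_complexes_never_ranked(self):
        net = fx.example1_driven()
        x_ss = find_steady_state(net)
        scn = Scenario(perturbation={"G": 1.0}, T=5.0, significant=["X3"])
        ranking = rank_candidates(net, scn, x_ss)
        assert all(alpha != 1 for alpha, _ in ranking)

    def test_disconnecting_candidates_skipped_by_default(self):
        # the bridge complex of the species-chained triple never appears
        net = fx.disconnecting_triple()
        x_ss = find_steady_state(net)
        i45 = [i for i, c in enumerate(net.complexes) if c.label() == "X4+X5"][0]
        scn = Scenario(perturbation={}, T=2.0, significant=["X1"])
        ranking = rank_candidates(net, scn, x_ss)
        assert all(alpha != i45 for alpha, _ in ranking)
        ranking2 = rank_candidates(net, scn, x_ss, allow_disconnecting=True)
        assert any(alpha == i45 for alpha, _ in ranking2)


class TestGreedyReduce:
    def test_balanced_intermediate_deleted_in_one_step(self):
        net = fx.example1_driven()
        red, trace = greedy_reduce(net, Scenario(**SCN, cutoff=0.1))
        assert [s["complex"] for s in trace.steps] == [1]
        assert trace.stopped_because == "no_candidates"
        assert trace.steps[0]["I"] <= 0.1
        assert red.n_state_variables == 4

    def test_zero_cutoff_returns_original_network(self):
        net = fx.example1_driven()
        model, trace = greedy_reduce(net, Scenario(**SCN, cutoff=0.0))
        assert model is net
        assert trace.steps == [] and trace.stopped_because == "cutoff"

    def test_accepted_steps_all_within_cutoff(self):
        net = fx.example1_driven()
        red, trace = greedy_reduce(net, Scenario(**SCN, cutoff=0.5))
        assert all(s["I"] <= 0.5 for s in trace.steps)


class TestSimulationCount:
    def test_closed_form_examples(self):
        assert simulation_count(43, 14, 31) == 299
        assert simulation_count(5, 0, 5) == 5
        assert simulation_count(3, 1, 2) == (2 - 1) + (3 - 1)

    def test_matches_greedy_candidate_count_on_unimolecular_chain(self):
        # exhaustive greedy run on a chain of unimolecular complexes: the
        # number of candidate simulations equals sum_{i=L}^{N} (i - M)
        net = fx.chain_network(5, params={"kf": [1.0, 2.0, 1.5, 0.8],
                                          "kr": [0.5, 1.0, 0.7, 0.4]})
        scn = Scenario(perturbation={}, T=2.0, significant=["S1", "S5"], cutoff=np.inf)
        x_ss = find_steady_state(net)
        total = 0
        deleted: set[int] = set()
        while True:
            ranking = rank_candidates(net, scn, x_ss, deleted)
            total += len(ranking)
            if not ranking:
                break
            deleted.add(ranking[0][0])
        N, M = 5, 2
        L = N - 3  # three interior complexes deletable
        assert total == simulation_count(N, M, L)


class TestConvergenceTimes:
    def test_single_exponential_closed_form(self):
        # clamped F feeding B: dB/dt = kf F - kr B relaxes at rate kr,
        # so the 95% time is ln(20)/kr
        kf, kr = 1.0, 0.8
        f, r = _rev_mass_action(kf, kr)
        net = build_complexes(
            [({"F": 1}, {"B": 1}, f), ({"B": 1}, {"F": 1}, r)],
            species=[Species("F", x0=0.5, fixed=True), Species("B", x0=kf * 0.5 / kr)],
        )
        scn = Scenario(perturbation={"F": 1.0}, T=10.0, significant=["B"])
        times = convergence_times(net, scn, ["B"])
        t_star, flagged = times["B"]
        assert not flagged
        assert t_star == pytest.approx(np.log(20.0) / kr, rel=0.02)

    def test_unchanged_species_flagged_zero(self):
        kf, kr = 1.0, 0.8
        f, r = _rev_mass_action(kf, kr)
        net = build_complexes(
            [({"F": 1}, {"B": 1}, f), ({"B": 1}, {"F": 1}, r)],
            species=[Species("F", x0=0.5, fixed=True), Species("B", x0=kf * 0.5 / kr)],
        )
        scn = Scenario(perturbation={"F": 0.5}, T=5.0, significant=["B"])  # no-op step
        t_star, flagged = convergence_times(net, scn, ["B"])["B"]
        assert flagged and t_star == 0.0

    def test_matches_dense_grid_scan(self, two_state):
        # monotone relaxation of the closed pair: brute-force scan oracle
        net = fx.example1_driven()
        scn = Scenario(perturbation={"G": 1.0}, T=5.0, significant=["X1"])
        times = convergence_times(net, scn, ["X1"], grid_points=4001)
        x_old = find_steady_state(net)
        from crnreduce.selection import _perturbed_state
        from crnreduce.simulate import simulate

        x_init = _perturbed_state(net, x_old, {"G": 1.0})
        x_new = find_steady_state(net, x_init)
        T = 2.0 * times["X1"][0]
        traj = simulate(net, x_init, T=T, t_eval=np.linspace(0, T, 16001))
        k = net.species_index["X1"]
        dev = np.abs(traj.states[:, k] - x_new[k]) / abs(x_new[k] - x_old[k])
        bad = np.nonzero(dev > 0.05)[0]
        oracle = traj.times[bad[-1] + 1]
        assert times["X1"][0] == pytest.approx(oracle, rel=0.02)
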