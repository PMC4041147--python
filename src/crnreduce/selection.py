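"""Automated choice of complexes to delete.

The procedure quantifies a candidate reduction by the error integral

    I = sum_{i in M_I} 1/(T n(M_I)) int_0^T |1 - x_i^r(t)/x_i^f(t)| dt,

the time- and species-averaged relative deviation of the reduced-model
trajectories x^r from the full-model ones x^f over the user-chosen
significant species M_I, under a given perturbation scenario.  Reduction
proceeds greedily: at each step every deletable complex is tried (one at
a time, on top of the deletions already accepted, with eliminated
species frozen at the original network's pre-event steady state), the
complex with the smallest I is deleted, and the iteration stops once the
best candidate's I exceeds the cutoff (default 0.1).

Complexes containing significant species are never deleted, and
deletions classified as disconnecting (they would split the network into
parts sharing no species) are refused by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .laplacian import full_rhs
from .network import ReactionNetwork
from .reduction import ReducedNetwork, ReductionError, classify_deletion, delete_complexes
from .simulate import SolverError, Trajectory, simulate

__all__ = [
    "Scenario",
    "ErrorReport",
    "ReductionTrace",
    "SteadyStateError",
    "find_steady_state",
    "error_integral",
    "rank_candidates",
    "greedy_reduce",
    "convergence_times",
    "simulation_count",
]

log = logging.getLogger(__name__)


@dataclass
class Scenario:
    """A perturbation experiment: step changes of clamped species at t=0,
    an observation horizon T (min), the significant species M_I, and the
    error-integral cutoff for the greedy iteration."""

    perturbation: dict[str, float]
    T: float
    significant: list[str]
    cutoff: float = 0.1

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("horizon T must be positive")
        if not self.significant:
            raise ValueError("significant species set must be nonempty")
        if self.cutoff < 0:
            raise ValueError("cutoff must be nonnegative")


@dataclass
class ErrorReport:
    I: float
    per_species: dict[str, float]
    T_used: float


@dataclass
class ReductionTrace:
    """Ordered record of the greedy deletions: for each accepted step the
    deleted complex, its (minimum) error integral, and the full candidate
    ranking at that step."""

    steps: list[dict] = field(default_factory=list)
    stopped_because: str = ""

    def min_errors(self) -> list[float]:
        return [s["I"] for s in self.steps]

    def to_records(self) -> list[dict]:
        return [
            {"step": k + 1, "complex": s["complex"], "label": s["label"], "I": s["I"]}
            for k, s in enumerate(self.steps)
        ]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.to_records())


class SteadyStateError(RuntimeError):
    pass


def _model_rhs(model):
    if isinstance(model, ReducedNetwork):
        return model.rhs
    return lambda x: full_rhs(model, x)


def _conservation_matrix(model) -> np.ndarray:
    """Columns g of structural conservation laws: g . dx/dt == 0 identically.

    The dynamics image lies in the column space of Z B (reactions) plus the
    boundary-flux columns of Z (full model), or of Z1 (reduced model), with
    clamped species rows zeroed; the left null space of that matrix gives
    the conserved moieties."""
    from scipy.linalg import null_space

    if isinstance(model, ReducedNetwork):
        M = model.Z1[model.retained_species, :].astype(float).copy()
    else:
        cols = [model.Z @ model.B]
        if model.boundary_fluxes:
            cols.append(model.Z[:, sorted(model.boundary_fluxes)])
        M = np.hstack(cols).astype(float)
    M[model.fixed_mask] = 0.0
    return null_space(M.T)


def find_steady_state(
    model: ReactionNetwork | ReducedNetwork,
    x0: np.ndarray | None = None,
    t_max: float = 1e5,
    tol: float = 1e-9,
) -> np.ndarray:
    """Steady state by long integration followed by root refinement.

    Integrates in doubling chunks until the right-hand side is small, then
    polishes with a bounded least-squares solve over the non-clamped
    species, constrained to the conservation manifold of the initial state
    (g . x = g . x0 for every structural moiety g).  Postcondition:
    ||rhs||_inf <= tol * max(1, ||x_ss||_inf).
    """
    rhs = _model_rhs(model)
    x = (model.x0 if x0 is None else np.asarray(x0, dtype=float)).copy()
    x_anchor = x.copy()
    fixed = model.fixed_mask
    free = ~fixed

    T = 10.0
    total = 0.0
    while total < t_max:
        traj = simulate(model, x, T=T)
        x = traj.final.copy()
        total += T
        T *= 2.0
        if np.max(np.abs(rhs(x))) < 1e3 * tol * max(1.0, float(np.max(np.abs(x)))):
            break
    else:
        raise SteadyStateError(
            f"no convergence to steady state within t={t_max} min; "
            f"||rhs||_inf={np.max(np.abs(rhs(x))):.3g}, tail state {x}"
        )

    C = _conservation_matrix(model)

    def resid(xfree: np.ndarray) -> np.ndarray:
        xf = x.copy()
        xf[free] = xfree
        r = rhs(xf)[free]
        if C.size:
            r = np.concatenate([r, C.T @ (xf - x_anchor)])
        return r

    if np.any(free):
        fit = least_squares(resid, x[free], bounds=(0.0, np.inf), xtol=3e-16, ftol=3e-16,
                            gtol=1e-15, max_nfev=2000)
        x[free] = fit.x
    dev = float(np.max(np.abs(rhs(x))))
    if dev > tol * max(1.0, float(np.max(np.abs(x)))):
        raise SteadyStateError(f"steady-state refinement stalled at ||rhs||_inf={dev:.3g}")
    return x


def error_integral(
    full_traj: Trajectory,
    reduced_traj: Trajectory,
    significant: Sequence[str],
    T: float,
) -> ErrorReport:
    """Trapezoid evaluation of the error integral on the union of the two
    solver grids, restricted to [0, T]."""
    ts = np.union1d(full_traj.times, reduced_traj.times)
    ts = ts[(ts >= 0) & (ts <= T)]
    if ts[-1] < T:
        raise ValueError(f"trajectories do not cover the horizon T={T}")
    per: dict[str, float] = {}
    for sid in significant:
        xf = np.interp(ts, full_traj.times, full_traj.col(sid))
        xr = np.interp(ts, reduced_traj.times, reduced_traj.col(sid))
        if np.any(xf <= 0):
            raise ValueError(f"full-model concentration of {sid} reaches 0; "
                             "relative error undefined")
        per[sid] = float(np.trapezoid(np.abs(1.0 - xr / xf), ts)) / T
    n = len(per)
    return ErrorReport(I=sum(per.values()) / n, per_species=per, T_used=float(T))


def _perturbed_state(model, x_ss: np.ndarray, perturbation: Mapping[str, float]) -> np.ndarray:
    x = np.asarray(x_ss, dtype=float).copy()
    for sid, value in perturbation.items():
        k = model.species_index[sid]
        if not model.species[k].fixed:
            raise ValueError(f"perturbation targets non-clamped species {sid!r}")
        x[k] = float(value)
    return x


def protected_complexes(net: ReactionNetwork, significant: Iterable[str]) -> set[int]:
    """Complexes containing a significant species (never deleted)."""
    sig = set(significant)
    return {alpha for alpha, cx in enumerate(net.complexes) if cx.species_ids() & sig}


def rank_candidates(
    net: ReactionNetwork,
    scenario: Scenario,
    x_ss: np.ndarray,
    deleted: Iterable[int] = (),
    full_traj: Trajectory | None = None,
    allow_disconnecting: bool = False,
) -> list[tuple[int, float]]:
    """Score every deletable complex by the error integral of deleting it
    on top of `deleted`, ascending; ties broken by complex index.

    Frozen values for eliminated species come from x_ss (the original
    network's pre-event steady state).  Candidates whose reduced model
    fails to simulate are skipped with a warning.
    """
    deleted = set(deleted)
    freeze = {s.id: float(x_ss[i]) for i, s in enumerate(net.species)}
    prot = protected_complexes(net, scenario.significant)

    if full_traj is None:
        full_traj = simulate(net, _perturbed_state(net, x_ss, scenario.perturbation),
                             T=scenario.T)

    scores: list[tuple[int, float]] = []
    any_candidate = False
    for alpha in range(net.c):
        if alpha in deleted or alpha in prot:
            continue
        if not allow_disconnecting and classify_deletion(net, alpha) == "disconnecting":
            log.info("skipping disconnecting deletion of complex %d", alpha)
            continue
        any_candidate = True
        try:
            red = delete_complexes(net, deleted | {alpha}, freeze)
            x0r = _perturbed_state(
                red, x_ss[red.retained_species], scenario.perturbation
            )
            red_traj = simulate(red, x0r, T=scenario.T)
            rep = error_integral(full_traj, red_traj, scenario.significant, scenario.T)
            scores.append((alpha, rep.I))
        except (ReductionError, SolverError, ValueError) as e:
            log.warning("candidate complex %d failed: %s", alpha, e)
    if any_candidate and not scores:
        raise SolverError("every candidate deletion failed to simulate")
    scores.sort(key=lambda t: (t[1], t[0]))
    return scores


def greedy_reduce(
    net: ReactionNetwork,
    scenario: Scenario,
    x_ss: np.ndarray | None = None,
    allow_disconnecting: bool = False,
) -> tuple[ReactionNetwork | ReducedNetwork, ReductionTrace]:
    """Iteratively delete the minimum-error-integral complex until the best
    candidate exceeds the cutoff or no candidates remain.  Returns the last
    accepted model (the original network if no deletion was accepted) and
    the trace of the accepted steps."""
    if x_ss is None:
        x_ss = find_steady_state(net)
    freeze = {s.id: float(x_ss[i]) for i, s in enumerate(net.species)}
    full_traj = simulate(net, _perturbed_state(net, x_ss, scenario.perturbation),
                         T=scenario.T)

    trace = ReductionTrace()
    deleted: set[int] = set()
    while True:
        if len(deleted) >= net.c - 1:
            trace.stopped_because = "exhausted"
            break
        ranking = rank_candidates(net, scenario, x_ss, deleted, full_traj,
                                  allow_disconnecting)
        if not ranking:
            trace.stopped_because = "no_candidates"
            break
        best, best_I = ranking[0]
        if best_I > scenario.cutoff:
            trace.stopped_because = "cutoff"
            break
        deleted.add(best)
        trace.steps.append({
            "complex": best,
            "label": net.complexes[best].label(),
            "I": best_I,
            "ranking": ranking,
        })
        log.info("deleted complex %d (%s), I=%.4g", best,
                 net.complexes[best].label(), best_I)

    if not deleted:
        return net, trace
    return delete_complexes(net, deleted, freeze), trace


def convergence_times(
    net: ReactionNetwork,
    scenario: Scenario,
    species: Sequence[str],
    grid_points: int = 2001,
    t_max: float = 1e5,
) -> dict[str, tuple[float, bool]]:
    """Time for each species to achieve 95% of its concentration change
    between the pre- and post-perturbation steady states.

    Returns {species: (t_star, flagged)}; flagged=True marks species with
    no concentration change (reported as 0).
    """
    x_old = find_steady_state(net)
    x_init = _perturbed_state(net, x_old, scenario.perturbation)
    x_new = find_steady_state(net, x_init)

    # horizon: extend until the whole state is inside the 5% band
    T = scenario.T
    while True:
        traj = simulate(net, x_init, T=T, t_eval=np.linspace(0.0, T, grid_points))
        if np.all(np.abs(traj.final - x_new) <= 0.05 * np.maximum(np.abs(x_new - x_old), 1e-12)):
            break
        T *= 4.0
        if T > t_max:
            raise SteadyStateError("trajectory does not settle within the time budget")

    out: dict[str, tuple[float, bool]] = {}
    for sid in species:
        k = net.species_index[sid]
        delta = abs(x_new[k] - x_old[k])
        if delta < 1e-9 * max(1.0, abs(x_new[k])):
            out[sid] = (0.0, True)
            continue
        dev = np.abs(traj.states[:, k] - x_new[k]) / delta
        bad = np.nonzero(dev > 0.05)[0]
        t_star = 0.0 if len(bad) == 0 else float(traj.times[min(bad[-1] + 1, len(traj.times) - 1)])
        out[sid] = (t_star, False)
    return out


def simulation_count(N: int, M: int, L: int) -> int:
    """Total candidate simulations of the greedy procedure for a network of
    N species with M protected species, reduced down to L species:
    sum_{i=L}^{N} (i - M)."""
    if not (0 <= L <= N):
        raise ValueError("need 0 <= L <= N")
    return sum(i - M for i in range(L, N + 1))
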