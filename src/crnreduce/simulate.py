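"""ODE integration of full and reduced network models.

Stiff-capable adaptive integration (LSODA by default: glycolysis-class
models mix fast equilibria with slow fluxes).  Default tolerances
rtol=1e-8 / atol=1e-10 keep quadrature error in downstream error
integrals well below the reduction cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.integrate import solve_ivp

from .laplacian import full_rhs
from .network import ReactionNetwork
from .reduction import ReducedNetwork

__all__ = ["Trajectory", "SolverError", "simulate", "RTOL", "ATOL"]

log = logging.getLogger(__name__)

RTOL = 1e-8
ATOL = 1e-10
NEGATIVE_CLAMP = 1e-12

Model = Union[ReactionNetwork, ReducedNetwork]


class SolverError(RuntimeError):
    """Integration failure; carries the last good state."""

    def __init__(self, message: str, t: float | None = None, x: np.ndarray | None = None):
        super().__init__(message)
        self.t = t
        self.x = x


@dataclass
class Trajectory:
    times: np.ndarray                 # strictly increasing, min
    states: np.ndarray                # (len(times), n_species), mM
    species_ids: list[str]
    meta: dict = field(default_factory=dict)

    def col(self, species_id: str) -> np.ndarray:
        return self.states[:, self.species_ids.index(species_id)]

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.states, index=pd.Index(self.times, name="time_min"),
                            columns=self.species_ids)


def _rhs_and_layout(model: Model):
    if isinstance(model, ReducedNetwork):
        return model.rhs, [s.id for s in model.species], model.x0
    return (lambda x: full_rhs(model, x)), [s.id for s in model.species], model.x0


def simulate(
    model: Model,
    x0: np.ndarray | None = None,
    T: float = 1.0,
    rtol: float = RTOL,
    atol: float = ATOL,
    t_eval: np.ndarray | None = None,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model from x0 over [0, T] (min).

    Clamped (fixed) species keep their initial values: a step perturbation
    is applied by handing in an x0 with the clamped entries already set to
    their post-event values.  Tiny negative excursions (>-1e-12) are
    clamped to zero and logged; larger ones abort.
    """
    rhs, ids, default_x0 = _rhs_and_layout(model)
    x0 = default_x0 if x0 is None else np.asarray(x0, dtype=float)
    if x0.shape != default_x0.shape:
        raise ValueError(f"x0 has {x0.shape[0]} entries, model has {default_x0.shape[0]} species")
    if np.any(x0 < 0):
        raise ValueError("negative initial concentrations")
    if T <= 0:
        raise ValueError("horizon T must be positive")

    def f(t: float, x: np.ndarray) -> np.ndarray:
        xs = np.where((x < 0) & (x > -NEGATIVE_CLAMP), 0.0, x)
        if np.any(xs < 0):
            raise SolverError(f"state went negative beyond tolerance at t={t}", t, x)
        return rhs(xs)

    sol = solve_ivp(f, (0.0, float(T)), x0, method=method, rtol=rtol, atol=atol,
                    t_eval=t_eval, dense_output=False)
    if not sol.success:
        raise SolverError(f"solver failed: {sol.message}", sol.t[-1] if len(sol.t) else None,
                          sol.y[:, -1] if sol.y.size else None)
    states = sol.y.T.copy()
    neg = states < 0
    if np.any(neg):
        worst = float(states[neg].min())
        if worst < -NEGATIVE_CLAMP:
            log.warning("clamping negative concentrations down to %g", worst)
        states[neg] = 0.0
    return Trajectory(
        times=sol.t.copy(),
        states=states,
        species_ids=ids,
        meta={"method": method, "rtol": rtol, "atol": atol, "T": float(T)},
    )
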