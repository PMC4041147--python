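"""State-dependent weighted Laplacian of the complex graph.

With edge weights k_j d_j(x), the adjacency matrix A(x) has entry
(pi, sigma) equal to the summed weight of all reactions sigma -> pi,
Delta(x) is the diagonal of column sums, and L(x) = Delta(x) - A(x).
The network dynamics then read

    dx/dt = -Z L(x) Exp(Z^T Ln x) + Z v_b(x)

where Exp(Z^T Ln x) is the vector of complex monomials (evaluated as
products so states with zero concentrations take the correct limit).
The identity B v(x) = -L(x) Exp(Z^T Ln x) ties this to the per-reaction
balance form dx/dt = Z B v(x) + Z v_b(x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ReactionNetwork

__all__ = [
    "LaplacianEval",
    "weighted_adjacency",
    "weighted_laplacian",
    "full_rhs",
    "laplacian_consistency_check",
]


@dataclass
class LaplacianEval:
    A: np.ndarray       # c x c, nonnegative
    Delta: np.ndarray   # c x c diagonal of column sums of A
    L: np.ndarray       # Delta - A
    at_state: np.ndarray


def weighted_adjacency(net: ReactionNetwork, x: np.ndarray) -> np.ndarray:
    """A(x)[pi, sigma] = sum of k_j d_j(x) over reactions sigma -> pi;
    parallel edges accumulate."""
    x = np.asarray(x, dtype=float)
    A = np.zeros((net.c, net.c))
    idx = net.species_index
    for rxn in net.reactions:
        A[rxn.product, rxn.substrate] += rxn.rate_law.k * rxn.rate_law.d(x, idx)
    return A


def weighted_laplacian(net: ReactionNetwork, x: np.ndarray) -> LaplacianEval:
    A = weighted_adjacency(net, x)
    Delta = np.diag(A.sum(axis=0))
    return LaplacianEval(A=A, Delta=Delta, L=Delta - A, at_state=np.asarray(x, float))


def full_rhs(net: ReactionNetwork, x: np.ndarray) -> np.ndarray:
    """dx/dt = -Z L(x) w(x) + Z v_b(x), with rows of externally clamped
    (fixed) species zeroed after assembly."""
    x = np.asarray(x, dtype=float)
    Z = net.Z
    L = weighted_laplacian(net, x).L
    w = net.complex_monomials(x)
    rhs = -Z @ (L @ w) + Z @ net.eval_boundary(x)
    if not np.all(np.isfinite(rhs)):
        bad = [net.species[i].id for i in np.nonzero(~np.isfinite(rhs))[0]]
        raise FloatingPointError(f"non-finite rate for species {bad} at x={x}")
    rhs[net.fixed_mask] = 0.0
    return rhs


def laplacian_consistency_check(net: ReactionNetwork, x: np.ndarray) -> float:
    """max-norm deviation of the identity B v(x) = -L(x) Exp(Z^T Ln x),
    relative to the flux scale."""
    x = np.asarray(x, dtype=float)
    Bv = net.B @ net.reaction_rates(x)
    Lw = weighted_laplacian(net, x).L @ net.complex_monomials(x)
    scale = max(1.0, float(np.max(np.abs(Bv))))
    return float(np.max(np.abs(Bv + Lw))) / scale


def dump_state(net: ReactionNetwork, x: np.ndarray, path: str) -> None:
    """Write A, Delta, L at a state to CSV (debugging aid)."""
    import pandas as pd

    ev = weighted_laplacian(net, x)
    labels = [cx.label() for cx in net.complexes]
    with open(path, "w") as fh:
        for name, M in (("A", ev.A), ("Delta", ev.Delta), ("L", ev.L)):
            fh.write(f"# {name}\n")
            pd.DataFrame(M, index=labels, columns=labels).to_csv(fh)
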