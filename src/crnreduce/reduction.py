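"""Model reduction by deletion of complexes (Kron/Schur reduction).

Deleting a set V_o of complexes imposes complex balancing on them: the
net inflow into each deleted complex equals its net outflow.  With the
Laplacian partitioned so the deleted indices come last,

    L = [[L11, L12], [L21, L22]],    P = [I  -L12 L22^-1],

the balancing constraint eliminates the deleted complexes' auxiliary
variables and yields the reduced dynamics

    dx/dt = Z1 (P v_b(x) - Lhat(x) Exp(Z1^T Ln x)),

where Lhat = L11 - L12 L22^-1 L21 is the Schur complement and Z1 holds
the retained columns of Z.  Lhat is again a weighted Laplacian (positive
diagonal, nonpositive off-diagonal, zero column sums), so the reduced
model is itself a reaction network on the retained complexes.  Species
whose Z1 rows vanish drop out of the dynamics; their concentrations are
frozen at caller-supplied values (typically the pre-perturbation steady
state) everywhere they appear, including inside saturation denominators.

The reduction is independent of the order of deletion: deleting {a, b}
in one Schur step equals deleting a then b.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import sympy as sp

from .kinetics import RateLaw, SiteProductDenominator
from .laplacian import weighted_laplacian
from .network import ReactionNetwork

__all__ = [
    "ReducedNetwork",
    "CollapsedRateLaw",
    "ReductionError",
    "schur_complement",
    "delete_complexes",
    "reduced_rhs",
    "eliminated_species",
    "classify_deletion",
    "symbolic_chain_collapse",
]

COND_LIMIT = 1e12


class ReductionError(ValueError):
    pass


def schur_complement(L: np.ndarray, delete_idx: Sequence[int]) -> np.ndarray:
    """Lhat = L11 - L12 L22^-1 L21, rows/cols `delete_idx` eliminated.

    The returned matrix is indexed by the retained complexes in their
    original order.  Raises on a singular or ill-conditioned L22.
    """
    L = np.asarray(L, dtype=float)
    delete_idx = sorted(set(int(i) for i in delete_idx))
    if not delete_idx:
        return L.copy()
    c = L.shape[0]
    if any(i < 0 or i >= c for i in delete_idx):
        raise ReductionError(f"deletion indices {delete_idx} out of range for c={c}")
    keep = [i for i in range(c) if i not in delete_idx]
    if not keep:
        raise ReductionError("cannot delete every complex")
    L11 = L[np.ix_(keep, keep)]
    L12 = L[np.ix_(keep, delete_idx)]
    L21 = L[np.ix_(delete_idx, keep)]
    L22 = L[np.ix_(delete_idx, delete_idx)]
    if np.linalg.cond(L22) > COND_LIMIT:
        raise ReductionError(
            f"L22 block for deleted complexes {delete_idx} is singular or "
            f"ill-conditioned (cond > {COND_LIMIT:g})"
        )
    return L11 - L12 @ np.linalg.solve(L22, L21)


def eliminated_species(net: ReactionNetwork, V_o: Iterable[int]) -> set[str]:
    """Species whose Z1 row (retained columns of Z) is all zero, i.e. that
    occur only in deleted complexes.  Species absent from every complex of
    the parent (clamped external inputs) are not reported."""
    V_o = set(V_o)
    keep = [i for i in range(net.c) if i not in V_o]
    Z = net.Z
    out = set()
    for i, s in enumerate(net.species):
        if np.any(Z[i, :]) and not np.any(Z[i, keep]):
            out.add(s.id)
    return out


class ReducedNetwork:
    """A reaction network with complexes V_o deleted by Schur complementation.

    The reduced right-hand side is evaluated against the *parent* network:
    at each state the parent Laplacian is assembled at the augmented state
    (retained concentrations merged with the frozen values of eliminated
    species) and Schur-complemented afresh — the reduction is exact in
    structure, approximate only through the frozen concentrations.
    """

    def __init__(
        self,
        parent: ReactionNetwork,
        deleted: Sequence[int],
        frozen: Mapping[str, float],
    ) -> None:
        self.parent = parent
        self.deleted = sorted(set(int(i) for i in deleted))
        if not self.deleted:
            raise ReductionError("V_o must be nonempty")
        if len(self.deleted) >= parent.c:
            raise ReductionError("V_o must be a proper subset of the complexes")
        self.retained = [i for i in range(parent.c) if i not in set(self.deleted)]
        self.Z1 = parent.Z[:, self.retained]

        self.eliminated = eliminated_species(parent, self.deleted)
        missing = self.eliminated - set(frozen)
        if missing:
            raise ReductionError(f"missing freeze values for eliminated species {sorted(missing)}")
        self.frozen = {s: float(frozen[s]) for s in self.eliminated}
        for s, v in self.frozen.items():
            if not (v > 0):
                raise ReductionError(f"frozen value for {s} must be positive, got {v}")

        # state layout: parent species that still take part in the dynamics
        # (nonzero Z1 row) or that are clamped external inputs
        Zp = parent.Z
        self.retained_species = [
            i for i, s in enumerate(parent.species)
            if s.id not in self.eliminated and (np.any(self.Z1[i, :]) or not np.any(Zp[i, :]))
        ]
        self.species = [parent.species[i] for i in self.retained_species]
        self.species_index = {s.id: k for k, s in enumerate(self.species)}
        self._full_template = parent.x0.copy()
        for sid, v in self.frozen.items():
            self._full_template[parent.species_index[sid]] = v

    # -- bookkeeping --------------------------------------------------------
    @property
    def c_hat(self) -> int:
        return len(self.retained)

    @property
    def n_state_variables(self) -> int:
        return sum(1 for s in self.species if not s.fixed)

    @property
    def x0(self) -> np.ndarray:
        return np.array([s.x0 for s in self.species], dtype=float)

    @property
    def fixed_mask(self) -> np.ndarray:
        return np.array([s.fixed for s in self.species], dtype=bool)

    def augment(self, x: np.ndarray) -> np.ndarray:
        """Embed the retained-species state into the parent's species order,
        eliminated species at their frozen values."""
        xf = self._full_template.copy()
        xf[self.retained_species] = np.asarray(x, dtype=float)
        return xf

    # -- structure of the reduced complex graph -----------------------------
    def structural_edges(self) -> set[tuple[int, int]]:
        """Directed edges of the Schur-reduced graph, as pairs of *parent*
        complex indices: alpha -> beta iff the parent has a directed path
        from alpha to beta through deleted vertices only."""
        succ: dict[int, set[int]] = {i: set() for i in range(self.parent.c)}
        for rxn in self.parent.reactions:
            succ[rxn.substrate].add(rxn.product)
        dele = set(self.deleted)
        edges: set[tuple[int, int]] = set()
        for a in self.retained:
            # BFS expanding only through deleted vertices
            frontier = list(succ[a])
            seen: set[int] = set(frontier)
            while frontier:
                v = frontier.pop()
                if v in dele:
                    for u in succ[v]:
                        if u not in seen:
                            seen.add(u)
                            frontier.append(u)
                elif v != a:
                    edges.add((a, v))
        return edges

    def reaction_counts(self) -> tuple[int, int]:
        """(reversible, irreversible) reaction counts of the reduced graph,
        a reversible pair counting as one reaction."""
        edges = self.structural_edges()
        rev = sum(1 for (a, b) in edges if a < b and (b, a) in edges)
        return rev, len(edges) - 2 * rev

    # -- dynamics ------------------------------------------------------------
    def rhs(self, x: np.ndarray) -> np.ndarray:
        return reduced_rhs(self, x)

    def reduced_laplacian(self, x: np.ndarray) -> np.ndarray:
        """Lhat(x) at a retained-species state."""
        xf = self.augment(x)
        L = weighted_laplacian(self.parent, xf).L
        return schur_complement(L, self.deleted)


def delete_complexes(
    net: ReactionNetwork,
    V_o: Iterable[int],
    freeze_values: Mapping[str, float],
    protected: Iterable[int] = (),
) -> ReducedNetwork:
    """Delete the complexes V_o, freezing eliminated species at
    `freeze_values` (mM).  `protected` complexes may not be deleted."""
    V_o = set(int(i) for i in V_o)
    clash = V_o & set(protected)
    if clash:
        raise ReductionError(f"complexes {sorted(clash)} are protected from deletion")
    return ReducedNetwork(net, sorted(V_o), freeze_values)


def reduced_rhs(red: ReducedNetwork, x: np.ndarray) -> np.ndarray:
    """dx/dt over the retained species: Z1 (P v_b - Lhat(x) w1), with the
    parent Laplacian evaluated at the augmented state and Schur-complemented
    at the current state; clamped species rows are zeroed."""
    net = red.parent
    xf = red.augment(x)
    L = weighted_laplacian(net, xf).L
    keep, dele = red.retained, red.deleted
    L11 = L[np.ix_(keep, keep)]
    L12 = L[np.ix_(keep, dele)]
    L21 = L[np.ix_(dele, keep)]
    L22 = L[np.ix_(dele, dele)]
    if np.linalg.cond(L22) > COND_LIMIT:
        raise ReductionError(
            f"L22 singular during evaluation at state {xf} "
            f"(deleted complexes {dele})"
        )
    w = net.complex_monomials(xf)
    w1 = w[keep]
    vb = net.eval_boundary(xf)
    Pvb = vb[keep] - L12 @ np.linalg.solve(L22, vb[dele])
    Lhat_w1 = L11 @ w1 - L12 @ np.linalg.solve(L22, L21 @ w1)
    rhs_full = red.Z1 @ (Pvb - Lhat_w1)
    rhs_full[net.fixed_mask] = 0.0
    return rhs_full[red.retained_species]


# -- structural classification of a single deletion --------------------------

def _neighbor_structure(net: ReactionNetwork, idx: int):
    fwd: set[int] = set()   # neighbors beta with idx -> beta
    back: set[int] = set()  # neighbors beta with beta -> idx
    for rxn in net.reactions:
        if rxn.substrate == idx:
            fwd.add(rxn.product)
        if rxn.product == idx:
            back.add(rxn.substrate)
    return fwd, back


def _species_sharing_components(reaction_species: list[set[str]]) -> int:
    """Connected components of the graph over reactions where two reactions
    are linked if they share a species."""
    n = len(reaction_species)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if reaction_species[i] & reaction_species[j]:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def classify_deletion(net: ReactionNetwork, complex_idx: int) -> str:
    """Classify the structural effect of deleting one complex.

    Returns one of:
      - "disconnecting": the deletion splits the species-sharing structure
        of the reactions into more independent groups (the hazard of
        deleting a complex whose reaction couples otherwise species-disjoint
        parts of the network);
      - "linkage_removal": the complex's linkage class is a single
        reversible pair, so deletion removes the whole linkage class;
      - "type3": the complex takes part in more than two reactions
        (degree > 2); deletion completely couples its neighbors and does
        not reduce the reaction or parameter count;
      - "type1": interior of a reversible chain (two reversible neighbors);
        the two reversible reactions merge into one;
      - "type2": one reversible and one irreversible neighbor; the pair
        merges into a single irreversible reaction;
      - "other": anything else.
    """
    if not (0 <= complex_idx < net.c):
        raise ReductionError(f"complex index {complex_idx} out of range")
    fwd, back = _neighbor_structure(net, complex_idx)
    neighbors = fwd | back

    # species-sharing components before/after the structural deletion
    def edge_species(a: int, b: int) -> set[str]:
        return net.complexes[a].species_ids() | net.complexes[b].species_ids()

    full_undirected = {tuple(sorted((r.substrate, r.product))) for r in net.reactions}
    before = _species_sharing_components([edge_species(a, b) for a, b in full_undirected])

    elim = eliminated_species(net, [complex_idx])
    reduced_edges = set()
    for a, b in full_undirected:
        if complex_idx in (a, b):
            continue
        reduced_edges.add((a, b))
    for a in neighbors:
        for b in neighbors:
            if a < b:
                reduced_edges.add((a, b))
    after = _species_sharing_components(
        [edge_species(a, b) - elim for a, b in reduced_edges]
    )
    if after > before:
        return "disconnecting"

    from .network import linkage_classes

    my_class = next(cl for cl in linkage_classes(net) if complex_idx in cl)
    if len(my_class) == 2 and len(neighbors) == 1:
        nb = next(iter(neighbors))
        if nb in fwd and nb in back:
            return "linkage_removal"

    if len(neighbors) > 2:
        return "type3"
    if len(neighbors) == 2:
        a, b = sorted(neighbors)
        rev_a = a in fwd and a in back
        rev_b = b in fwd and b in back
        if rev_a and rev_b:
            return "type1"
        if rev_a != rev_b:
            return "type2"
    return "other"


# -- symbolic collapse of a reversible-MM chain interior ----------------------

@dataclass
class CollapsedRateLaw:
    """Closed-form overall rate of a collapsed reversible-MM chain step:

        v(x) = (kf_red * w_sub - kr_red * w_prod)
               / (1 + sum_monomials m(x)/Km_red[m])

    with w_sub, w_prod the substrate/product complex monomials.  The
    reduced constants absorb the original rate and Michaelis constants
    and the frozen concentrations of the eliminated intermediates; the
    equilibrium constant composes: kf_red/kr_red = Keq_I * Keq_II.
    """

    kf_red: float
    kr_red: float
    Km_red: dict[tuple[tuple[str, int], ...], float]  # monomial -> Km
    substrate_stoich: dict[str, int]
    product_stoich: dict[str, int]

    @property
    def keq(self) -> float:
        return self.kf_red / self.kr_red

    @property
    def n_parameters(self) -> int:
        return 2 + len(self.Km_red)

    def rate(self, x: np.ndarray, index: Mapping[str, int]) -> float:
        """Net rate in the forward direction at a state."""
        def mono(stoich: Mapping[str, int]) -> float:
            p = 1.0
            for s, e in stoich.items():
                p *= x[index[s]] ** e
            return p

        num = self.kf_red * mono(self.substrate_stoich) - self.kr_red * mono(self.product_stoich)
        den = 1.0
        for m, Km in self.Km_red.items():
            den += mono(dict(m)) / Km
        return num / den


def symbolic_chain_collapse(
    net: ReactionNetwork,
    mid_complex: int,
    frozen: Mapping[str, float],
) -> CollapsedRateLaw:
    """Collapse left <-> mid <-> right (both steps reversible MM) into one
    reversible reaction left <-> right by complex balancing on `mid`.

    Balancing v1f - v1r = v2f - v2r and substituting the implied
    intermediate monomial gives the overall forward rate

        v = (kfI kfII w_left - krI krII w_right) / (kfII p1 + krI p2);

    the intermediates' concentrations inside p1, p2 are then fixed at
    `frozen`, and the denominator polynomial is expanded and normalized
    so its constant term is 1, yielding reduced constants kf_red, kr_red
    and one reduced saturation constant per surviving monomial.
    """
    fwd, back = _neighbor_structure(net, mid_complex)
    neighbors = sorted(fwd | back)
    if len(neighbors) != 2:
        raise ReductionError("symbolic collapse needs a chain interior (exactly two neighbors)")
    left, right = neighbors

    def find_edge(a: int, b: int) -> RateLaw:
        for rxn in net.reactions:
            if rxn.substrate == a and rxn.product == b:
                return rxn.rate_law
        raise ReductionError(f"missing reaction {a} -> {b}: both steps must be reversible")

    law_f1 = find_edge(left, mid_complex)
    law_r1 = find_edge(mid_complex, left)
    law_f2 = find_edge(mid_complex, right)
    law_r2 = find_edge(right, mid_complex)
    for law in (law_f1, law_r1, law_f2, law_r2):
        if not isinstance(law.denominator, SiteProductDenominator):
            raise ReductionError(
                "symbolic collapse requires reversible Michaelis-Menten steps "
                "(site-product denominators)"
            )
    p1, p2 = law_f1.denominator, law_f2.denominator
    if law_r1.denominator is not p1 or law_r2.denominator is not p2:
        raise ReductionError("each reversible step must share one denominator")

    mid_species = net.complexes[mid_complex].species_ids()
    end_species = (
        net.complexes[left].species_ids() | net.complexes[right].species_ids()
    )
    intermediates = mid_species - end_species
    missing = intermediates - set(frozen)
    if missing:
        raise ReductionError(f"missing frozen values for intermediates {sorted(missing)}")
    for s in intermediates:
        if not (float(frozen[s]) > 0):
            raise ReductionError(f"frozen value for {s} must be positive")

    syms: dict[str, sp.Symbol] = {}

    def term_expr(ref, K):
        tag, payload = ref
        if tag == "const":
            return sp.Float(payload) / K
        sid = payload
        if sid in intermediates:
            return sp.Float(float(frozen[sid])) / K
        syms.setdefault(sid, sp.Symbol(sid, positive=True))
        return syms[sid] / K

    def poly_of(den: SiteProductDenominator):
        p = sp.Integer(1)
        for site in den.sites:
            p *= 1 + sum(term_expr(ref, K) for ref, K in site)
        return sp.expand(p)

    D = sp.expand(law_f2.k * poly_of(p1) + law_r1.k * poly_of(p2))
    gens = sorted(syms.values(), key=lambda s: s.name)
    if gens:
        poly = sp.Poly(D, *gens)
        coeffs = {tuple(m): float(co) for m, co in zip(poly.monoms(), poly.coeffs())}
    else:
        coeffs = {(): float(D)}
    c0 = coeffs.pop(tuple([0] * len(gens)), 0.0)
    if not (c0 > 0):
        raise ReductionError("degenerate collapsed denominator (nonpositive constant term)")

    Km_red: dict[tuple[tuple[str, int], ...], float] = {}
    for mono, co in coeffs.items():
        key = tuple(
            sorted((g.name, int(e)) for g, e in zip(gens, mono) if e > 0)
        )
        Km_red[key] = c0 / co

    return CollapsedRateLaw(
        kf_red=law_f1.k * law_f2.k / c0,
        kr_red=law_r1.k * law_r2.k / c0,
        Km_red=Km_red,
        substrate_stoich=net.complexes[left].as_map(),
        product_stoich=net.complexes[right].as_map(),
    )
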