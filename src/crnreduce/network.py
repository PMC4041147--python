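"""Complex-graph representation of a kinetic reaction network.

A reaction network is viewed as a directed graph whose vertices are
*complexes* — the distinct left- and right-hand sides of the reactions —
and whose edges are the (directed) reactions.  Species enter through the
complex stoichiometric matrix ``Z`` (m x c), whose column alpha gives the
species composition of complex alpha; the graph itself is carried by the
incidence matrix ``B`` (c x r).  The species balance laws are then

    dx/dt = Z B v(x) + Z v_b(x)

with v the reaction rates and v_b per-complex boundary (exchange) fluxes.

Units throughout the package: concentrations in mM, time in min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .kinetics import RateLaw

__all__ = [
    "Species",
    "Complex",
    "Reaction",
    "BoundaryFlux",
    "ReactionNetwork",
    "NetworkValidationError",
    "build_complexes",
    "complex_stoichiometric_matrix",
    "incidence_matrix",
    "linkage_classes",
    "validate_network",
]


class NetworkValidationError(ValueError):
    """Raised on a fatally inconsistent network description."""


@dataclass
class Species:
    id: str
    name: str = ""
    x0: float = 0.0
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.x0 < 0:
            raise NetworkValidationError(
                f"species {self.id!r}: negative initial concentration {self.x0}"
            )


@dataclass(frozen=True)
class Complex:
    """A multiset of species: the left- or right-hand side of a reaction."""

    stoich: tuple[tuple[str, int], ...]  # sorted (species_id, coeff>0) pairs

    @staticmethod
    def from_map(stoich: Mapping[str, int]) -> "Complex":
        items = tuple(sorted((s, int(n)) for s, n in stoich.items() if n != 0))
        if not items:
            raise NetworkValidationError("complex with all-zero stoichiometry")
        if any(n < 0 for _, n in items):
            raise NetworkValidationError(f"negative stoichiometry in complex {dict(stoich)}")
        return Complex(items)

    def as_map(self) -> dict[str, int]:
        return dict(self.stoich)

    def species_ids(self) -> set[str]:
        return {s for s, _ in self.stoich}

    def label(self) -> str:
        return "+".join(f"{n if n > 1 else ''}{s}" for s, n in self.stoich)


@dataclass
class Reaction:
    """Directed edge of the complex graph.

    Reversible reactions are stored as two directed records sharing the
    denominator of their rate law (see :mod:`crnreduce.kinetics`).
    """

    substrate: int  # complex index S_j (tail)
    product: int    # complex index P_j (head)
    rate_law: RateLaw
    reverse_of: int | None = None  # index of the partner edge, if reversible


@dataclass
class BoundaryFlux:
    """Per-complex exchange flux v_b (mM/min, positive = inflow).

    kind "constant": value; kind "linear": coef * x[species]; kind
    "monomial": coef * prod_i x_i^{Z[i, complex]} (first order in the
    complex); kind "custom": arbitrary callable of the full state (not
    serializable).
    """

    kind: str
    value: float = 0.0
    coef: float = 0.0
    species: str | None = None
    fn: Callable[[np.ndarray], float] | None = None


class ReactionNetwork:
    """Species, complexes, directed reactions and boundary fluxes."""

    def __init__(
        self,
        species: Sequence[Species],
        complexes: Sequence[Complex],
        reactions: Sequence[Reaction],
        boundary_fluxes: Mapping[int, BoundaryFlux] | None = None,
        name: str = "",
    ) -> None:
        self.species = list(species)
        self.complexes = list(complexes)
        self.reactions = list(reactions)
        self.boundary_fluxes = dict(boundary_fluxes or {})
        self.name = name
        if not self.species or not self.complexes or not self.reactions:
            raise NetworkValidationError("network needs at least one species, complex and reaction")
        self.species_index = {s.id: i for i, s in enumerate(self.species)}
        if len(self.species_index) != len(self.species):
            raise NetworkValidationError("duplicate species ids")
        self._Z: np.ndarray | None = None
        self._B: np.ndarray | None = None

    # -- dimensions ---------------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.species)

    @property
    def c(self) -> int:
        return len(self.complexes)

    @property
    def r(self) -> int:
        return len(self.reactions)

    @property
    def x0(self) -> np.ndarray:
        return np.array([s.x0 for s in self.species], dtype=float)

    @property
    def fixed_mask(self) -> np.ndarray:
        return np.array([s.fixed for s in self.species], dtype=bool)

    # -- structure ----------------------------------------------------------
    @property
    def Z(self) -> np.ndarray:
        if self._Z is None:
            self._Z = complex_stoichiometric_matrix(self)
        return self._Z

    @property
    def B(self) -> np.ndarray:
        if self._B is None:
            self._B = incidence_matrix(self)
        return self._B

    def complex_monomials(self, x: np.ndarray) -> np.ndarray:
        """w_alpha = prod_i x_i^{Z[i,alpha]} with the 0^0 := 1 convention."""
        Z = self.Z
        xc = np.asarray(x, dtype=float)
        # where the exponent is zero the factor is 1 even at x_i = 0
        base = np.where(Z > 0, xc[:, None], 1.0)
        expo = np.where(Z > 0, Z, 0)
        return np.prod(base ** expo, axis=0)

    def eval_boundary(self, x: np.ndarray) -> np.ndarray:
        """Boundary flux vector v_b(x) in R^c."""
        vb = np.zeros(self.c)
        if not self.boundary_fluxes:
            return vb
        w = None
        for alpha, bf in self.boundary_fluxes.items():
            if bf.kind == "constant":
                vb[alpha] = bf.value
            elif bf.kind == "linear":
                vb[alpha] = bf.coef * x[self.species_index[bf.species]]
            elif bf.kind == "monomial":
                if w is None:
                    w = self.complex_monomials(x)
                vb[alpha] = bf.coef * w[alpha]
            elif bf.kind == "custom":
                vb[alpha] = bf.fn(x)
            else:  # pragma: no cover - guarded at construction
                raise NetworkValidationError(f"unknown boundary flux kind {bf.kind!r}")
        return vb

    def reaction_rates(self, x: np.ndarray) -> np.ndarray:
        """v(x) in R^r, per-reaction evaluation of the factored rate laws."""
        from .kinetics import eval_rate

        Z = self.Z
        return np.array(
            [eval_rate(rxn.rate_law, Z[:, rxn.substrate], x, self.species_index)
             for rxn in self.reactions]
        )

    def n_parameters(self) -> int:
        """Kinetic parameter count: one k per directed edge plus the distinct
        constants of each denominator, counting shared (reversible-pair)
        denominators once."""
        n = self.r  # one proportionality constant per directed reaction
        seen: set[int] = set()
        for rxn in self.reactions:
            d = rxn.rate_law.denominator
            if d is None or id(d) in seen:
                continue
            seen.add(id(d))
            n += d.n_parameters()
        return n

    def reversible_pair_count(self) -> tuple[int, int]:
        """(number of reversible reactions, number of irreversible ones)."""
        rev = sum(1 for rxn in self.reactions if rxn.reverse_of is not None)
        return rev // 2, self.r - rev


def build_complexes(
    reaction_specs: Iterable[tuple[Mapping[str, int], Mapping[str, int], RateLaw]],
    species: Sequence[Species] | None = None,
    boundary_fluxes: Mapping[int, BoundaryFlux] | None = None,
    name: str = "",
) -> ReactionNetwork:
    """Assemble a network from (substrate map, product map, rate law) triples.

    Complexes are the union of all distinct left- and right-hand sides;
    duplicates are merged and the ordering is insertion order of first
    appearance (left side before right side, reaction order).  If `species`
    is omitted, species records are created in order of first appearance
    with x0 = 0.
    """
    specs = list(reaction_specs)
    if not specs:
        raise NetworkValidationError("empty reaction list")

    complexes: list[Complex] = []
    index: dict[Complex, int] = {}
    sp_order: list[str] = []
    sp_seen: set[str] = set()

    def intern(stoich: Mapping[str, int]) -> int:
        cx = Complex.from_map(stoich)
        if cx not in index:
            index[cx] = len(complexes)
            complexes.append(cx)
            for s, _ in cx.stoich:
                if s not in sp_seen:
                    sp_seen.add(s)
                    sp_order.append(s)
        return index[cx]

    reactions: list[Reaction] = []
    for sub, prod, law in specs:
        si = intern(sub)
        pi = intern(prod)
        if si == pi:
            raise NetworkValidationError(
                f"reaction with identical substrate and product complex {complexes[si].label()}"
            )
        reactions.append(Reaction(si, pi, law))

    # annotate reversible pairs: consecutive edges sharing a denominator object
    # and swapped endpoints
    for i, ri in enumerate(reactions):
        if ri.reverse_of is not None:
            continue
        for j in range(i + 1, len(reactions)):
            rj = reactions[j]
            if (
                rj.reverse_of is None
                and rj.substrate == ri.product
                and rj.product == ri.substrate
                and ri.rate_law.denominator is not None
                and rj.rate_law.denominator is ri.rate_law.denominator
            ):
                ri.reverse_of, rj.reverse_of = j, i
                break

    if species is None:
        species = [Species(sid) for sid in sp_order]
    else:
        species = list(species)

    return ReactionNetwork(species, complexes, reactions, boundary_fluxes, name=name)


def complex_stoichiometric_matrix(net: ReactionNetwork) -> np.ndarray:
    """Z (m x c): column alpha is the species composition of complex alpha."""
    Z = np.zeros((net.m, net.c), dtype=int)
    for alpha, cx in enumerate(net.complexes):
        for sid, n in cx.stoich:
            Z[net.species_index[sid], alpha] = n
    return Z


def incidence_matrix(net: ReactionNetwork) -> np.ndarray:
    """B (c x r): -1 at the substrate (tail) complex, +1 at the product."""
    B = np.zeros((net.c, net.r), dtype=int)
    for j, rxn in enumerate(net.reactions):
        B[rxn.substrate, j] = -1
        B[rxn.product, j] = 1
    return B


def linkage_classes(net: ReactionNetwork) -> list[list[int]]:
    """Connected components of the undirected complex graph, each sorted,
    ordered by smallest member."""
    adj: dict[int, set[int]] = {i: set() for i in range(net.c)}
    for rxn in net.reactions:
        adj[rxn.substrate].add(rxn.product)
        adj[rxn.product].add(rxn.substrate)
    seen: set[int] = set()
    classes: list[list[int]] = []
    for start in range(net.c):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            v = stack.pop()
            comp.append(v)
            for u in adj[v]:
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        classes.append(sorted(comp))
    return classes


@dataclass
class Diagnostics:
    warnings: list[str] = field(default_factory=list)

    def ok(self) -> bool:
        return not self.warnings


def validate_network(net: ReactionNetwork) -> Diagnostics:
    """Structural checks; raises :class:`NetworkValidationError` on fatal
    issues, collects the rest as warnings."""
    diag = Diagnostics()
    for rxn in net.reactions:
        if not (0 <= rxn.substrate < net.c) or not (0 <= rxn.product < net.c):
            raise NetworkValidationError(
                f"reaction references complex index out of range: {rxn.substrate}->{rxn.product}"
            )
        if rxn.substrate == rxn.product:
            raise NetworkValidationError("self-loop reaction (S_j = P_j)")
    for s in net.species:
        if s.x0 < 0:
            raise NetworkValidationError(f"species {s.id!r}: negative x0")

    seen: dict[Complex, int] = {}
    for alpha, cx in enumerate(net.complexes):
        if not cx.stoich:
            raise NetworkValidationError(f"complex {alpha} has all-zero stoichiometry")
        if cx in seen:
            diag.warnings.append(f"duplicate complexes {seen[cx]} and {alpha} ({cx.label()})")
        seen[cx] = alpha

    used = {s for cx in net.complexes for s in cx.species_ids()}
    for bf in net.boundary_fluxes.values():
        if bf.species is not None:
            used.add(bf.species)
    orphans = [s.id for s in net.species if s.id not in used]
    if orphans:
        diag.warnings.append(f"orphan species (in no complex): {', '.join(orphans)}")

    touched = {rxn.substrate for rxn in net.reactions} | {rxn.product for rxn in net.reactions}
    touched |= set(net.boundary_fluxes)
    for alpha in range(net.c):
        if alpha not in touched:
            diag.warnings.append(
                f"complex {alpha} ({net.complexes[alpha].label()}) used by no reaction or boundary flux"
            )

    for msg in diag.warnings:
        warnings.warn(msg, stacklevel=2)
    return diag
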