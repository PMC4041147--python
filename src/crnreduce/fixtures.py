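"""Programmatic generators for the network archetypes used in tests.

All fixtures are small kinetic networks built in memory — nothing is
read from disk.  Default parameters are chosen so that the archetypes
behave as intended physically: in the three-complex chain the interior
complex equilibrates fast relative to the ends, which is the regime in
which complex balancing (the premise of the reduction) is a good
approximation.
"""

from __future__ import annotations

import numpy as np

from .kinetics import make_rate_law, reversible_mm_pair
from .network import BoundaryFlux, ReactionNetwork, Species, build_complexes

__all__ = [
    "example1_network",
    "example1_driven",
    "chain_network",
    "type2_chain",
    "type3_star",
    "disconnecting_triple",
    "two_state",
    "random_enzymatic_network",
]


def example1_network(
    kf_I: float = 1.0,
    kr_I: float = 0.5,
    kf_II: float = 50.0,
    kr_II: float = 25.0,
    Km_I: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
    Km_II: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
    x0: tuple[float, ...] = (2.0, 2.0, 0.1, 0.1, 0.5, 0.5),
) -> ReactionNetwork:
    """The three-complex reversible-MM chain X1+X2 <-> X3+X4 <-> X5+X6.

    Saturation denominators (shared between the two directions of each
    step): p1 = (1 + x1/KmI1 + x3/KmI3)(1 + x2/KmI2 + x4/KmI4) and
    p2 = (1 + x3/KmII3 + x5/KmII5)(1 + x4/KmII4 + x6/KmII6).
    6 species, 3 complexes, 4 directed reactions, 12 kinetic parameters.
    The second step is fast by default (kf_II, kr_II >> kf_I, kr_I) so the
    intermediate complex is close to balanced.
    """
    K1, K2, K3a, K4a = Km_I
    K3b, K4b, K5, K6 = Km_II
    f1, r1 = reversible_mm_pair(kf_I, kr_I, [[("X1", K1), ("X3", K3a)],
                                             [("X2", K2), ("X4", K4a)]])
    f2, r2 = reversible_mm_pair(kf_II, kr_II, [[("X3", K3b), ("X5", K5)],
                                               [("X4", K4b), ("X6", K6)]])
    c12 = {"X1": 1, "X2": 1}
    c34 = {"X3": 1, "X4": 1}
    c56 = {"X5": 1, "X6": 1}
    species = [Species(f"X{i+1}", x0=x0[i]) for i in range(6)]
    return build_complexes(
        [(c12, c34, f1), (c34, c12, r1), (c34, c56, f2), (c56, c34, r2)],
        species=species,
        name="example1",
    )


def example1_driven(
    k_in: float = 0.05,
    k_out: float = 0.05,
    g0: float = 0.2,
    **kwargs,
) -> ReactionNetwork:
    """Open variant of the three-complex chain, driven by a clamped external
    species G: constant-per-G inflow into the X1+X2 complex and first-order
    outflow from the X5+X6 complex.  A step change of G emulates a
    substrate-upshift scenario."""
    net = example1_network(**kwargs)
    species = net.species + [Species("G", x0=g0, fixed=True)]
    return ReactionNetwork(
        species,
        net.complexes,
        net.reactions,
        boundary_fluxes={
            0: BoundaryFlux("linear", coef=k_in, species="G"),
            2: BoundaryFlux("monomial", coef=-k_out),
        },
        name="example1_driven",
    )


def _rev_mass_action(kf: float, kr: float):
    # reversible mass action = reversible pair with an empty (d == 1)
    # shared denominator, so the two directions stay linked
    return reversible_mm_pair(kf, kr, sites=[])


def chain_network(
    n: int = 3,
    kinetics_kind: str = "mass_action",
    params: dict | None = None,
    seed: int | None = None,
) -> ReactionNetwork:
    """Reversible chain C1 <-> C2 <-> ... <-> Cn of unimolecular complexes.

    kinetics_kind "mass_action": rate constants kf[i], kr[i] (default 1.0
    and 0.5, or log-uniform when `seed` is given); "rev_mm": additionally
    Michaelis constants Km[i] per species (default 1.0)."""
    if n < 3:
        raise ValueError("chain needs n >= 3 complexes")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if seed is not None:
        kf = 10.0 ** rng.uniform(-1, 1, n - 1)
        kr = 10.0 ** rng.uniform(-1, 1, n - 1)
    else:
        kf = params.get("kf", [1.0] * (n - 1))
        kr = params.get("kr", [0.5] * (n - 1))
    Km = params.get("Km", [1.0] * n)
    x0 = params.get("x0", [1.0] * n)

    specs = []
    for i in range(n - 1):
        a, b = f"S{i+1}", f"S{i+2}"
        if kinetics_kind == "mass_action":
            f, r = _rev_mass_action(kf[i], kr[i])
        elif kinetics_kind == "rev_mm":
            f, r = reversible_mm_pair(kf[i], kr[i], [[(a, Km[i]), (b, Km[i + 1])]])
        else:
            raise ValueError(f"unknown kinetics kind {kinetics_kind!r}")
        specs.append(({a: 1}, {b: 1}, f))
        specs.append(({b: 1}, {a: 1}, r))
    species = [Species(f"S{i+1}", x0=x0[i]) for i in range(n)]
    return build_complexes(specs, species=species, name=f"chain{n}")


def type2_chain() -> ReactionNetwork:
    """C1 <-> C2 -> C3: an interior complex with one reversible and one
    irreversible neighbor."""
    f, r = _rev_mass_action(1.0, 0.5)
    irr = make_rate_law("mm_irreversible", V=2.0, Km=1.0, substrate="B")
    species = [Species("A", x0=1.0), Species("B", x0=1.0), Species("C", x0=0.1)]
    return build_complexes(
        [({"A": 1}, {"B": 1}, f), ({"B": 1}, {"A": 1}, r), ({"B": 1}, {"C": 1}, irr)],
        species=species,
        name="type2_chain",
    )


def type3_star() -> ReactionNetwork:
    """Star linkage class: hub C2 reversibly connected to C1, C3 and C4
    (a complex involved in more than two reactions)."""
    species = [Species(s, x0=1.0) for s in "ABCD"]
    specs = []
    for leaf, (kf, kr) in zip("ACD", [(1.0, 0.5), (2.0, 1.0), (0.8, 0.4)]):
        f, r = _rev_mass_action(kf, kr)
        specs.append(({leaf: 1}, {"B": 1}, f))
        specs.append(({"B": 1}, {leaf: 1}, r))
    # order complexes as C1, C2, C3, C4
    net = build_complexes(specs, species=species, name="type3_star")
    return net


def disconnecting_triple() -> ReactionNetwork:
    """Three reversible bimolecular reactions chained only through shared
    species: X1+X2 <-> X3+X4, X4+X5 <-> X6+X7, X7+X8 <-> X9+X10.
    Deleting the complex X4+X5 removes the middle reaction and decouples
    the outer two, which share no species — the disconnecting hazard."""
    species = [Species(f"X{i}", x0=1.0) for i in range(1, 11)]
    pairs = [({"X1": 1, "X2": 1}, {"X3": 1, "X4": 1}),
             ({"X4": 1, "X5": 1}, {"X6": 1, "X7": 1}),
             ({"X7": 1, "X8": 1}, {"X9": 1, "X10": 1})]
    specs = []
    for sub, prod in pairs:
        f, r = _rev_mass_action(1.0, 0.5)
        specs.append((sub, prod, f))
        specs.append((prod, sub, r))
    return build_complexes(specs, species=species, name="disconnecting_triple")


def two_state(kf: float = 2.0, kr: float = 1.0, a0: float = 3.0, b0: float = 0.0) -> ReactionNetwork:
    """Closed A <-> B mass-action pair; equilibrium at b/a = kf/kr with
    a + b conserved."""
    f, r = _rev_mass_action(kf, kr)
    species = [Species("A", x0=a0), Species("B", x0=b0)]
    return build_complexes(
        [({"A": 1}, {"B": 1}, f), ({"B": 1}, {"A": 1}, r)],
        species=species,
        name="two_state",
    )


def random_enzymatic_network(
    m: int = 6,
    c: int = 5,
    density: float = 0.3,
    kinetics_mix: tuple[str, ...] = ("mass_action", "rev_mm"),
    seed: int = 0,
) -> ReactionNetwork:
    """Random connected complex graph with catalogued rate laws and
    log-uniform parameters; identical for identical seeds.

    All edges are reversible, so every complex has outflow and any single
    deletion leaves an invertible L22 block.  The first complexes pair up
    consecutive species so that no species is orphaned.
    """
    rng = np.random.default_rng(seed)
    sids = [f"S{i}" for i in range(m)]
    base = [{sids[i]: 1, sids[min(i + 1, m - 1)]: 1} if i + 1 < m else {sids[i]: 1}
            for i in range(0, m, 2)]
    if c < len(base):
        raise ValueError(f"need c >= {len(base)} complexes to cover {m} species")

    seen = {tuple(sorted(cx.items())) for cx in base}
    complexes = list(base)
    guard = 0
    while len(complexes) < c:
        guard += 1
        if guard > 1000:
            raise ValueError("cannot generate enough distinct complexes")
        k = int(rng.integers(1, 3))
        chosen = rng.choice(m, size=min(k, m), replace=False)
        cx = {sids[i]: int(rng.integers(1, 3)) for i in sorted(chosen)}
        key = tuple(sorted(cx.items()))
        if key not in seen:
            seen.add(key)
            complexes.append(cx)

    # spanning tree + density extras, all reversible
    order = rng.permutation(c)
    edges = {(min(int(order[i]), int(a)), max(int(order[i]), int(a)))
             for i, a in ((i, order[int(rng.integers(0, i))]) for i in range(1, c))}
    for a in range(c):
        for b in range(a + 1, c):
            if (a, b) not in edges and rng.random() < density:
                edges.add((a, b))

    specs = []
    for a, b in sorted(edges):
        kind = kinetics_mix[int(rng.integers(0, len(kinetics_mix)))]
        kf, kr = 10.0 ** rng.uniform(-1, 1, 2)
        sub, prod = complexes[a], complexes[b]
        if kind == "mass_action":
            f, r = _rev_mass_action(kf, kr)
        else:
            site = [(s, float(10.0 ** rng.uniform(-1, 1)))
                    for s in sorted(set(sub) | set(prod))]
            f, r = reversible_mm_pair(kf, kr, [site])
        specs.append((sub, prod, f))
        specs.append((prod, sub, r))

    species = [Species(s, x0=float(10.0 ** rng.uniform(-1, 1))) for s in sids]
    net = build_complexes(specs, species=species, name=f"random{seed}")
    assert net.c == c
    return net
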