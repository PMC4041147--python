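# Methods

## Model

A reaction network is stored as species (mM), complexes (integer
multisets of species) and directed reactions between complexes.
Reversible reactions are two directed edges sharing one saturation
denominator object, so detailed balance (`v_f = v_r` exactly at the
equilibrium concentration ratio `K_eq = k_f/k_r`) holds by construction
rather than by numerical cancellation. Units are fixed at mM and min;
conversion is the caller's job.

The dynamics are assembled in the Laplacian form
`dx/dt = −Z L(x) Exp(Zᵀ Ln x) + Z v_b(x)`. The complex monomials
`Exp(Zᵀ Ln x)` are computed as literal products `∏ x_i^{Z[i,α]}` with the
`0⁰ := 1` convention, which realizes the correct limit at states with
zero concentrations without evaluating `log(0)`. The identity between
this vertex form and the per-reaction edge form, `B v(x) = −L(x)
Exp(Zᵀ Ln x)`, is enforced by a property test at 1e-10 on random
networks; it is the main internal consistency check of the assembly.

Clamped species (external inputs such as an imposed extracellular
substrate) keep their value by zeroing their rows of the assembled
right-hand side; `Z` is left intact so that reduction operates on the
full complex structure. Boundary fluxes attach to complexes, not
species: a species-level inflow is expressed through its unimolecular
complex. Serializable boundary kinds are `constant`, `linear` (coef ×
one species, used for feeds proportional to a clamped input) and
`monomial` (coef × the complex monomial, a first-order drain).

## Rate-law catalogue

Each law is factored into `k` and a positive `d(x)`:

| kind | d(x) | k |
|---|---|---|
| mass_action | 1 | k |
| mm_irreversible | (1 + x/K)⁻¹ | V/K |
| mm_competitive | (1 + x/K + i/K_i)⁻¹ | V/K |
| mm_noncompetitive | ((1 + x/K)(1 + i/K_i))⁻¹ | V/K |
| mm_uncompetitive | (1 + (x/K)(1 + i/K_i))⁻¹ | V/K |
| rev_mm_halfreaction | ∏_sites (1 + Σ x/K)⁻¹, shared by both directions | k_f or k_r |
| hill | x^{n−1}/(1 + (x/K)ⁿ) | V/Kⁿ |
| custom_denominator | user callable | k |

The Hill factorization keeps the substrate complex at integer
stoichiometry (exponent 1 in the monomial) and absorbs `x^{n−1}` into
`d`, so `v = k·d·x = V xⁿ/(Kⁿ + xⁿ)` while the complex-graph machinery
sees an ordinary unimolecular complex; `d` remains positive on the open
orthant for any real `n ≥ 1`. Reversible mass action is the empty-site
limit of `rev_mm_halfreaction` (`d ≡ 1`), which keeps the two directions
linked through the shared denominator object. Modifier concentrations
may be network species or fixed numbers, resolved by id at construction.
`custom_denominator` accepts any callable but is excluded from
serialization and should pass `denominator_positivity_check`
(log-uniform sampling of the positive orthant over [1e-3, 1e3] per
coordinate) before a simulation is trusted, since positivity of `d` is
what makes the Laplacian weights nonnegative.

## Reduction

`schur_complement` eliminates the deleted block by a dense solve;
`c` is small in practice (≤ ~50), so no sparse path is provided. An L22
block with condition number above 1e12 raises, naming the deleted
complexes — this happens when a deleted complex has (numerically) no
outflow, so the balancing condition cannot determine its implied
monomial.

`ReducedNetwork` re-evaluates the parent Laplacian at every right-hand
side call and Schur-complements it at the current state: `L` depends on
the state through every `d_j`, so the complement cannot be frozen
without changing the model. The closed-form path (`CollapsedRateLaw`)
exists only for reversible-MM chain interiors, where the balancing
substitution gives an exact rational rate; its reduced constants are
obtained by expanding `k_f^II p1 + k_r^I p2` (intermediates frozen) with
sympy and normalizing the constant term to 1, not from hand-derived
closed forms. Numeric agreement with the direct substitution is tested
over random parameter sets at 1e-10.

Species elimination is decided structurally (integer rows of `Z1`),
never by floating-point tests. Frozen species keep their value inside
every saturation denominator of retained reactions as well — the same
rule the chain collapse applies to its `p1, p2` — and inside boundary
fluxes. During automated ranking the frozen values are the *original*
network's pre-event steady state at every greedy step; order
independence of the Schur reduction supports using one fixed reference
rather than re-deriving steady states of partially reduced models. The
API also accepts explicit frozen values for manual use.

Deletion classification (`classify_deletion`) is structural: an interior
of a reversible chain merges two reversible reactions into one (type 1),
a reversible/irreversible interior merges into one irreversible reaction
(type 2), a hub of degree > 2 completely couples its neighbors without
reducing reactions or parameters (type 3), a complex whose linkage class
is a single reversible pair removes that class entirely, and a deletion
whose removal splits the species-sharing structure of the reactions into
more independent groups is *disconnecting*. Disconnecting deletions are
refused by the automated procedure unless explicitly allowed: they
produce reduced models whose parts evolve independently and track the
original poorly. The disconnection test compares connected components of
the reaction graph (reactions linked when they share a species) before
and after the structural deletion; for the "after" graph the neighbors
of the deleted complex are taken as pairwise coupled, a slight
over-connection that can only under-report disconnection in exotic
irreversible topologies.

## Steady states and the error integral

`find_steady_state` integrates in doubling chunks until the right-hand
side is small, then polishes with bounded least squares over the
non-clamped species. The refinement is constrained to the conservation
manifold of the starting state (`gᵀx = gᵀx0` for every structural
moiety `g`, computed as the left null space of the dynamics image —
`[ZB, Z·boundary]` columns with clamped rows zeroed, or `Z1` for reduced
models); without the constraint the root polish can drift along the
manifold of a conservative network. Postcondition:
`‖rhs‖∞ ≤ 1e-9 · max(1, ‖x‖∞)`.

The error integral uses the absolute integrand `|1 − x^r/x^f|`; a signed
integrand could cancel opposite deviations and report spurious
agreement. Quadrature is trapezoidal on the union of the two adaptive
solver grids with linear interpolation; with solver tolerances
rtol 1e-8 / atol 1e-10 the quadrature error is orders of magnitude below
the 0.1 cutoff. `I` is dimensionless and invariant under rescaling of
concentration units. The greedy loop simulates the full model once per
scenario (cached), one reduced model per candidate, and stops at the
cutoff; all accepted steps satisfy `I ≤ cutoff`, but no monotonicity of
the minimum-`I` sequence is asserted — the method does not guarantee it.

Convergence times (95% of the concentration change between the two
steady states) are read off a dense trajectory grid, extending the
horizon by factors of 4 until the whole state is inside the 5% band;
species with no concentration change are reported as 0 and flagged.

## Fixtures and what they do (not) show

The generators produce the archetypes the reduction theory
distinguishes: the three-complex reversible-MM chain (closed, and driven
by a clamped feed species for perturbation scenarios), reversible
chains, a reversible/irreversible interior, a degree-3 star, the
species-bridged triple whose middle deletion is disconnecting, a
two-state pair with closed-form equilibrium, and seeded random enzymatic
networks (all-reversible connected complex graphs with mixed mass-action
/ MM kinetics and log-uniform parameters over one decade). Default chain
parameters make the interior step 50× faster than the ends, the regime
where complex balancing is accurate; the driven fixture's feed and drain
coefficients (0.05) keep turnover slow against that internal
equilibration. These fixtures exercise structure, exactness and
invariants at desk scale; they do not emulate the stiffness spread,
cofactor coupling or parameter correlations of genome-scale or published
pathway models, so passing tests certify the machinery, not reduction
quality on any particular real pathway. Full-size pathway models can be
supplied as SBML (catalogued kinds via the package annotation) or native
JSON and run through the same pipeline.

## Numerical choices

- LSODA by default (stiff-capable), rtol 1e-8, atol 1e-10; simulation of
  a model from the same state at fixed tolerances is reproducible on one
  machine.
- Negative concentrations: values above −1e-12 are clamped to 0 (and
  logged); larger excursions abort the run.
- Ranking ties on equal `I` break toward the lowest complex index, and
  complex ordering is insertion order of first appearance, so all
  matrices and traces are reproducible run to run.
- Everything in the pipeline is deterministic; random fixtures take
  explicit seeds.

## Known limitations

- QSSA-style elimination of individual species is deliberately not
  offered; complex balancing is the only reduction mode. The comparison
  is instructive: eliminating a species by QSSA generally requires
  solving quadratic/quartic equations and leaves non-enzyme-kinetic
  rates, whereas complex balancing stays within the rate-law catalogue.
- SBML import requires the package's rate-law annotation; arbitrary
  MathML kinetic laws are rejected by design rather than mis-factored.
- Closed-form collapsed laws exist only for reversible-MM chain
  interiors; all other reductions are evaluated through the
  state-dependent Schur complement.
- Error-bound precomputation (choosing the deletion set without
  simulation) is out of scope.
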