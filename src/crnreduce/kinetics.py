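"""Factored enzyme-kinetic rate laws.

Every unidirectional rate handled here is written as

    v_j(x) = d_j(x) * k_j * prod_i x_i^(Z_S)_i

i.e. a mass-action monomial over the substrate complex, scaled by a
proportionality constant k_j and a state-dependent factor d_j that is
strictly positive on the open positive orthant.  For mass action d_j = 1;
for Michaelis-Menten-type laws d_j is the reciprocal of the familiar
saturation denominator and k_j absorbs Vmax / (product of Michaelis
constants), e.g. the irreversible law V x/(K + x) = (V/K) * x / (1 + x/K)
has k = V/K and d = (1 + x/K)^-1.

The factorization is what makes the weighted-Laplacian form of the
dynamics possible: the edge weight of reaction j in the complex graph is
k_j * d_j(x), and the monomial is shared by all reactions leaving the
same substrate complex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "RateLaw",
    "Denominator",
    "SiteProductDenominator",
    "UncompetitiveDenominator",
    "HillDenominator",
    "CustomDenominator",
    "make_rate_law",
    "reversible_mm_pair",
    "eval_rate",
    "denominator_positivity_check",
    "RateLawError",
]

RATE_LAW_KINDS = (
    "mass_action",
    "rev_mm_halfreaction",
    "mm_irreversible",
    "mm_competitive",
    "mm_noncompetitive",
    "mm_uncompetitive",
    "hill",
    "custom_denominator",
)


class RateLawError(ValueError):
    """Missing, inconsistent or nonpositive rate-law parameters."""


def _require_positive(name: str, value: float) -> float:
    value = float(value)
    if not (value > 0) or not math.isfinite(value):
        raise RateLawError(f"parameter {name} must be positive and finite, got {value}")
    return value


# term reference: a species id (looked up in the state) or a fixed number
Ref = tuple[str, object]  # ("species", id) | ("const", value)


def _ref_value(ref: Ref, x: np.ndarray, index: Mapping[str, int]) -> float:
    tag, payload = ref
    if tag == "species":
        try:
            return float(x[index[payload]])
        except KeyError:
            raise RateLawError(f"modifier species {payload!r} unknown to the network") from None
    return float(payload)


class Denominator:
    """Base for the d_j factor; subclasses are positive on the open orthant
    (checked empirically by :func:`denominator_positivity_check`)."""

    def __call__(self, x: np.ndarray, index: Mapping[str, int]) -> float:
        raise NotImplementedError

    def n_parameters(self) -> int:
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError


@dataclass
class SiteProductDenominator(Denominator):
    """d(x) = 1 / prod_sites (1 + sum_terms v/K).

    Each site is a binding pocket: a list of (ref, K) competing terms.
    Covers the reversible MM half-reaction denominators (one site per
    substrate/product pair, as in p1(x) = (1 + x1/K1 + x3/K3)(1 + x2/K2 +
    x4/K4)), irreversible MM (one site, one term), and competitive /
    non-competitive modifiers.
    """

    sites: list[list[tuple[Ref, float]]]

    def __post_init__(self) -> None:
        for site in self.sites:
            for ref, K in site:
                _require_positive(f"K[{ref[1]}]", K)

    def __call__(self, x: np.ndarray, index: Mapping[str, int]) -> float:
        p = 1.0
        for site in self.sites:
            p *= 1.0 + sum(_ref_value(ref, x, index) / K for ref, K in site)
        return 1.0 / p

    def saturation(self, x: np.ndarray, index: Mapping[str, int]) -> float:
        """The denominator polynomial itself (1/d)."""
        return 1.0 / self(x, index)

    def n_parameters(self) -> int:
        return sum(len(site) for site in self.sites)

    def to_dict(self) -> dict:
        return {
            "form": "site_product",
            "sites": [[[list(ref), K] for ref, K in site] for site in self.sites],
        }


@dataclass
class UncompetitiveDenominator(Denominator):
    """d = (1 + (x_s/K)(1 + i/Ki))^-1: the modifier binds the ES complex only."""

    substrate: str
    K: float
    inhibitor: Ref
    Ki: float

    def __post_init__(self) -> None:
        _require_positive("K", self.K)
        _require_positive("Ki", self.Ki)

    def __call__(self, x: np.ndarray, index: Mapping[str, int]) -> float:
        s = float(x[index[self.substrate]])
        i = _ref_value(self.inhibitor, x, index)
        return 1.0 / (1.0 + (s / self.K) * (1.0 + i / self.Ki))

    def n_parameters(self) -> int:
        return 2

    def to_dict(self) -> dict:
        return {
            "form": "uncompetitive",
            "substrate": self.substrate,
            "K": self.K,
            "inhibitor": list(self.inhibitor),
            "Ki": self.Ki,
        }


@dataclass
class HillDenominator(Denominator):
    """Hill law V x^n/(K^n + x^n) factored with k = V/K^n:
    d = x^(n-1) / (1 + (x/K)^n), so v = k d x = V x^n/(K^n + x^n).

    The substrate complex keeps its integer stoichiometry (exponent 1 in
    the monomial); the extra x^(n-1) lives in d, which stays positive on
    the open orthant for any real n >= 1.
    """

    species: str
    K: float
    n: float

    def __post_init__(self) -> None:
        _require_positive("K", self.K)
        if self.n < 1:
            raise RateLawError(f"Hill exponent must be >= 1, got {self.n}")

    def __call__(self, x: np.ndarray, index: Mapping[str, int]) -> float:
        s = float(x[index[self.species]])
        if s == 0.0:
            # limit of x^(n-1)/(1+(x/K)^n): 1 when n == 1, 0 when n > 1
            return 1.0 if self.n == 1 else 0.0
        return s ** (self.n - 1.0) / (1.0 + (s / self.K) ** self.n)

    def n_parameters(self) -> int:
        return 2  # K and n

    def to_dict(self) -> dict:
        return {"form": "hill", "species": self.species, "K": self.K, "n": self.n}


@dataclass
class CustomDenominator(Denominator):
    """User-supplied d(x); must pass denominator_positivity_check before a
    simulation is trusted.  Not serializable."""

    fn: Callable[[np.ndarray, Mapping[str, int]], float]
    n_params: int = 0

    def __call__(self, x: np.ndarray, index: Mapping[str, int]) -> float:
        return float(self.fn(x, index))

    def n_parameters(self) -> int:
        return self.n_params

    def to_dict(self) -> dict:
        raise RateLawError("custom denominators are not serializable")


@dataclass
class RateLaw:
    """kind, proportionality constant k, and the positive factor d."""

    kind: str
    k: float
    denominator: Denominator | None = None  # None <=> d == 1 (mass action)
    params: dict = field(default_factory=dict)  # original named constants

    def __post_init__(self) -> None:
        if self.kind not in RATE_LAW_KINDS:
            raise RateLawError(f"unknown rate-law kind {self.kind!r}")
        _require_positive("k", self.k)

    def d(self, x: np.ndarray, index: Mapping[str, int]) -> float:
        return 1.0 if self.denominator is None else self.denominator(x, index)


def _as_ref(value) -> Ref:
    if isinstance(value, str):
        return ("species", value)
    return ("const", _require_positive("modifier concentration", value))


def make_rate_law(kind: str, **params) -> RateLaw:
    """Construct a catalogued rate law from named constants.

    mass_action: k.
    mm_irreversible: V, Km, substrate.
    mm_competitive: V, Km, substrate, Ki, inhibitor (species id or number).
    mm_noncompetitive / mm_uncompetitive: same parameters.
    hill: V, K, n, substrate.
    rev_mm_halfreaction: k, denominator (a shared SiteProductDenominator);
        use :func:`reversible_mm_pair` to build both directions at once.
    custom_denominator: k, fn(x, index), optionally n_params.
    """
    try:
        if kind == "mass_action":
            return RateLaw(kind, _require_positive("k", params["k"]), None, dict(params))
        if kind == "mm_irreversible":
            V, Km, s = params["V"], params["Km"], params["substrate"]
            den = SiteProductDenominator([[(("species", s), _require_positive("Km", Km))]])
            return RateLaw(kind, _require_positive("V", V) / Km, den, dict(params))
        if kind == "mm_competitive":
            V, Km, s = params["V"], params["Km"], params["substrate"]
            Ki, inh = params["Ki"], params["inhibitor"]
            den = SiteProductDenominator(
                [[(("species", s), _require_positive("Km", Km)),
                  (_as_ref(inh), _require_positive("Ki", Ki))]]
            )
            return RateLaw(kind, _require_positive("V", V) / Km, den, dict(params))
        if kind == "mm_noncompetitive":
            V, Km, s = params["V"], params["Km"], params["substrate"]
            Ki, inh = params["Ki"], params["inhibitor"]
            den = SiteProductDenominator(
                [[(("species", s), _require_positive("Km", Km))],
                 [(_as_ref(inh), _require_positive("Ki", Ki))]]
            )
            return RateLaw(kind, _require_positive("V", V) / Km, den, dict(params))
        if kind == "mm_uncompetitive":
            V, Km, s = params["V"], params["Km"], params["substrate"]
            den = UncompetitiveDenominator(s, Km, _as_ref(params["inhibitor"]), params["Ki"])
            return RateLaw(kind, _require_positive("V", V) / Km, den, dict(params))
        if kind == "hill":
            V, K, n, s = params["V"], params["K"], params["n"], params["substrate"]
            den = HillDenominator(s, K, n)
            return RateLaw(kind, _require_positive("V", V) / K ** n, den, dict(params))
        if kind == "rev_mm_halfreaction":
            den = params["denominator"]
            if not isinstance(den, Denominator):
                raise RateLawError("rev_mm_halfreaction needs a Denominator instance")
            return RateLaw(kind, _require_positive("k", params["k"]), den, {})
        if kind == "custom_denominator":
            den = CustomDenominator(params["fn"], int(params.get("n_params", 0)))
            return RateLaw(kind, _require_positive("k", params["k"]), den, {})
    except KeyError as e:
        raise RateLawError(f"rate law {kind!r}: missing parameter {e.args[0]!r}") from None
    raise RateLawError(f"unknown rate-law kind {kind!r}")


def reversible_mm_pair(
    kf: float,
    kr: float,
    sites: Sequence[Sequence[tuple[str, float]]],
) -> tuple[RateLaw, RateLaw]:
    """Forward and reverse half-reactions of a reversible MM reaction.

    `sites` lists the binding sites of the shared saturation denominator,
    each a sequence of (species_id, Km) terms mixing substrate and product
    species of that site, e.g. for X1+X2 <-> X3+X4:
    sites = [[("X1", K1), ("X3", K3)], [("X2", K2), ("X4", K4)]].

    Both directions reference one denominator object, so detailed balance
    v_f = v_r at the state where (prod of products)/(prod of substrates)
    equals K_eq = kf/kr holds identically.
    """
    den = SiteProductDenominator(
        [[(("species", s), K) for s, K in site] for site in sites]
    )
    fwd = make_rate_law("rev_mm_halfreaction", k=kf, denominator=den)
    rev = make_rate_law("rev_mm_halfreaction", k=kr, denominator=den)
    return fwd, rev


def eval_rate(
    law: RateLaw,
    Z_S: np.ndarray,
    x: np.ndarray,
    index: Mapping[str, int],
) -> float:
    """v = d(x) * k * prod_i x_i^(Z_S)_i, monomial evaluated with 0^0 := 1
    so the x -> 0 limit is taken correctly."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative concentration passed to eval_rate")
    mono = 1.0
    for i, e in enumerate(np.asarray(Z_S)):
        if e > 0:
            mono *= x[i] ** e
    if mono == 0.0:
        return 0.0
    return law.d(x, index) * law.k * mono


def denominator_positivity_check(
    law: RateLaw,
    species_ids: Sequence[str],
    n_samples: int = 1000,
    seed: int = 0,
    log_range: tuple[float, float] = (-3.0, 3.0),
) -> tuple[bool, np.ndarray | None]:
    """Sample the positive orthant log-uniformly and verify d(x) > 0 and
    finite everywhere; returns (ok, witness state or None)."""
    rng = np.random.default_rng(seed)
    index = {s: i for i, s in enumerate(species_ids)}
    lo, hi = log_range
    for _ in range(n_samples):
        x = 10.0 ** rng.uniform(lo, hi, size=len(species_ids))
        d = law.d(x, index)
        if not np.isfinite(d) or d <= 0:
            return False, x
    return True, None
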