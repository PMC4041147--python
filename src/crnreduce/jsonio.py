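"""Native JSON network description (full fidelity, bit-exact round trip).

Layout:
    {
      "name": str,
      "species": [{"id", "name", "x0", "fixed"}, ...],
      "complexes": [{species_id: coeff, ...}, ...],
      "denominators": [<denominator dict>, ...],   # shared, referenced by index
      "reactions": [{"substrate", "product", "kind", "k",
                     "denominator": index|null}, ...],
      "boundary_fluxes": {complex_index: {"kind", ...}, ...}
    }

Reversible pairs are preserved exactly because both directions reference
the same denominator entry.  A reduced model serializes as its parent
plus a "reduction" block (deleted complexes, frozen values, parent hash).
"""

from __future__ import annotations

import hashlib
import json
from typing import Union

from .kinetics import (
    Denominator,
    HillDenominator,
    RateLaw,
    RateLawError,
    SiteProductDenominator,
    UncompetitiveDenominator,
)
from .network import BoundaryFlux, Complex, ReactionNetwork, Reaction, Species
from .reduction import ReducedNetwork

__all__ = ["to_dict", "from_dict", "dumps", "loads", "write_json", "read_json"]


def _denominator_from_dict(d: dict) -> Denominator:
    form = d["form"]
    if form == "site_product":
        return SiteProductDenominator(
            [[(tuple(ref), float(K)) for ref, K in site] for site in d["sites"]]
        )
    if form == "uncompetitive":
        return UncompetitiveDenominator(d["substrate"], float(d["K"]),
                                        tuple(d["inhibitor"]), float(d["Ki"]))
    if form == "hill":
        return HillDenominator(d["species"], float(d["K"]), float(d["n"]))
    raise RateLawError(f"unknown denominator form {form!r}")


def to_dict(model: Union[ReactionNetwork, ReducedNetwork]) -> dict:
    if isinstance(model, ReducedNetwork):
        parent = to_dict(model.parent)
        parent["reduction"] = {
            "deleted": list(model.deleted),
            "frozen": {k: model.frozen[k] for k in sorted(model.frozen)},
            "parent_hash": hashlib.sha256(dumps_net(parent).encode()).hexdigest(),
        }
        return parent

    net = model
    dens: list[dict] = []
    den_index: dict[int, int] = {}
    reactions = []
    for rxn in net.reactions:
        d = rxn.rate_law.denominator
        if d is None:
            di = None
        elif id(d) in den_index:
            di = den_index[id(d)]
        else:
            di = den_index[id(d)] = len(dens)
            dens.append(d.to_dict())
        reactions.append({
            "substrate": rxn.substrate,
            "product": rxn.product,
            "kind": rxn.rate_law.kind,
            "k": rxn.rate_law.k,
            "denominator": di,
        })
    bfs = {}
    for alpha in sorted(net.boundary_fluxes):
        bf = net.boundary_fluxes[alpha]
        if bf.kind == "custom":
            raise RateLawError("custom boundary fluxes are not serializable")
        entry: dict = {"kind": bf.kind}
        if bf.kind == "constant":
            entry["value"] = bf.value
        else:
            entry["coef"] = bf.coef
            if bf.species is not None:
                entry["species"] = bf.species
        bfs[str(alpha)] = entry
    return {
        "name": net.name,
        "species": [{"id": s.id, "name": s.name, "x0": s.x0, "fixed": s.fixed}
                    for s in net.species],
        "complexes": [cx.as_map() for cx in net.complexes],
        "denominators": dens,
        "reactions": reactions,
        "boundary_fluxes": bfs,
    }


def from_dict(data: dict) -> Union[ReactionNetwork, ReducedNetwork]:
    species = [Species(d["id"], d.get("name", ""), float(d.get("x0", 0.0)),
                       bool(d.get("fixed", False))) for d in data["species"]]
    complexes = [Complex.from_map(cx) for cx in data["complexes"]]
    dens = [_denominator_from_dict(d) for d in data.get("denominators", [])]
    reactions = []
    for r in data["reactions"]:
        di = r.get("denominator")
        law = RateLaw(r["kind"], float(r["k"]), None if di is None else dens[di])
        reactions.append(Reaction(int(r["substrate"]), int(r["product"]), law))
    bfs = {}
    for key, entry in data.get("boundary_fluxes", {}).items():
        bfs[int(key)] = BoundaryFlux(entry["kind"], value=float(entry.get("value", 0.0)),
                                     coef=float(entry.get("coef", 0.0)),
                                     species=entry.get("species"))
    net = ReactionNetwork(species, complexes, reactions, bfs, name=data.get("name", ""))
    # re-annotate reversible pairs from shared denominators
    for i, ri in enumerate(net.reactions):
        if ri.reverse_of is not None:
            continue
        for j in range(i + 1, net.r):
            rj = net.reactions[j]
            if (rj.reverse_of is None and rj.substrate == ri.product
                    and rj.product == ri.substrate
                    and ri.rate_law.denominator is not None
                    and rj.rate_law.denominator is ri.rate_law.denominator):
                ri.reverse_of, rj.reverse_of = j, i
                break
    if "reduction" in data:
        red = data["reduction"]
        return ReducedNetwork(net, [int(i) for i in red["deleted"]],
                              {k: float(v) for k, v in red["frozen"].items()})
    return net


def dumps_net(data: dict) -> str:
    base = {k: v for k, v in data.items() if k != "reduction"}
    return json.dumps(base, sort_keys=True, separators=(",", ":"))


def dumps(model: Union[ReactionNetwork, ReducedNetwork]) -> str:
    return json.dumps(to_dict(model), indent=2, sort_keys=True)


def loads(text: str) -> Union[ReactionNetwork, ReducedNetwork]:
    return from_dict(json.loads(text))


def write_json(model: Union[ReactionNetwork, ReducedNetwork], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(dumps(model))
        fh.write("\n")


def read_json(path: str) -> Union[ReactionNetwork, ReducedNetwork]:
    with open(path) as fh:
        return loads(fh.read())
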