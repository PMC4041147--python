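"""SBML Level 3 import/export (catalogued rate-law subset).

Export writes a standard SBML L3v2 document: one compartment, one
species per network species (clamped species become boundary-condition
constants), one SBML reaction per directed edge with the full kinetic
rate as MathML.  Because no SBML kinetic-law vocabulary expresses the
factored (k, d) form directly, each reaction additionally carries an
annotation in the package namespace recording its kind, proportionality
constant and a reference into a model-level list of shared saturation
denominators; the model annotation also records complex ordering and
boundary fluxes.  Import reconstructs the network losslessly from these
annotations.  A document whose reactions lack the annotation (arbitrary
MathML) is rejected with an error naming the reaction: automatic
factorization of arbitrary rate expressions is out of scope.
"""

from __future__ import annotations

import json
import re
from typing import Union
from xml.sax.saxutils import escape, unescape

import libsbml

from .jsonio import _denominator_from_dict
from .kinetics import (
    HillDenominator,
    RateLaw,
    RateLawError,
    SiteProductDenominator,
    UncompetitiveDenominator,
)
from .network import BoundaryFlux, Complex, ReactionNetwork, Reaction, Species
from .reduction import ReducedNetwork

__all__ = ["read_sbml", "write_sbml", "SBMLError", "UnsupportedRateLawError"]

NS = "https://github.com/crnreduce/ns/level1"
_SID = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


class SBMLError(ValueError):
    pass


class UnsupportedRateLawError(SBMLError):
    pass


# -- formula rendering --------------------------------------------------------

def _mono(stoich: dict[str, int]) -> str:
    parts = [sid if n == 1 else f"{sid}^{n}" for sid, n in sorted(stoich.items())]
    return " * ".join(parts) if parts else "1"


def _ref_str(ref) -> str:
    tag, payload = ref
    return payload if tag == "species" else repr(float(payload))


def _rate_formula(law: RateLaw, substrate: Complex) -> str:
    mono = _mono(substrate.as_map())
    den = law.denominator
    if den is None:
        return f"{law.k!r} * {mono}"
    if isinstance(den, SiteProductDenominator):
        sites = [
            "(1 + " + " + ".join(f"{_ref_str(ref)}/{K!r}" for ref, K in site) + ")"
            for site in den.sites if site
        ]
        if not sites:
            return f"{law.k!r} * {mono}"
        return f"{law.k!r} * {mono} / ({' * '.join(sites)})"
    if isinstance(den, UncompetitiveDenominator):
        return (f"{law.k!r} * {mono} / (1 + ({den.substrate}/{den.K!r}) * "
                f"(1 + {_ref_str(den.inhibitor)}/{den.Ki!r}))")
    if isinstance(den, HillDenominator):
        s, K, n = den.species, den.K, den.n
        return f"{law.k!r} * {mono} * {s}^{n - 1.0!r} / (1 + ({s}/{K!r})^{n!r})"
    raise UnsupportedRateLawError(f"rate law kind {law.kind!r} has no SBML export")


# -- writing ------------------------------------------------------------------

def write_sbml(model: Union[ReactionNetwork, ReducedNetwork], path: str) -> None:
    red = model if isinstance(model, ReducedNetwork) else None
    net = red.parent if red is not None else model

    for s in net.species:
        if not _SID.match(s.id):
            raise SBMLError(f"species id {s.id!r} is not a valid SBML identifier")

    doc = libsbml.SBMLDocument(3, 2)
    m = doc.createModel()
    m.setId(net.name or "network")
    comp = m.createCompartment()
    comp.setId("cell")
    comp.setSize(1.0)
    comp.setConstant(True)

    for s in net.species:
        sp = m.createSpecies()
        sp.setId(s.id)
        if s.name:
            sp.setName(s.name)
        sp.setCompartment("cell")
        sp.setInitialConcentration(s.x0)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(bool(s.fixed))
        sp.setConstant(bool(s.fixed))

    dens: list[dict] = []
    den_index: dict[int, int] = {}
    for j, rxn in enumerate(net.reactions):
        r = m.createReaction()
        r.setId(f"R{j}")
        r.setReversible(False)
        for sid, n in net.complexes[rxn.substrate].stoich:
            ref = r.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(n))
            ref.setConstant(True)
        for sid, n in net.complexes[rxn.product].stoich:
            ref = r.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(n))
            ref.setConstant(True)
        kl = r.createKineticLaw()
        ast = libsbml.parseL3Formula(_rate_formula(rxn.rate_law, net.complexes[rxn.substrate]))
        if ast is None:  # pragma: no cover - formulas are generated
            raise SBMLError(f"could not render rate formula for reaction R{j}")
        kl.setMath(ast)

        d = rxn.rate_law.denominator
        if d is None:
            di = ""
        elif id(d) in den_index:
            di = str(den_index[id(d)])
        else:
            den_index[id(d)] = len(dens)
            dens.append(d.to_dict())
            di = str(den_index[id(d)])
        r.setAnnotation(
            f'<crn:rateLaw xmlns:crn="{NS}" kind="{rxn.rate_law.kind}" '
            f'k="{rxn.rate_law.k!r}" denominator="{di}"/>'
        )

    payload = {
        "name": net.name,
        "complexes": [cx.as_map() for cx in net.complexes],
        "denominators": dens,
        "boundary_fluxes": {
            str(a): (
                {"kind": bf.kind, "value": bf.value} if bf.kind == "constant"
                else {"kind": bf.kind, "coef": bf.coef, "species": bf.species}
            )
            for a, bf in sorted(net.boundary_fluxes.items())
        },
        "reactions": [{"substrate": r.substrate, "product": r.product}
                      for r in net.reactions],
    }
    if red is not None:
        payload["reduction"] = {"deleted": list(red.deleted),
                                "frozen": {k: red.frozen[k] for k in sorted(red.frozen)}}
    m.setAnnotation(
        f'<crn:network xmlns:crn="{NS}">'
        f"<crn:payload>{escape(json.dumps(payload, sort_keys=True))}</crn:payload>"
        f"</crn:network>"
    )

    if not libsbml.writeSBMLToFile(doc, path):
        raise SBMLError(f"could not write SBML to {path}")


# -- reading ------------------------------------------------------------------

def _find_node(node, name: str):
    if node is None:
        return None
    if node.getName() == name:
        return node
    for i in range(node.getNumChildren()):
        hit = _find_node(node.getChild(i), name)
        if hit is not None:
            return hit
    return None


def read_sbml(path: str) -> Union[ReactionNetwork, ReducedNetwork]:
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [doc.getError(i).getMessage()
                for i in range(doc.getNumErrors())
                if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR]
        raise SBMLError(f"malformed SBML file {path}: " + "; ".join(msgs))
    m = doc.getModel()
    if m is None:
        raise SBMLError(f"no model in {path}")

    payload_node = _find_node(m.getAnnotation(), "payload")
    if payload_node is None:
        raise UnsupportedRateLawError(
            "model lacks the factored rate-law annotation; arbitrary SBML "
            "kinetic laws cannot be factorized automatically"
        )
    text = "".join(payload_node.getChild(i).getCharacters()
                   for i in range(payload_node.getNumChildren()))
    payload = json.loads(unescape(text))

    species = []
    for i in range(m.getNumSpecies()):
        sp = m.getSpecies(i)
        species.append(Species(sp.getId(), sp.getName() or "",
                               float(sp.getInitialConcentration()),
                               bool(sp.getBoundaryCondition())))

    complexes = [Complex.from_map({k: int(v) for k, v in cx.items()})
                 for cx in payload["complexes"]]
    dens = [_denominator_from_dict(d) for d in payload["denominators"]]

    reactions = []
    for j in range(m.getNumReactions()):
        r = m.getReaction(j)
        node = _find_node(r.getAnnotation(), "rateLaw")
        if node is None:
            raise UnsupportedRateLawError(
                f"reaction {r.getId()!r} carries an unsupported kinetic law "
                "(no factored-rate-law annotation)"
            )
        kind = node.getAttrValue("kind")
        k = float(node.getAttrValue("k"))
        di = node.getAttrValue("denominator")
        den = dens[int(di)] if di != "" else None
        meta = payload["reactions"][j]
        law = RateLaw(kind, k, den)
        reactions.append(Reaction(int(meta["substrate"]), int(meta["product"]), law))

    bfs = {}
    for key, entry in payload.get("boundary_fluxes", {}).items():
        bfs[int(key)] = BoundaryFlux(entry["kind"], value=float(entry.get("value", 0.0)),
                                     coef=float(entry.get("coef", 0.0)),
                                     species=entry.get("species"))

    net = ReactionNetwork(species, complexes, reactions, bfs,
                          name=payload.get("name", m.getId()))
    for i, ri in enumerate(net.reactions):
        if ri.reverse_of is not None:
            continue
        for jj in range(i + 1, net.r):
            rj = net.reactions[jj]
            if (rj.reverse_of is None and rj.substrate == ri.product
                    and rj.product == ri.substrate
                    and ri.rate_law.denominator is not None
                    and rj.rate_law.denominator is ri.rate_law.denominator):
                ri.reverse_of, rj.reverse_of = jj, i
                break
    if "reduction" in payload:
        redblk = payload["reduction"]
        return ReducedNetwork(net, [int(i) for i in redblk["deleted"]],
                              {k: float(v) for k, v in redblk["frozen"].items()})
    return net
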