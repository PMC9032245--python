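"""SBML import and export (Level 3 Version 1 with the fbc package).

Reading accepts Level 2 or Level 3 documents with a single model;
species become compounds (charge and chemical formula from fbc
attributes when present), reactions carry stoichiometry, reversibility,
gene associations and flux bounds.  Kinetic laws are ignored.

Writing emits L3V1 + fbc v2.  Identifiers are sanitized to SBML-legal
symbols with a reversible escape table, and bookkeeping that SBML has no
slot for (pathways, provenance, database links, mock flags, registered
cofactor pairs) goes into structured notes, so a write/read round trip
reproduces the model content exactly.
"""

from __future__ import annotations

import json
import re
from fractions import Fraction
from typing import Iterable
from xml.sax.saxutils import escape as _xml_escape

import libsbml

from .gpr import Gpr
from .model import Compound, CofactorPair, Model, Reaction, Origin, formula_to_string, parse_formula

__all__ = ["SbmlError", "read_sbml", "write_sbml"]

_NOTES_MARK = "metanex:"
_LEGAL_BODY = re.compile(r"^[A-Za-z0-9_]+$")
_ESCAPE_SEQ = re.compile(r"_x([0-9A-Fa-f]{2})_|_u([0-9A-Fa-f]{4,6})_")


class SbmlError(RuntimeError):
    """Unreadable or structurally invalid SBML input."""


# ---------------------------------------------------------------------------
# id sanitization — reversible
# ---------------------------------------------------------------------------


def _encode_char(ch: str) -> str:
    cp = ord(ch)
    return f"_x{cp:02X}_" if cp < 256 else f"_u{cp:04X}_"


def sanitize_id(raw: str, kind: str) -> str:
    """Map an arbitrary id to an SBML SId: ``M_<id>`` when already legal,
    otherwise ``Mesc<escaped>`` with '_' and every illegal char escaped so
    decoding is unambiguous."""
    if _LEGAL_BODY.match(raw):
        return f"{kind}_{raw}"
    enc = "".join(
        ch if (ch.isascii() and (ch.isalnum())) else _encode_char(ch) for ch in raw
    )
    return f"{kind}esc{enc}"


def desanitize_id(sid: str, kind: str) -> str:
    """Invert :func:`sanitize_id`; foreign ids pass through unchanged
    apart from the conventional ``M_``/``R_``/``G_`` prefix strip."""
    if sid.startswith(f"{kind}esc"):
        body = sid[len(kind) + 3 :]
        return _ESCAPE_SEQ.sub(
            lambda m: chr(int(m.group(1) or m.group(2), 16)), body
        )
    if sid.startswith(f"{kind}_"):
        return sid[len(kind) + 1 :]
    return sid


# ---------------------------------------------------------------------------
# structured notes
# ---------------------------------------------------------------------------


def _notes_xml(payload: dict) -> str:
    blob = _xml_escape(_NOTES_MARK + json.dumps(payload, sort_keys=True))
    return (
        '<body xmlns="http://www.w3.org/1999/xhtml">'
        f"<p>{blob}</p></body>"
    )


def _parse_notes(node) -> dict:
    if node is None:
        return {}
    text = node.toXMLString() if hasattr(node, "toXMLString") else str(node)
    idx = text.find(_NOTES_MARK)
    if idx < 0:
        return {}
    # notes were XML-escaped on write; undo the relevant entities
    tail = text[idx + len(_NOTES_MARK) :]
    end = tail.find("</p>")
    raw = tail[:end] if end >= 0 else tail
    raw = raw.replace("&lt;", "<").replace("&gt;", ">").replace("&quot;", '"').replace("&amp;", "&")
    try:
        return json.loads(raw)
    except json.JSONDecodeError:
        return {}


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _check(call_result, what: str) -> None:
    if call_result is None:
        raise SbmlError(f"libsbml failed: {what}")
    if isinstance(call_result, int) and call_result != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise SbmlError(f"libsbml error {call_result} during: {what}")


def _build_association(parent, node) -> None:
    """Recursively mirror a GPR tree into fbc association objects."""
    if isinstance(node, str):
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(sanitize_id(node, "G"))
        return
    op, children = node
    grp = parent.createAnd() if op == "and" else parent.createOr()
    for child in children:
        _build_association(grp, child)


def write_sbml(model: Model, path: str) -> None:
    """Serialize a model as SBML L3V1 with the fbc v2 package."""
    model.check_integrity()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId("metanex_model")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(False)
    sm.setNotes(
        _notes_xml(
            {
                "namespace": model.namespace,
                "cofactor_pairs": [[p.donor, p.acceptor] for p in model.cofactor_pairs],
                "free_notes": model.notes,
            }
        )
    )

    compartments: dict[str, None] = {}
    for c in model.compounds.values():
        compartments.setdefault(c.compartment or "c", None)
    for comp_id in sorted(compartments):
        comp = sm.createCompartment()
        comp.setId(sanitize_id(comp_id, "C"))
        comp.setConstant(True)

    for cid in sorted(model.compounds):
        c = model.compounds[cid]
        sp = sm.createSpecies()
        sp.setId(sanitize_id(cid, "M"))
        if c.name:
            sp.setName(c.name)
        sp.setCompartment(sanitize_id(c.compartment or "c", "C"))
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        splug = sp.getPlugin("fbc")
        if c.charge is not None:
            splug.setCharge(int(c.charge))
        if c.formula is not None:
            splug.setChemicalFormula(formula_to_string(c.formula))
        extras: dict = {}
        if c.is_mock:
            extras["is_mock"] = True
        if c.database_links:
            extras["database_links"] = {k: sorted(v) for k, v in sorted(c.database_links.items())}
        if c.compartment is None:
            extras["compartment_default"] = True
        if extras:
            sp.setNotes(_notes_xml(extras))

    genes: set[str] = set()
    for r in model.reactions.values():
        genes.update(r.gpr.genes())
    for gene in sorted(genes):
        gp = mplug.createGeneProduct()
        gp.setId(sanitize_id(gene, "G"))
        gp.setLabel(gene)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"bnd_{len(bound_params)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(float(value))
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rid in sorted(model.reactions):
        r = model.reactions[rid]
        rx = sm.createReaction()
        rx.setId(sanitize_id(rid, "R"))
        rx.setReversible(bool(r.reversible))
        rx.setFast(False)
        for cid, coeff in sorted(r.stoichiometry.items()):
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(sanitize_id(cid, "M"))
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        lo, hi = r.bounds if r.bounds is not None else ((-1000.0, 1000.0) if r.reversible else (0.0, 1000.0))
        rplug.setLowerFluxBound(bound_param(lo))
        rplug.setUpperFluxBound(bound_param(hi))
        if not r.gpr.is_empty:
            gpa = rplug.createGeneProductAssociation()
            _build_association(gpa, r.gpr._root)
        extras = {"origin": r.origin.value}
        if r.pathways:
            extras["pathways"] = sorted(r.pathways)
        if r.database_links:
            extras["database_links"] = {k: sorted(v) for k, v in sorted(r.database_links.items())}
        if r.bounds is None:
            extras["bounds_default"] = True
        rx.setNotes(_notes_xml(extras))

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise SbmlError(f"could not write SBML to {path!r}")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _snap(value: float) -> float:
    """Undo the precision loss of XML double serialization.

    Stoichiometric coefficients are small rationals (integers, biomass
    fractions, mass-splitting ratios); 15 significant digits identify a
    rational with denominator <= 1e6 uniquely, so snapping recovers the
    exact coefficient that was written.
    """
    if value == 0 or value != value:
        return value
    return float(Fraction(value).limit_denominator(10**6))


def _gpr_from_association(assoc, gene_names: dict[str, str]) -> Gpr:
    if assoc is None:
        return Gpr.empty()
    if isinstance(assoc, libsbml.GeneProductRef):
        gid = assoc.getGeneProduct()
        return Gpr.gene(gene_names.get(gid, desanitize_id(gid, "G")))
    parts = [
        _gpr_from_association(assoc.getAssociation(i), gene_names)
        for i in range(assoc.getNumAssociations())
    ]
    if isinstance(assoc, libsbml.FbcAnd):
        return Gpr.all_of(parts)
    if isinstance(assoc, libsbml.FbcOr):
        return Gpr.any_of(parts)
    raise SbmlError(f"unsupported gene association node: {type(assoc).__name__}")


def _infer_namespace(compound_ids: Iterable[str]) -> str:
    ids = [c for c in compound_ids]
    if not ids:
        return "other"
    bigg = sum(1 for c in ids if re.match(r"^[a-z0-9_]+_[a-zA-Z]{1,2}$", c))
    metacyc = sum(1 for c in ids if re.match(r"^[A-Z][A-Z0-9+.-]*$", c))
    if bigg >= 0.8 * len(ids):
        return "bigg"
    if metacyc >= 0.8 * len(ids):
        return "metacyc"
    return "other"


def read_sbml(path: str) -> Model:
    """Read an SBML L2/L3 document into a model.

    fbc charge/formula/GPR/bounds are used when present; kinetic laws are
    ignored.  A reaction referencing a species missing from the listOfSpecies
    is an error.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise SbmlError(f"unparsable SBML {path!r}: {msgs[:3]}")
    sm = doc.getModel()
    if sm is None:
        raise SbmlError(f"no model element in {path!r}")

    model_meta = _parse_notes(sm.getNotes())

    compounds: dict[str, Compound] = {}
    sid_to_cid: dict[str, str] = {}
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        cid = desanitize_id(sp.getId(), "M")
        extras = _parse_notes(sp.getNotes())
        charge = None
        formula = None
        splug = sp.getPlugin("fbc")
        if splug is not None:
            if splug.isSetCharge():
                charge = int(splug.getCharge())
            if splug.isSetChemicalFormula() and splug.getChemicalFormula():
                formula = parse_formula(splug.getChemicalFormula())
        elif sp.isSetCharge():  # SBML L2 carries charge on the species
            charge = int(sp.getCharge())
        compartment = desanitize_id(sp.getCompartment(), "C") if sp.isSetCompartment() else None
        if extras.get("compartment_default"):
            compartment = None
        compounds[cid] = Compound(
            id=cid,
            name=sp.getName() or None,
            formula=formula,
            charge=charge,
            compartment=compartment,
            database_links={k: list(v) for k, v in extras.get("database_links", {}).items()},
            is_mock=bool(extras.get("is_mock", False)),
        )
        sid_to_cid[sp.getId()] = cid

    gene_names: dict[str, str] = {}
    mplug = sm.getPlugin("fbc")
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_names[gp.getId()] = gp.getLabel() or desanitize_id(gp.getId(), "G")

    def param_value(pid: str) -> float | None:
        par = sm.getParameter(pid)
        return par.getValue() if par is not None else None

    reactions: list[Reaction] = []
    for i in range(sm.getNumReactions()):
        rx = sm.getReaction(i)
        rid = desanitize_id(rx.getId(), "R")
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            if ref.getSpecies() not in sid_to_cid:
                raise SbmlError(f"reaction {rid!r} references missing species {ref.getSpecies()!r}")
            cid = sid_to_cid[ref.getSpecies()]
            stoich[cid] = stoich.get(cid, 0.0) - _snap(float(ref.getStoichiometry()))
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            if ref.getSpecies() not in sid_to_cid:
                raise SbmlError(f"reaction {rid!r} references missing species {ref.getSpecies()!r}")
            cid = sid_to_cid[ref.getSpecies()]
            stoich[cid] = stoich.get(cid, 0.0) + _snap(float(ref.getStoichiometry()))
        stoich = {c: v for c, v in stoich.items() if v != 0}
        if not stoich:
            continue  # fully catalytic / empty reaction carries no topology
        extras = _parse_notes(rx.getNotes())
        gpr = Gpr.empty()
        bounds: tuple[float, float] | None = None
        rplug = rx.getPlugin("fbc")
        if rplug is not None:
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None:
                gpr = _gpr_from_association(gpa.getAssociation(), gene_names)
            if rplug.isSetLowerFluxBound() and rplug.isSetUpperFluxBound():
                lo = param_value(rplug.getLowerFluxBound())
                hi = param_value(rplug.getUpperFluxBound())
                if lo is not None and hi is not None:
                    bounds = (lo, hi)
        if extras.get("bounds_default"):
            bounds = None
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                reversible=bool(rx.getReversible()),
                gpr=gpr,
                pathways=set(extras.get("pathways", [])),
                database_links={k: list(v) for k, v in extras.get("database_links", {}).items()},
                bounds=bounds,
                origin=Origin(extras.get("origin", "base")),
            )
        )

    namespace = model_meta.get("namespace") or _infer_namespace(compounds)
    pairs = [CofactorPair(d, a) for d, a in model_meta.get("cofactor_pairs", [])]
    return Model(
        compounds=compounds.values(),
        reactions=reactions,
        cofactor_pairs=pairs,
        namespace=namespace,
        notes=model_meta.get("free_notes", ""),
    )
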