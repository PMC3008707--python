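"""SBML serialisation for the supported model subset.

Writes SBML Level 3 Version 1 core with MIRIAM-style controlled-vocabulary
annotations (identifiers.org URIs) and MathML kinetic laws; reads Level 2
and Level 3 documents back, normalising legacy ``urn:miriam`` URIs.
Unsupported constructs (events, rules, function definitions, constraints)
raise :class:`UnsupportedFeatureError` naming the construct.

libsbml does the XML heavy lifting; this module maps between the package's
domain types and libsbml's object model.
"""

from __future__ import annotations

from fractions import Fraction

import libsbml

from .expr import parse_expression, to_infix
from .model import (
    Annotation,
    Compartment,
    KineticLaw,
    Model,
    Parameter,
    Reaction,
    Species,
    Violation,
    normalise_uri,
    validate_model,
)

__all__ = ["write_sbml", "read_sbml", "UnsupportedFeatureError", "InvalidModelError"]


class UnsupportedFeatureError(ValueError):
    """Document uses an SBML construct outside the supported subset."""


class InvalidModelError(ValueError):
    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__("; ".join(str(v) for v in violations))


_QUAL_TO_BQB = {
    "is": libsbml.BQB_IS,
    "isVersionOf": libsbml.BQB_IS_VERSION_OF,
    "hasPart": libsbml.BQB_HAS_PART,
    "isPartOf": libsbml.BQB_IS_PART_OF,
    "isHomologTo": libsbml.BQB_IS_HOMOLOG_TO,
    "isDescribedBy": libsbml.BQB_IS_DESCRIBED_BY,
    "isEncodedBy": libsbml.BQB_IS_ENCODED_BY,
    "encodes": libsbml.BQB_ENCODES,
    "occursIn": libsbml.BQB_OCCURS_IN,
    "hasProperty": libsbml.BQB_HAS_PROPERTY,
}
_BQB_TO_QUAL = {v: k for k, v in _QUAL_TO_BQB.items()}

# SBO terms distinguishing metabolite from enzyme species
_SBO_METABOLITE = 247  # simple chemical
_SBO_ENZYME = 252  # polypeptide chain

# package unit tag <-> SBML unit-definition id
_UNIT_IDS = {"mM": "mM", "mM/s": "mM_per_s", "1/s": "per_s", "s": "second",
             "dimensionless": "dimensionless"}
_IDS_UNIT = {v: k for k, v in _UNIT_IDS.items()}


def _add_unit_definitions(sm: libsbml.Model) -> None:
    def unit(ud, kind, exponent, scale=0, multiplier=1.0):
        u = ud.createUnit()
        u.setKind(kind)
        u.setExponent(exponent)
        u.setScale(scale)
        u.setMultiplier(multiplier)

    ud = sm.createUnitDefinition()
    ud.setId("mM")
    unit(ud, libsbml.UNIT_KIND_MOLE, 1, -3)
    unit(ud, libsbml.UNIT_KIND_LITRE, -1)

    ud = sm.createUnitDefinition()
    ud.setId("mM_per_s")
    unit(ud, libsbml.UNIT_KIND_MOLE, 1, -3)
    unit(ud, libsbml.UNIT_KIND_LITRE, -1)
    unit(ud, libsbml.UNIT_KIND_SECOND, -1)

    ud = sm.createUnitDefinition()
    ud.setId("per_s")
    unit(ud, libsbml.UNIT_KIND_SECOND, -1)

    sm.setTimeUnits("second")
    sm.setSubstanceUnits("mole")
    sm.setExtentUnits("mole")
    sm.setVolumeUnits("litre")


def _attach_annotations(element, meta_id: str, annotations: list[Annotation]) -> None:
    if not annotations:
        return
    element.setMetaId(meta_id)
    by_qual: dict[str, list[str]] = {}
    for a in annotations:
        by_qual.setdefault(a.qualifier, []).append(a.resource_uri)
    for qual, uris in by_qual.items():
        cv = libsbml.CVTerm()
        cv.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
        cv.setBiologicalQualifierType(_QUAL_TO_BQB[qual])
        seen = set()
        for uri in uris:
            if uri not in seen:  # no URI duplicated within a block
                cv.addResource(uri)
                seen.add(uri)
        element.addCVTerm(cv)


def _read_annotations(element) -> list[Annotation]:
    out: list[Annotation] = []
    for i in range(element.getNumCVTerms()):
        cv = element.getCVTerm(i)
        if cv.getQualifierType() != libsbml.BIOLOGICAL_QUALIFIER:
            continue
        qual = _BQB_TO_QUAL.get(cv.getBiologicalQualifierType())
        if qual is None:
            continue
        for j in range(cv.getNumResources()):
            out.append(Annotation(qual, normalise_uri(cv.getResourceURI(j))))
    return out


def _set_parameter_units(p, tag: str) -> None:
    uid = _UNIT_IDS.get(tag)
    if uid is not None:
        p.setUnits(uid)


def _get_parameter_units(p) -> str:
    if p.isSetUnits():
        return _IDS_UNIT.get(p.getUnits(), p.getUnits())
    return "dimensionless"


def write_sbml(model: Model) -> str:
    """Serialise a validated model to an SBML L3V1 document string."""
    violations = validate_model(model)
    if violations:
        raise InvalidModelError(violations)

    doc = libsbml.SBMLDocument(3, 1)
    sm = doc.createModel()
    sm.setId(model.id)
    if model.name:
        sm.setName(model.name)
    _add_unit_definitions(sm)

    for c in model.compartments:
        sc = sm.createCompartment()
        sc.setId(c.id)
        if c.name:
            sc.setName(c.name)
        sc.setConstant(True)
        sc.setSize(1.0)
        sc.setSpatialDimensions(3)
        sc.setUnits("litre")
        _attach_annotations(sc, f"meta_{c.id}", c.annotations)

    for s in model.species:
        ss = sm.createSpecies()
        ss.setId(s.id)
        if s.name:
            ss.setName(s.name)
        ss.setCompartment(s.compartment_ref)
        ss.setHasOnlySubstanceUnits(False)
        ss.setBoundaryCondition(s.boundary)
        ss.setConstant(False)
        ss.setSBOTerm(_SBO_ENZYME if s.role_hint == "enzyme" else _SBO_METABOLITE)
        if s.initial_concentration is not None:
            ss.setInitialConcentration(s.initial_concentration)
        ss.setSubstanceUnits("mole")
        _attach_annotations(ss, f"meta_{s.id}", s.annotations)

    for p in model.global_parameters:
        sp = sm.createParameter()
        sp.setId(p.id)
        sp.setValue(p.value)
        sp.setConstant(True)
        _set_parameter_units(sp, p.units)

    for r in model.reactions:
        sr = sm.createReaction()
        sr.setId(r.id)
        if r.name:
            sr.setName(r.name)
        sr.setReversible(r.reversible)
        sr.setFast(False)
        for sid, stoich in r.reactants:
            ref = sr.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(stoich))
            ref.setConstant(True)
        for sid, stoich in r.products:
            ref = sr.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(stoich))
            ref.setConstant(True)
        for sid in r.modifiers:
            ref = sr.createModifier()
            ref.setSpecies(sid)
        _attach_annotations(sr, f"meta_{r.id}", r.annotations)
        if r.kinetic_law is not None:
            kl = sr.createKineticLaw()
            ast = libsbml.parseL3Formula(to_infix(r.kinetic_law.expression))
            if ast is None:  # pragma: no cover - parser emits valid infix
                raise ValueError(f"cannot serialise rate law of {r.id}")
            kl.setMath(ast)
            for lp in r.kinetic_law.local_parameters:
                slp = kl.createLocalParameter()
                slp.setId(lp.id)
                slp.setValue(lp.value)
                _set_parameter_units(slp, lp.units)
            kl.setNotes(
                "<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>provenance: {r.kinetic_law.provenance}</p></body>"
            )
    return libsbml.writeSBMLToString(doc)


def _check_unsupported(sm: libsbml.Model) -> None:
    for attr, label in (
        ("getNumEvents", "event"),
        ("getNumRules", "rule"),
        ("getNumFunctionDefinitions", "functionDefinition"),
        ("getNumConstraints", "constraint"),
        ("getNumInitialAssignments", "initialAssignment"),
    ):
        if getattr(sm, attr)() > 0:
            raise UnsupportedFeatureError(
                f"SBML construct {label!r} is not supported"
            )


def _provenance_from_notes(kl) -> str:
    if kl.isSetNotes():
        text = kl.getNotesString()
        for tag in ("matched", "fallback_mass_action", "user"):
            if f"provenance: {tag}" in text:
                return tag
    return "user"


def read_sbml(text: str) -> Model:
    """Parse an SBML document (L2 or L3) into a :class:`Model`."""
    doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise ValueError(f"SBML parse error: {err.getMessage().strip()}")
    sm = doc.getModel()
    if sm is None:
        raise ValueError("document contains no model")
    _check_unsupported(sm)

    model = Model(id=sm.getId() or "model", name=sm.getName() or "")

    for i in range(sm.getNumCompartments()):
        sc = sm.getCompartment(i)
        model.compartments.append(
            Compartment(sc.getId(), sc.getName() or "", _read_annotations(sc))
        )

    for i in range(sm.getNumSpecies()):
        ss = sm.getSpecies(i)
        role = "enzyme" if ss.getSBOTerm() == _SBO_ENZYME else "metabolite"
        conc = ss.getInitialConcentration() if ss.isSetInitialConcentration() else None
        model.species.append(Species(
            id=ss.getId(),
            name=ss.getName() or "",
            compartment_ref=ss.getCompartment(),
            role_hint=role,
            initial_concentration=conc,
            boundary=ss.getBoundaryCondition(),
            annotations=_read_annotations(ss),
        ))

    for i in range(sm.getNumParameters()):
        sp = sm.getParameter(i)
        model.global_parameters.append(
            Parameter(sp.getId(), sp.getValue(), _get_parameter_units(sp), "global")
        )

    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        rxn = Reaction(
            id=sr.getId(),
            name=sr.getName() or "",
            reversible=sr.getReversible(),
            annotations=_read_annotations(sr),
        )
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            rxn.reactants.append((
                ref.getSpecies(),
                Fraction(ref.getStoichiometry()).limit_denominator(10 ** 6),
            ))
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            rxn.products.append((
                ref.getSpecies(),
                Fraction(ref.getStoichiometry()).limit_denominator(10 ** 6),
            ))
        for j in range(sr.getNumModifiers()):
            rxn.modifiers.append(sr.getModifier(j).getSpecies())
        if sr.isSetKineticLaw():
            kl = sr.getKineticLaw()
            formula = libsbml.formulaToL3String(kl.getMath())
            locals_ = [
                Parameter(
                    kl.getLocalParameter(j).getId(),
                    kl.getLocalParameter(j).getValue(),
                    _get_parameter_units(kl.getLocalParameter(j)),
                    "local",
                )
                for j in range(kl.getNumLocalParameters())
            ] or [
                # L2 documents use plain parameters inside kineticLaw
                Parameter(kl.getParameter(j).getId(), kl.getParameter(j).getValue(),
                          _get_parameter_units(kl.getParameter(j)), "local")
                for j in range(kl.getNumParameters())
            ]
            rxn.kinetic_law = KineticLaw(
                expression=parse_expression(formula),
                local_parameters=locals_,
                provenance=_provenance_from_notes(kl),
            )
        model.reactions.append(rxn)
    return model


def validate_document(text: str) -> int:
    """Run libsbml's full consistency check; return the number of errors."""
    doc = libsbml.readSBMLFromString(text)
    n = doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR)
    if n:
        return n
    doc.checkConsistency()
    return doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR)
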