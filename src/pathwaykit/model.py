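"""Domain types for a MIRIAM-annotated kinetic model.

A :class:`Model` holds compartments, species, reactions and global
parameters, each of which may carry controlled-vocabulary annotations
(cross-references to ChEBI, UniProt, SGD, GO, EC ... records).  A model
whose reactions all carry kinetic laws is *quantitative*; one without any
kinetic laws is *qualitative* — the raw output of network assembly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional

from . import units
from .expr import MathExpression, names_in

__all__ = [
    "Annotation",
    "Compartment",
    "Species",
    "Parameter",
    "KineticLaw",
    "Reaction",
    "Model",
    "Violation",
    "validate_model",
    "sanitize_id",
]

QUALIFIERS = frozenset({
    "is", "isVersionOf", "hasPart", "isPartOf", "isHomologTo",
    "isDescribedBy", "isEncodedBy", "encodes", "occursIn", "hasProperty",
})

_URI_RE = re.compile(
    r"^(?:https?://identifiers\.org/(?P<ns>[^/]+)/(?P<acc>.+)"
    r"|urn:miriam:(?P<ns2>[^:]+):(?P<acc2>.+))$"
)


@dataclass(frozen=True)
class Annotation:
    """A MIRIAM-style cross-reference: qualifier + database record URI."""

    qualifier: str
    resource_uri: str

    def __post_init__(self) -> None:
        if self.qualifier not in QUALIFIERS:
            raise ValueError(f"unknown annotation qualifier {self.qualifier!r}")
        if not self.resource_uri or self.parse_uri() is None:
            raise ValueError(f"unparseable resource URI {self.resource_uri!r}")

    def parse_uri(self) -> Optional[tuple[str, str]]:
        """Split the URI into (namespace, accession), or None."""
        m = _URI_RE.match(self.resource_uri)
        if m is None:
            return None
        ns = m.group("ns") or m.group("ns2")
        acc = m.group("acc") or m.group("acc2")
        return ns, acc

    @property
    def accession(self) -> str:
        parsed = self.parse_uri()
        assert parsed is not None
        return parsed[1]

    @property
    def namespace(self) -> str:
        parsed = self.parse_uri()
        assert parsed is not None
        return parsed[0]


def identifiers_org_uri(namespace: str, accession: str) -> str:
    """Canonical identifiers.org URI for a database record."""
    return f"https://identifiers.org/{namespace}/{accession}"


def normalise_uri(uri: str) -> str:
    """Rewrite a legacy ``urn:miriam:`` URI to identifiers.org form."""
    m = _URI_RE.match(uri)
    if m and m.group("ns2"):
        return identifiers_org_uri(m.group("ns2"), m.group("acc2"))
    return uri


@dataclass
class Compartment:
    id: str
    name: str = ""
    annotations: list[Annotation] = field(default_factory=list)


@dataclass
class Species:
    id: str
    name: str = ""
    compartment_ref: str = ""
    role_hint: str = "metabolite"  # metabolite | enzyme
    initial_concentration: Optional[float] = None  # package concentration unit
    boundary: bool = False  # clamped during simulation
    annotations: list[Annotation] = field(default_factory=list)

    def accessions(self, namespace: Optional[str] = None) -> list[str]:
        """Annotation accessions, optionally restricted to one namespace."""
        out = []
        for a in self.annotations:
            parsed = a.parse_uri()
            if parsed and (namespace is None or parsed[0] == namespace):
                out.append(parsed[1])
        return out


@dataclass
class Parameter:
    id: str
    value: float
    units: str = "dimensionless"
    scope: str = "global"  # global | local


@dataclass
class KineticLaw:
    expression: MathExpression
    local_parameters: list[Parameter] = field(default_factory=list)
    provenance: str = "user"  # matched | fallback_mass_action | user


@dataclass
class Reaction:
    id: str
    name: str = ""
    reactants: list[tuple[str, Fraction]] = field(default_factory=list)
    products: list[tuple[str, Fraction]] = field(default_factory=list)
    modifiers: list[str] = field(default_factory=list)
    reversible: bool = True
    kinetic_law: Optional[KineticLaw] = None
    annotations: list[Annotation] = field(default_factory=list)


@dataclass
class Model:
    id: str
    name: str = ""
    compartments: list[Compartment] = field(default_factory=list)
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    global_parameters: list[Parameter] = field(default_factory=list)
    concentration_unit: str = units.CONCENTRATION_UNIT
    time_unit: str = units.TIME_UNIT

    # -- lookup helpers -------------------------------------------------
    def species_by_id(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def reaction_by_id(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def species_ids(self) -> set[str]:
        return {s.id for s in self.species}

    def is_quantitative(self) -> bool:
        """True when every reaction carries a kinetic law."""
        return bool(self.reactions) and all(
            r.kinetic_law is not None for r in self.reactions
        )


@dataclass(frozen=True)
class Violation:
    kind: str  # duplicate_id | dangling_ref | negative_value | unresolved_name | missing_annotation | bad_stoichiometry
    where: str  # entity id or path
    detail: str

    def __str__(self) -> str:
        return f"[{self.kind}] {self.where}: {self.detail}"


def _dupes(ids: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    d: set[str] = set()
    for i in ids:
        if i in seen:
            d.add(i)
        seen.add(i)
    return d


def validate_model(model: Model) -> list[Violation]:
    """Check every structural invariant; returns one record per breach.

    Total: never raises, and an empty list means the model is well-formed.
    """
    out: list[Violation] = []
    comp_ids = [c.id for c in model.compartments]
    sp_ids = [s.id for s in model.species]
    rxn_ids = [r.id for r in model.reactions]
    par_ids = [p.id for p in model.global_parameters]

    for coll, ids in (("compartment", comp_ids), ("species", sp_ids),
                      ("reaction", rxn_ids), ("parameter", par_ids)):
        for d in sorted(_dupes(ids)):
            out.append(Violation("duplicate_id", d, f"duplicate {coll} id"))

    comp_set, sp_set = set(comp_ids), set(sp_ids)
    global_names = set(par_ids) | sp_set

    for s in model.species:
        if s.compartment_ref not in comp_set:
            out.append(Violation("dangling_ref", s.id,
                                 f"compartment {s.compartment_ref!r} not found"))
        if s.initial_concentration is not None and s.initial_concentration < 0:
            out.append(Violation("negative_value", s.id,
                                 f"initial concentration {s.initial_concentration}"))

    for r in model.reactions:
        reactant_ids = {sid for sid, _ in r.reactants}
        product_ids = {sid for sid, _ in r.products}
        for sid, stoich in list(r.reactants) + list(r.products):
            if sid not in sp_set:
                out.append(Violation("dangling_ref", r.id,
                                     f"species {sid!r} not found"))
            if stoich <= 0:
                out.append(Violation("bad_stoichiometry", r.id,
                                     f"stoichiometry {stoich} for {sid}"))
        overlap = reactant_ids & product_ids
        if overlap:
            out.append(Violation("bad_stoichiometry", r.id,
                                 f"species on both sides: {sorted(overlap)}"))
        for sid in r.modifiers:
            if sid not in sp_set:
                out.append(Violation("dangling_ref", r.id,
                                     f"modifier {sid!r} not found"))
        if r.kinetic_law is not None:
            local = {p.id for p in r.kinetic_law.local_parameters}
            for nm in sorted(names_in(r.kinetic_law.expression)):
                if nm not in local and nm not in global_names and nm != "time":
                    out.append(Violation("unresolved_name", r.id,
                                         f"kinetic-law name {nm!r} unresolved"))
    return out


_ID_SANITIZE = re.compile(r"[^A-Za-z0-9_]")


def sanitize_id(raw: str, prefix: str = "") -> str:
    """Deterministic SBML-safe id: prefix + raw with non-word chars -> '_'."""
    core = _ID_SANITIZE.sub("_", raw)
    if not core or core[0].isdigit():
        core = "_" + core
    return prefix + core
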