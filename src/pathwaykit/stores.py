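"""Kinetics and concentration stores, and identifier-set reaction matching.

The kinetics store emulates an enzyme-kinetics database (SABIO-RK style):
each entry carries a rate-law expression over metabolite accessions plus
parameter values, keyed by a :class:`ReactionSignature` — the multisets of
reactant and product ChEBI accessions and the set of modifier (enzyme)
UniProt accessions.  The key-results store holds measured starting
concentrations keyed by accession.

Matching is by identifier sets, never by names.  Charge-balancing
differences between curated networks and kinetics databases (extra protons
or water on one side) are absorbed by a configurable cofactor-ignore list
applied to both sides of the comparison before equality is tested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from . import units
from .expr import ExpressionError, MathExpression, names_in, parse_expression
from .model import Model, Reaction

__all__ = [
    "ReactionSignature",
    "KineticsEntry",
    "KineticsStore",
    "ConcentrationRecord",
    "KeyResultsStore",
    "MatchTolerance",
    "MatchCandidate",
    "load_kinetics",
    "load_key_results",
    "signature_of",
    "find_kinetics",
    "SignatureError",
    "StoreLoadError",
]

#: ChEBI accessions ignored during matching by default (hydron, water)
DEFAULT_COFACTOR_IGNORE = frozenset({"CHEBI:15378", "CHEBI:15377"})


class StoreLoadError(ValueError):
    """Store file violates its schema; the message names the entry."""


class SignatureError(ValueError):
    """A reaction species lacks the annotation needed to build a signature."""


@dataclass(frozen=True)
class ReactionSignature:
    """Identifier-set key of a reaction: accessions only, never names."""

    reactants: tuple[str, ...]  # sorted multiset of ChEBI accessions
    products: tuple[str, ...]
    modifiers: frozenset[str] = frozenset()  # enzyme UniProt accessions

    @staticmethod
    def make(reactants, products, modifiers=()) -> "ReactionSignature":
        return ReactionSignature(
            tuple(sorted(reactants)), tuple(sorted(products)), frozenset(modifiers)
        )

    def without(self, ignored: frozenset[str]) -> "ReactionSignature":
        return ReactionSignature(
            tuple(a for a in self.reactants if a not in ignored),
            tuple(a for a in self.products if a not in ignored),
            self.modifiers,
        )

    def reversed(self) -> "ReactionSignature":
        return ReactionSignature(self.products, self.reactants, self.modifiers)


@dataclass(frozen=True)
class MatchTolerance:
    """Options loosening signature comparison."""

    ignore_cofactors: bool = False
    cofactor_accessions: frozenset[str] = DEFAULT_COFACTOR_IGNORE


@dataclass
class KineticsEntry:
    id: str
    signature: ReactionSignature
    rate_law: str  # infix text over accessions and parameter names
    expression: MathExpression
    parameters: dict[str, float]  # values in package units
    conditions: dict = field(default_factory=dict)


@dataclass
class KineticsStore:
    entries: list[KineticsEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ConcentrationRecord:
    accession: str
    value: float  # package concentration unit (mM)
    condition: str = ""


@dataclass
class KeyResultsStore:
    records: list[ConcentrationRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, accession: str, condition: Optional[str] = None) -> Optional[float]:
        """First matching record's value, or None."""
        for rec in self.records:
            if rec.accession == accession and (
                condition is None or rec.condition == condition
            ):
                return rec.value
        return None


def load_kinetics(path: Union[str, Path]) -> KineticsStore:
    """Load a kinetics JSON file; units normalised to package defaults."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as e:
            raise StoreLoadError(f"not valid JSON: {e}") from None
    store = KineticsStore()
    for entry in data.get("entries", []):
        eid = entry.get("id")
        if not eid:
            raise StoreLoadError("kinetics entry without id")
        try:
            expr = parse_expression(entry["rate_law"])
        except (KeyError, ExpressionError) as e:
            raise StoreLoadError(f"entry {eid}: bad rate law ({e})") from None
        params: dict[str, float] = {}
        for pname, pval in entry.get("parameters", {}).items():
            try:
                params[pname] = units.convert_rate_parameter(
                    float(pval["value"]), pval.get("unit", ""))
            except (TypeError, KeyError, units.UnitError) as e:
                raise StoreLoadError(f"entry {eid}: parameter {pname}: {e}") from None
        sig = ReactionSignature.make(
            entry.get("reactants", []), entry.get("products", []),
            entry.get("modifiers", []))
        accession_names = set(sig.reactants) | set(sig.products) | set(sig.modifiers)
        unvalued = names_in(expr) - set(params) - accession_names
        if unvalued:
            raise StoreLoadError(
                f"entry {eid}: expression names without values: {sorted(unvalued)}")
        store.entries.append(KineticsEntry(
            id=eid, signature=sig, rate_law=entry["rate_law"],
            expression=expr, parameters=params,
            conditions=entry.get("conditions", {})))
    store.entries.sort(key=lambda e: e.id)
    return store


def load_key_results(path: Union[str, Path]) -> KeyResultsStore:
    """Load a key-results JSON file; concentrations converted to mM."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as e:
            raise StoreLoadError(f"not valid JSON: {e}") from None
    store = KeyResultsStore()
    for i, rec in enumerate(data.get("records", [])):
        try:
            acc = rec["accession"]
            value = units.to_millimolar(float(rec["value"]), rec.get("unit", "mM"))
        except (KeyError, TypeError, units.UnitError) as e:
            raise StoreLoadError(f"record {i}: {e}") from None
        if value < 0:
            raise StoreLoadError(f"record {i} ({acc}): negative concentration")
        store.records.append(ConcentrationRecord(acc, value, rec.get("condition", "")))
    return store


def signature_of(
    reaction: Reaction, model: Model,
    tolerance: MatchTolerance = MatchTolerance(),
) -> ReactionSignature:
    """Extract the identifier signature of a model reaction.

    Reactant/product accessions come from ChEBI annotations, modifier
    accessions from UniProt annotations.  With cofactor tolerance enabled,
    accessions on the ignore list are dropped.
    """

    def accession(sid: str, namespace: str) -> str:
        sp = model.species_by_id(sid)
        accs = sp.accessions(namespace) or sp.accessions()
        if not accs:
            raise SignatureError(f"species {sid!r} carries no accession")
        return accs[0]

    sig = ReactionSignature.make(
        [accession(sid, "chebi") for sid, _ in reaction.reactants],
        [accession(sid, "chebi") for sid, _ in reaction.products],
        [accession(sid, "uniprot") for sid in reaction.modifiers],
    )
    if tolerance.ignore_cofactors:
        sig = sig.without(tolerance.cofactor_accessions)
    return sig


@dataclass(frozen=True)
class MatchCandidate:
    entry: KineticsEntry
    rank: int  # 1 exact, 2 reverse direction, 3 enzyme mismatch (advisory)
    reverse: bool
    modifier_mismatch: bool


def find_kinetics(
    store: KineticsStore,
    signature: ReactionSignature,
    direction_policy: str = "both",  # "both" | "forward"
    tolerance: MatchTolerance = MatchTolerance(),
) -> list[MatchCandidate]:
    """Rank store entries against a reaction signature.

    Rank 1: metabolite multisets and modifier set match exactly.
    Rank 2: metabolites match with reactants/products swapped (permitted
    when *direction_policy* is ``"both"``).  Rank 3 (advisory): metabolites
    match but enzyme accessions differ — kinetics databases may record
    orthologous enzymes.  Within a rank, entries are id-ordered.  An empty
    list signals that the caller should fall back to mass action.
    """
    ignored = (tolerance.cofactor_accessions if tolerance.ignore_cofactors
               else frozenset())
    sig = signature.without(ignored)
    out: list[MatchCandidate] = []
    for entry in store.entries:  # already id-sorted
        esig = entry.signature.without(ignored)
        fwd = (esig.reactants == sig.reactants and esig.products == sig.products)
        rev = (esig.reactants == sig.products and esig.products == sig.reactants)
        if not fwd and not (rev and direction_policy == "both"):
            continue
        mod_ok = esig.modifiers == sig.modifiers
        if fwd and mod_ok:
            rank, reverse = 1, False
        elif rev and mod_ok and direction_policy == "both":
            rank, reverse = 2, True
        else:
            rank, reverse = 3, not fwd
        out.append(MatchCandidate(entry, rank, reverse, not mod_ok))
    out.sort(key=lambda c: (c.rank, c.entry.id))
    return out
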