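"""Parameterisation: turn a qualitative model into a quantitative one.

Each reaction receives a kinetic law — either a matched entry from the
kinetics store (selected by policy among ranked candidates) or, when no
entry matches, a mass-action law whose rate constants are set to one (the
failsafe that keeps every reaction simulatable).  Species receive starting
concentrations from the key-results store by accession; metabolites
without a record fall back to a configurable default and are flagged.

Matched rate laws reference species by database accession; binding
rewrites those references to model species ids and refuses expressions
whose accessions do not occur in the reaction, which would silently build
an anomalous model.  Fallback mass-action laws are classical: they do not
multiply by the enzyme concentration.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

from .expr import BinOp, MathExpression, Name, Num, names_in, substitute
from .model import KineticLaw, Model, Parameter, Reaction, validate_model
from .stores import (
    KeyResultsStore,
    KineticsStore,
    MatchCandidate,
    MatchTolerance,
    SignatureError,
    find_kinetics,
    signature_of,
)

__all__ = ["parameterise", "mass_action_fallback", "ParameterisationReport"]

Chooser = Callable[[Reaction, list[MatchCandidate]], MatchCandidate]


@dataclass
class ReactionOutcome:
    reaction_id: str
    provenance: str  # matched | fallback_mass_action
    entry_id: Optional[str] = None
    rank: Optional[int] = None
    reverse: bool = False
    modifier_mismatch: bool = False
    notes: list[str] = field(default_factory=list)


@dataclass
class ParameterisationReport:
    reactions: list[ReactionOutcome] = field(default_factory=list)
    enzymes_without_concentration: list[str] = field(default_factory=list)
    metabolites_defaulted: list[str] = field(default_factory=list)
    overwritten: list[str] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return sum(1 for r in self.reactions if r.provenance == "matched")

    @property
    def n_fallback(self) -> int:
        return sum(1 for r in self.reactions if r.provenance == "fallback_mass_action")

    def to_dict(self) -> dict:
        return {
            "reactions": [vars(r) for r in self.reactions],
            "n_matched": self.n_matched,
            "n_fallback": self.n_fallback,
            "enzymes_without_concentration": self.enzymes_without_concentration,
            "metabolites_defaulted": self.metabolites_defaulted,
            "overwritten": self.overwritten,
        }


def _rate_term(constant: str,
               terms: list[tuple[str, float]]) -> MathExpression:
    """Left-associated ``constant * s1^n1 * s2^n2 * ...`` chain."""
    expr: MathExpression = Name(constant)
    for sid, stoich in terms:
        factor: MathExpression = Name(sid)
        if stoich != 1:
            factor = BinOp("^", factor, Num(float(stoich)))
        expr = BinOp("*", expr, factor)
    return expr


def mass_action_fallback(reaction: Reaction) -> KineticLaw:
    """Mass-action law with every rate constant set to one.

    Irreversible: ``k_f * prod(reactant^stoich)``.  Reversible adds
    ``- k_r * prod(product^stoich)``.  Rate constants are local parameters.
    """
    fwd = _rate_term("k_f", [(sid, float(st)) for sid, st in reaction.reactants])
    params = [Parameter("k_f", 1.0, "1/s", "local")]
    expr: MathExpression = fwd
    if reaction.reversible:
        rev = _rate_term("k_r", [(sid, float(st)) for sid, st in reaction.products])
        expr = BinOp("-", fwd, rev)
        params.append(Parameter("k_r", 1.0, "1/s", "local"))
    return KineticLaw(expression=expr, local_parameters=params,
                      provenance="fallback_mass_action")


class BindingError(ValueError):
    """A matched rate law references an accession absent from the reaction."""


def _bind_matched_law(candidate: MatchCandidate, reaction: Reaction,
                      model: Model) -> KineticLaw:
    entry = candidate.entry
    acc_to_sid: dict[str, str] = {}
    for sid in ([s for s, _ in reaction.reactants]
                + [s for s, _ in reaction.products] + list(reaction.modifiers)):
        sp = model.species_by_id(sid)
        for acc in sp.accessions():
            acc_to_sid.setdefault(acc, sid)
    referenced = names_in(entry.expression)
    accession_refs = referenced - set(entry.parameters)
    missing = {a for a in accession_refs if a not in acc_to_sid}
    if missing:
        raise BindingError(
            f"entry {entry.id}: accessions {sorted(missing)} not in reaction "
            f"{reaction.id}")
    expr = substitute(entry.expression, acc_to_sid)
    params = [Parameter(name, value, "dimensionless", "local")
              for name, value in sorted(entry.parameters.items())]
    return KineticLaw(expression=expr, local_parameters=params,
                      provenance="matched")


def parameterise(
    model: Model,
    kstore: KineticsStore,
    cstore: KeyResultsStore,
    selection: Union[str, Chooser] = "first",
    tolerance: MatchTolerance = MatchTolerance(),
    direction_policy: str = "both",
    default_metabolite_conc: float = 1.0,
    policy: str = "overwrite",  # overwrite | keep-existing
) -> tuple[Model, ParameterisationReport]:
    """Return a quantitative copy of *model* plus a full provenance report.

    Never fatal: every unmatched reaction gets the mass-action failsafe and
    every gap is reported.
    """
    model = copy.deepcopy(model)
    report = ParameterisationReport()

    for rxn in model.reactions:
        if rxn.kinetic_law is not None:
            if policy == "keep-existing":
                report.reactions.append(ReactionOutcome(
                    rxn.id, rxn.kinetic_law.provenance,
                    notes=["kept existing kinetic law"]))
                continue
            report.overwritten.append(rxn.id)
        outcome = _parameterise_reaction(
            rxn, model, kstore, selection, tolerance, direction_policy)
        report.reactions.append(outcome)

    for sp in model.species:
        namespace = "uniprot" if sp.role_hint == "enzyme" else "chebi"
        value = None
        for acc in sp.accessions(namespace) or sp.accessions():
            value = cstore.get(acc)
            if value is not None:
                break
        if value is not None:
            sp.initial_concentration = value
        elif sp.role_hint == "enzyme":
            report.enzymes_without_concentration.append(sp.id)
            if sp.initial_concentration is None:
                sp.initial_concentration = default_metabolite_conc
        else:
            report.metabolites_defaulted.append(sp.id)
            if sp.initial_concentration is None:
                sp.initial_concentration = default_metabolite_conc

    violations = validate_model(model)
    assert not violations, f"parameterisation produced invalid model: {violations}"
    return model, report


def _parameterise_reaction(rxn, model, kstore, selection, tolerance,
                           direction_policy) -> ReactionOutcome:
    notes: list[str] = []
    try:
        sig = signature_of(rxn, model, tolerance)
        candidates = find_kinetics(kstore, sig, direction_policy, tolerance)
    except SignatureError as e:
        candidates = []
        notes.append(str(e))

    while candidates:
        if callable(selection):
            cand = selection(rxn, candidates)
        else:
            cand = candidates[0]  # policy "first": top-ranked candidate
        try:
            rxn.kinetic_law = _bind_matched_law(cand, rxn, model)
        except BindingError as e:
            notes.append(str(e))
            candidates = [c for c in candidates if c is not cand]
            continue
        return ReactionOutcome(
            rxn.id, "matched", entry_id=cand.entry.id, rank=cand.rank,
            reverse=cand.reverse, modifier_mismatch=cand.modifier_mismatch,
            notes=notes)

    rxn.kinetic_law = mass_action_fallback(rxn)
    return ReactionOutcome(rxn.id, "fallback_mass_action", notes=notes)
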