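"""Qualitative model assembly.

Builds a MIRIAM-annotated, qualitative (no kinetics, no concentrations)
:class:`~pathwaykit.model.Model` from network-store query results.  Species
identity is keyed on (cross-reference accession, compartment) rather than
on name strings, so metabolites that share a name but not an accession stay
distinct, and repeated or overlapping builds merge idempotently.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

from .model import (
    Annotation,
    Compartment,
    Model,
    Reaction,
    Species,
    identifiers_org_uri,
    sanitize_id,
)
from .network import NetworkRecord, NetworkStore, reactions_for_orfs, reactions_for_pathway

__all__ = ["assemble_model"]

DEFAULT_COMPARTMENT = "cytosol"


def _chebi_uri(acc: str) -> str:
    return identifiers_org_uri("chebi", acc)


def _uniprot_uri(acc: str) -> str:
    return identifiers_org_uri("uniprot", acc)


def assemble_model(
    store: NetworkStore,
    orfs: Optional[Sequence[str]] = None,
    pathway: Optional[str] = None,
    model_name: str = "assembled model",
    model_id: str = "assembled_model",
    exclude_accessions: Iterable[str] = (),
    default_compartment: str = DEFAULT_COMPARTMENT,
) -> Model:
    """Assemble a qualitative annotated model from query results.

    Exactly one of *orfs* / *pathway* selects the reactions.  Metabolites
    whose ChEBI accession appears in *exclude_accessions* (e.g. currency
    metabolites) are dropped from reactions.  Records without a compartment
    fall into *default_compartment*.  An empty query yields a valid empty
    model with a warning.
    """
    if (orfs is None) == (pathway is None):
        raise ValueError("provide exactly one of orfs or pathway")
    if orfs is not None:
        records, unknown = reactions_for_orfs(store, list(orfs))
        if unknown:
            warnings.warn(f"ORFs not found in network store: {unknown}")
    else:
        records = reactions_for_pathway(store, pathway)

    model = Model(id=model_id, name=model_name)
    if not records:
        warnings.warn("query matched no reactions; returning an empty model")
        return model

    excluded = set(exclude_accessions)
    comp_ids: dict[str, str] = {}  # compartment name -> model id
    species_ids: dict[tuple[str, str], str] = {}  # (accession, comp) -> id

    def compartment_id(name: str) -> str:
        name = name or default_compartment
        if name not in comp_ids:
            cid = sanitize_id(name, "c_")
            comp_ids[name] = cid
            model.compartments.append(Compartment(id=cid, name=name))
        return comp_ids[name]

    def metabolite_species(ref, comp_name: str) -> str:
        cid = compartment_id(comp_name)
        key = (ref.chebi, cid)
        if key not in species_ids:
            sid = sanitize_id(f"{ref.chebi}_{comp_name or default_compartment}", "s_")
            species_ids[key] = sid
            model.species.append(Species(
                id=sid,
                name=ref.name,
                compartment_ref=cid,
                role_hint="metabolite",
                boundary=ref.external,
                annotations=[Annotation("is", _chebi_uri(ref.chebi))],
            ))
        return species_ids[key]

    def enzyme_species(enz, comp_name: str) -> str:
        cid = compartment_id(comp_name)
        key = (enz.orf, cid)
        if key not in species_ids:
            sid = sanitize_id(f"{enz.orf}_{comp_name or default_compartment}", "s_")
            species_ids[key] = sid
            model.species.append(Species(
                id=sid,
                name=enz.name or enz.orf,
                compartment_ref=cid,
                role_hint="enzyme",
                annotations=[Annotation("is", _uniprot_uri(enz.uniprot))],
            ))
        return species_ids[key]

    for rec in records:  # already reaction-id sorted
        rxn = _build_reaction(rec, metabolite_species, enzyme_species, excluded)
        model.reactions.append(rxn)
    return model


def _build_reaction(rec: NetworkRecord, metabolite_species, enzyme_species,
                    excluded: set[str]) -> Reaction:
    rxn = Reaction(
        id=sanitize_id(rec.reaction_id, "r_"),
        name=rec.name,
        reversible=rec.reversible if rec.reversible is not None else True,
    )
    for ref in rec.reactants:
        if ref.chebi in excluded:
            continue
        rxn.reactants.append((metabolite_species(ref, rec.compartment),
                              ref.stoichiometry))
    for ref in rec.products:
        if ref.chebi in excluded:
            continue
        rxn.products.append((metabolite_species(ref, rec.compartment),
                             ref.stoichiometry))
    for enz in rec.enzymes:
        # each subunit of a multi-protein complex is its own modifier species
        rxn.modifiers.append(enzyme_species(enz, rec.compartment))
        rxn.annotations.append(Annotation("isVersionOf", _uniprot_uri(enz.uniprot)))
    if not rxn.annotations:
        # uncatalysed reaction: carry the substrate cross-references instead
        for ref in rec.reactants + rec.products:
            rxn.annotations.append(Annotation("hasPart", _chebi_uri(ref.chebi)))
    return rxn
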