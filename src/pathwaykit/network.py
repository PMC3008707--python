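"""File-backed reaction-network store.

Replaces a remote consensus-network service with a JSON file holding
reactions, their reactant/product metabolites (cross-referenced to ChEBI),
and their catalysing enzymes (identified by yeast ORF and UniProt
accessions).  Queries return deterministic, reaction-id-sorted results.

JSON schema (top level)::

    {
      "compartments": [{"id", "name"}],
      "metabolites":  [{"id", "name", "chebi", "compartment", "external"?}],
      "proteins":     [{"orf", "name", "uniprot"}],
      "reactions":    [{"id", "name", "compartment",
                        "reactants": [{"metabolite", "stoichiometry"}],
                        "products":  [{"metabolite", "stoichiometry"}],
                        "enzymes":   [orf, ...],
                        "pathways":  [term, ...],
                        "reversible"?}],
      "pathways":     [term, ...]
    }
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Union


class NetworkSchemaError(ValueError):
    """Store file violates the documented schema; message names the spot."""


@dataclass(frozen=True)
class MetaboliteRef:
    id: str
    name: str
    chebi: str
    stoichiometry: Fraction
    external: bool = False


@dataclass(frozen=True)
class EnzymeRef:
    orf: str
    name: str
    uniprot: str


@dataclass(frozen=True)
class NetworkRecord:
    """One consensus reaction: metabolites, enzymes, compartment, pathways."""

    reaction_id: str
    name: str
    compartment: str
    reactants: tuple[MetaboliteRef, ...]
    products: tuple[MetaboliteRef, ...]
    enzymes: tuple[EnzymeRef, ...]
    pathways: tuple[str, ...]
    reversible: Optional[bool] = None


@dataclass
class NetworkStore:
    records: list[NetworkRecord] = field(default_factory=list)
    compartments: dict[str, str] = field(default_factory=dict)  # id -> name
    _by_orf: dict[str, list[str]] = field(default_factory=dict)
    _by_pathway: dict[str, list[str]] = field(default_factory=dict)
    _by_chebi: dict[str, list[str]] = field(default_factory=dict)
    _by_id: dict[str, NetworkRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def orfs(self) -> set[str]:
        return set(self._by_orf)

    def pathway_terms(self) -> set[str]:
        return {t for r in self.records for t in r.pathways}

    def _index(self) -> None:
        self._by_orf.clear()
        self._by_pathway.clear()
        self._by_chebi.clear()
        self._by_id.clear()
        for rec in self.records:
            self._by_id[rec.reaction_id] = rec
            for e in rec.enzymes:
                self._by_orf.setdefault(e.orf, []).append(rec.reaction_id)
            for term in rec.pathways:
                self._by_pathway.setdefault(term.casefold(), []).append(rec.reaction_id)
            for m in rec.reactants + rec.products:
                self._by_chebi.setdefault(m.chebi, []).append(rec.reaction_id)


def _req(obj: dict, key: str, where: str):
    if key not in obj:
        raise NetworkSchemaError(f"{where}: missing field {key!r}")
    return obj[key]


def load_network(path: Union[str, Path]) -> NetworkStore:
    """Load and index a network JSON file; deterministic for a given file."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as e:
            raise NetworkSchemaError(f"not valid JSON: {e}") from None

    store = NetworkStore()
    for c in _req(data, "compartments", "top level"):
        store.compartments[_req(c, "id", "compartment")] = c.get("name", c["id"])

    metabolites: dict[str, dict] = {}
    for m in _req(data, "metabolites", "top level"):
        mid = _req(m, "id", "metabolite")
        if not m.get("chebi"):
            raise NetworkSchemaError(
                f"metabolite {mid!r}: missing cross-reference (chebi)")
        metabolites[mid] = m

    proteins: dict[str, dict] = {}
    for p in _req(data, "proteins", "top level"):
        orf = _req(p, "orf", "protein")
        if not orf:
            raise NetworkSchemaError("protein with empty orf")
        proteins[orf] = p

    def met_ref(entry: dict, rid: str) -> MetaboliteRef:
        mid = _req(entry, "metabolite", f"reaction {rid}")
        if mid not in metabolites:
            raise NetworkSchemaError(f"reaction {rid}: unknown metabolite {mid!r}")
        stoich = Fraction(str(_req(entry, "stoichiometry", f"reaction {rid}")))
        if stoich <= 0:
            raise NetworkSchemaError(f"reaction {rid}: stoichiometry {stoich} <= 0")
        m = metabolites[mid]
        return MetaboliteRef(mid, m.get("name", mid), m["chebi"], stoich,
                             bool(m.get("external", False)))

    for r in _req(data, "reactions", "top level"):
        rid = _req(r, "id", "reaction")
        enzymes = []
        for orf in r.get("enzymes", []):
            if orf not in proteins:
                raise NetworkSchemaError(f"reaction {rid}: unknown enzyme {orf!r}")
            p = proteins[orf]
            enzymes.append(EnzymeRef(orf, p.get("name", orf),
                                     _req(p, "uniprot", f"protein {orf}")))
        store.records.append(NetworkRecord(
            reaction_id=rid,
            name=r.get("name", rid),
            compartment=r.get("compartment", ""),
            reactants=tuple(met_ref(e, rid) for e in _req(r, "reactants", f"reaction {rid}")),
            products=tuple(met_ref(e, rid) for e in _req(r, "products", f"reaction {rid}")),
            enzymes=tuple(enzymes),
            pathways=tuple(r.get("pathways", [])),
            reversible=r.get("reversible"),
        ))
    store.records.sort(key=lambda rec: rec.reaction_id)
    store._index()
    return store


def reactions_for_orfs(
    store: NetworkStore, orfs: list[str]
) -> tuple[list[NetworkRecord], list[str]]:
    """Records catalysed by any listed ORF, deduplicated and id-sorted.

    Returns ``(records, unknown_orfs)``; unknown ORFs are reported, never
    fatal.
    """
    hit_ids: set[str] = set()
    unknown: list[str] = []
    for orf in orfs:
        ids = store._by_orf.get(orf)
        if ids is None:
            unknown.append(orf)
        else:
            hit_ids.update(ids)
    records = [store._by_id[rid] for rid in sorted(hit_ids)]
    return records, unknown


def reactions_for_pathway(store: NetworkStore, term: str) -> list[NetworkRecord]:
    """Records whose pathway terms contain *term* (case-insensitive exact)."""
    ids = store._by_pathway.get(term.casefold(), [])
    return [store._by_id[rid] for rid in sorted(set(ids))]
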