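"""Kinetics/key-results stores and identifier-set matching."""

import json

import pytest

from pathwaykit.stores import (
    MatchTolerance,
    ReactionSignature,
    SignatureError,
    StoreLoadError,
    find_kinetics,
    load_key_results,
    load_kinetics,
    signature_of,
)


def _write(tmp_path, name, payload):
    p = tmp_path / name
    p.write_text(json.dumps(payload))
    return p


def _entry(eid="K1", reactants=("CHEBI:1",), products=("CHEBI:2",),
           modifiers=("P1",), rate_law="k*CHEBI:1",
           parameters=None):
    return {"id": eid, "reactants": list(reactants),
            "products": list(products), "modifiers": list(modifiers),
            "rate_law": rate_law,
            "parameters": parameters or {"k": {"value": 2.0, "unit": "1/s"}}}


class TestLoading:
    def test_empty_files_give_empty_stores(self, tmp_path):
        assert len(load_kinetics(_write(tmp_path, "k.json", {"entries": []}))) == 0
        assert len(load_key_results(_write(tmp_path, "c.json", {"records": []}))) == 0

    def test_expression_with_unvalued_parameter_fails(self, tmp_path):
        bad = _entry(rate_law="k*Kx*CHEBI:1")
        with pytest.raises(StoreLoadError, match="Kx"):
            load_kinetics(_write(tmp_path, "k.json", {"entries": [bad]}))

    def test_unit_conversion_at_load(self, tmp_path):
        entry = _entry(parameters={
            "Vmax": {"value": 2.0, "unit": "uM/s"},
            "Km": {"value": 3.0, "unit": "M"}}, rate_law="Vmax*CHEBI:1/(Km+CHEBI:1)")
        store = load_kinetics(_write(tmp_path, "k.json", {"entries": [entry]}))
        assert store.entries[0].parameters["Vmax"] == pytest.approx(0.002)
        assert store.entries[0].parameters["Km"] == pytest.approx(3000.0)

    def test_key_results_negative_value_rejected(self, tmp_path):
        with pytest.raises(StoreLoadError, match="negative"):
            load_key_results(_write(tmp_path, "c.json", {"records": [
                {"accession": "P1", "value": -1, "unit": "mM"}]}))

    def test_key_results_unit_normalisation(self, tmp_path):
        store = load_key_results(_write(tmp_path, "c.json", {"records": [
            {"accession": "P1", "value": 5.0, "unit": "uM"}]}))
        assert store.get("P1") == pytest.approx(0.005)
        assert store.get("P2") is None

    def test_glycolysis_fixture_has_two_deposited_enzymes(self, glyco_paths):
        store = load_kinetics(glyco_paths["paths"]["kinetics"])
        assert len(store) == 2  # aldolase and pyruvate decarboxylase steps


class TestSignature:
    def test_signature_extracts_accessions(self, glyco_model):
        rxn = glyco_model.reactions[0]
        sig = signature_of(rxn, glyco_model)
        assert len(sig.reactants) == 1 and len(sig.products) == 1
        assert all(a.startswith("CHEBI:TEST") for a in sig.reactants)
        assert all(a.startswith("TESTP") for a in sig.modifiers)

    def test_cofactor_tolerance_drops_ignored_accessions(self):
        sig = ReactionSignature.make(["CHEBI:15378", "CHEBI:1"], ["CHEBI:2"])
        dropped = sig.without(frozenset({"CHEBI:15378"}))
        assert dropped.reactants == ("CHEBI:1",)

    def test_unannotated_species_raises(self, glyco_model):
        import copy
        m = copy.deepcopy(glyco_model)
        m.species[0].annotations = []
        rxn = next(r for r in m.reactions
                   if any(s == m.species[0].id for s, _ in r.reactants))
        with pytest.raises(SignatureError, match=m.species[0].id):
            signature_of(rxn, m)


class TestMatching:
    @pytest.fixture
    def store(self, tmp_path):
        entries = [
            _entry("K_fwd", ["CHEBI:1"], ["CHEBI:2"], ["P1"]),
            _entry("K_other_enzyme", ["CHEBI:1"], ["CHEBI:2"], ["P9"]),
            _entry("K_water", ["CHEBI:1", "CHEBI:15377"], ["CHEBI:2"], ["P1"]),
        ]
        return load_kinetics(_write(tmp_path, "k.json", {"entries": entries}))

    def test_exact_match_ranks_first(self, store):
        sig = ReactionSignature.make(["CHEBI:1"], ["CHEBI:2"], ["P1"])
        cands = find_kinetics(store, sig)
        assert cands[0].entry.id == "K_fwd" and cands[0].rank == 1

    def test_reverse_direction_ranks_second(self, store):
        sig = ReactionSignature.make(["CHEBI:2"], ["CHEBI:1"], ["P1"])
        cands = find_kinetics(store, sig, direction_policy="both")
        assert cands[0].entry.id == "K_fwd" and cands[0].rank == 2
        assert cands[0].reverse
        assert find_kinetics(store, sig, direction_policy="forward") == [] or \
            all(c.rank == 3 for c in
                find_kinetics(store, sig, direction_policy="forward"))

    def test_enzyme_mismatch_is_advisory_rank_three(self, store):
        sig = ReactionSignature.make(["CHEBI:1"], ["CHEBI:2"], ["P1"])
        cands = find_kinetics(store, sig)
        third = [c for c in cands if c.entry.id == "K_other_enzyme"]
        assert third and third[0].rank == 3 and third[0].modifier_mismatch

    def test_no_match_returns_empty_list(self, store):
        sig = ReactionSignature.make(["CHEBI:77"], ["CHEBI:78"], ["P1"])
        assert find_kinetics(store, sig) == []

    def test_duplicate_signatures_return_id_sorted(self, tmp_path):
        entries = [_entry("K_b"), _entry("K_a")]
        store = load_kinetics(_write(tmp_path, "k.json", {"entries": entries}))
        sig = ReactionSignature.make(["CHEBI:1"], ["CHEBI:2"], ["P1"])
        assert [c.entry.id for c in find_kinetics(store, sig)] == ["K_a", "K_b"]

    def test_multiset_semantics_order_independent(self, tmp_path):
        e = _entry("K1", ["CHEBI:2", "CHEBI:1"], ["CHEBI:3"],
                   rate_law="k*CHEBI:1")
        store = load_kinetics(_write(tmp_path, "k.json", {"entries": [e]}))
        sig = ReactionSignature.make(["CHEBI:1", "CHEBI:2"], ["CHEBI:3"], ["P1"])
        assert len(find_kinetics(store, sig)) == 1

    def test_cofactor_tolerance_never_shrinks_candidates(self, store):
        # the charge-balancing remedy: extra water on one side only
        sig = ReactionSignature.make(["CHEBI:1"], ["CHEBI:2"], ["P1"])
        off = find_kinetics(store, sig, tolerance=MatchTolerance(False))
        on = find_kinetics(store, sig, tolerance=MatchTolerance(True))
        assert {c.entry.id for c in off} <= {c.entry.id for c in on}
        assert any(c.entry.id == "K_water" for c in on)
        assert not any(c.entry.id == "K_water" for c in off)
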