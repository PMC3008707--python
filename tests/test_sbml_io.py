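"""SBML serialisation: round-trips, annotation blocks, validator checks,
and rejection of constructs outside the supported subset."""

from fractions import Fraction

import numpy as np
import pytest

from pathwaykit.expr import parse_expression
from pathwaykit.model import (
    Annotation,
    Compartment,
    KineticLaw,
    Model,
    Parameter,
    Reaction,
    Species,
)
from pathwaykit.parameterise import mass_action_fallback
from pathwaykit.sbml_io import (
    InvalidModelError,
    UnsupportedFeatureError,
    read_sbml,
    validate_document,
    write_sbml,
)

QUALIFIER_POOL = ["is", "isVersionOf", "hasPart", "isDescribedBy"]


def random_model(rng: np.random.Generator) -> Model:
    """Seeded generator of valid models inside the supported subset."""
    m = Model(id=f"m{rng.integers(1000)}", name="random model")
    n_comp = int(rng.integers(1, 3))
    for i in range(n_comp):
        m.compartments.append(Compartment(
            f"c_{i}", f"compartment {i}",
            annotations=[Annotation("is", f"https://identifiers.org/go/GO:{7000 + i}")]))
    n_sp = int(rng.integers(2, 7))
    for i in range(n_sp):
        anns = []
        # each annotation gets a distinct URI: one URI never appears under
        # two qualifiers on the same component
        for k, q in enumerate(sorted(rng.choice(
                QUALIFIER_POOL, size=int(rng.integers(0, 3)),
                replace=False).tolist())):
            anns.append(Annotation(
                q, f"https://identifiers.org/chebi/CHEBI:{1000 + 10 * i + k}"))
        m.species.append(Species(
            id=f"s_{i}", name=f"species {i}",
            compartment_ref=f"c_{int(rng.integers(n_comp))}",
            role_hint=str(rng.choice(["metabolite", "enzyme"])),
            initial_concentration=(None if rng.random() < 0.3
                                   else float(np.round(rng.uniform(0, 5), 6))),
            boundary=bool(rng.random() < 0.2),
            annotations=anns))
    for i in range(int(rng.integers(0, 3))):
        m.global_parameters.append(Parameter(
            f"gp_{i}", float(np.round(rng.uniform(0.1, 10), 6)), "mM"))
    n_rxn = int(rng.integers(1, 5))
    for i in range(n_rxn):
        ids = rng.permutation(n_sp)
        n_react = int(rng.integers(1, min(3, n_sp)))
        n_prod = int(rng.integers(1, max(2, n_sp - n_react)))
        rxn = Reaction(
            id=f"r_{i}", name=f"reaction {i}",
            reactants=[(f"s_{ids[j]}", Fraction(int(rng.integers(1, 4))))
                       for j in range(n_react)],
            products=[(f"s_{ids[n_react + j]}", Fraction(1, 2) * int(rng.integers(1, 4)))
                      for j in range(min(n_prod, n_sp - n_react))],
            modifiers=[f"s_{ids[-1]}"] if rng.random() < 0.4 else [],
            reversible=bool(rng.random() < 0.5),
            annotations=[Annotation(
                "isVersionOf", f"https://identifiers.org/ec-code/1.1.1.{i + 1}")],
        )
        if rng.random() < 0.7:
            rxn.kinetic_law = mass_action_fallback(rxn)
        m.reactions.append(rxn)
    return m


def test_empty_model_produces_valid_sbml():
    text = write_sbml(Model(id="empty"))
    assert "<sbml" in text and validate_document(text) == 0
    assert read_sbml(text).id == "empty"


def test_annotation_block_contains_resource_uri():
    m = Model(
        id="m", compartments=[Compartment("c_c", "cytosol")],
        species=[Species("s_glc", "glucose", "c_c", annotations=[
            Annotation("is", "https://identifiers.org/chebi/CHEBI:4167")])])
    assert "https://identifiers.org/chebi/CHEBI:4167" in write_sbml(m)


def test_round_trip_preserves_model(glyco_quant):
    model, _ = glyco_quant
    assert read_sbml(write_sbml(model)) == model


def test_randomised_round_trips():
    rng = np.random.default_rng(42)
    for _ in range(25):
        m = random_model(rng)
        assert read_sbml(write_sbml(m)) == m


def test_glycolysis_document_passes_independent_validator(glyco_quant):
    model, _ = glyco_quant
    assert validate_document(write_sbml(model)) == 0


def test_write_refuses_invalid_model():
    m = Model(id="bad", species=[Species("s", "s", "missing_comp")])
    with pytest.raises(InvalidModelError):
        write_sbml(m)


def test_event_document_raises_unsupported_feature():
    doc = """<?xml version="1.0" encoding="UTF-8"?>
    <sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
      <model id="with_event">
        <listOfEvents>
          <event useValuesFromTriggerTime="true">
            <trigger initialValue="true" persistent="true">
              <math xmlns="http://www.w3.org/1998/Math/MathML"><true/></math>
            </trigger>
          </event>
        </listOfEvents>
      </model>
    </sbml>"""
    with pytest.raises(UnsupportedFeatureError, match="event"):
        read_sbml(doc)


def test_minimal_handwritten_l2_document_reads():
    doc = """<?xml version="1.0" encoding="UTF-8"?>
    <sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
      <model id="tiny">
        <listOfCompartments><compartment id="c"/></listOfCompartments>
        <listOfSpecies>
          <species id="s1" compartment="c" initialConcentration="2.5"/>
        </listOfSpecies>
      </model>
    </sbml>"""
    m = read_sbml(doc)
    assert len(m.species) == 1
    assert m.species[0].initial_concentration == 2.5


def test_provenance_survives_round_trip():
    rxn = Reaction("r_1", reactants=[("s_A", Fraction(1))], reversible=False)
    rxn.kinetic_law = mass_action_fallback(rxn)
    m = Model(id="m", compartments=[Compartment("c_c")],
              species=[Species("s_A", "A", "c_c")], reactions=[rxn])
    back = read_sbml(write_sbml(m))
    assert back.reactions[0].kinetic_law.provenance == "fallback_mass_action"
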