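"""Synthetic fixture generation: toy pathway stores with known ground truth.

Emulates the three file-backed stores (reaction network, kinetics,
starting concentrations) for a chain- or branch-topology pathway, plus a
truth record of every generated parameter for recovery studies.  All
accessions use reserved test namespaces (``CHEBI:TEST...``, ``TESTP...``)
so fixture data can never be mistaken for curated identifiers.

A dedicated glycolysis-shaped fixture labels an eleven-reaction chain with
the twelve yeast ORFs of the classic glycolytic enzyme set (both
phosphofructokinase subunits catalysing one reaction) and deposits
kinetics for exactly two enzymes — aldolase (FBA1) and pyruvate
decarboxylase (PDC1) — leaving the rest to the mass-action failsafe.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .model import Model
from .ode import simulate
from .sbrml import ResultSet, timecourse_to_resultset, write_sbrml

__all__ = ["generate_fixture", "glycolysis_fixture", "generate_measurements",
           "recovery_study", "GLYCOLYSIS_ORFS"]

#: Systematic ORF names of the canonical yeast glycolytic enzyme set
GLYCOLYSIS_ORFS = [
    "YAL038W",  # pyruvate kinase
    "YGR254W",  # enolase I
    "YKL060C",  # fructose 1,6-bisphosphate aldolase (FBA1)
    "YKL152C",  # phosphoglycerate mutase
    "YFR053C",  # hexokinase 1
    "YLR044C",  # pyruvate decarboxylase (PDC1)
    "YGR240C",  # phosphofructokinase alpha subunit
    "YMR205C",  # phosphofructokinase beta subunit
    "YBR196C",  # phosphoglucose isomerase
    "YCR012W",  # 3-phosphoglycerate kinase
    "YJL052W",  # glyceraldehyde-3-phosphate dehydrogenase 1
    "YDR050C",  # triose phosphate isomerase
]


def _dump(obj: dict, path: Path) -> None:
    # sorted keys + fixed separators -> byte-identical files per seed
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def _chebi(i: int) -> str:
    return f"CHEBI:TEST{i:03d}"


def _uniprot(i: int) -> str:
    return f"TESTP{i:03d}"


def generate_fixture(
    n_reactions: int,
    topology: str = "chain",
    seed: int = 0,
    kinetics_coverage: float = 0.5,
    out_dir: Union[str, Path, None] = None,
    orf_labels: Optional[Sequence[str]] = None,
    pathway_term: str = "test pathway",
) -> dict:
    """Generate network/kinetics/key-results files plus a truth record.

    ``chain``: M0 -> M1 -> ... -> Mn.  ``branched``: reaction *i* consumes
    metabolite ``M[i // 2]``, giving a binary-tree fan-out.  A seeded
    subset of reactions (fraction *kinetics_coverage*, rounded) receives
    kinetics entries — alternating irreversible Michaelis-Menten and
    first-order mass-action forms — and the rest are deliberately missing
    so parameterisation must fall back to mass action.  Deterministic per
    seed.  Returns a dict with the four payloads and, when *out_dir* is
    given, the written file paths.
    """
    if n_reactions < 1:
        raise ValueError("n_reactions must be >= 1")
    if topology not in ("chain", "branched"):
        raise ValueError(f"unknown topology {topology!r}")
    rng = np.random.default_rng(seed)

    if topology == "chain":
        edges = [(i, i + 1) for i in range(n_reactions)]
    else:
        edges = [(i // 2, i + 1) for i in range(n_reactions)]
    n_mets = max(dst for _, dst in edges) + 1

    orfs = (list(orf_labels) if orf_labels is not None
            else [f"YTE{i + 1:03d}W" for i in range(n_reactions)])
    if len(orfs) != n_reactions:
        raise ValueError("orf_labels length must equal n_reactions")

    network = {
        "compartments": [{"id": "cytosol", "name": "cytosol"}],
        "metabolites": [
            {"id": f"M{i:03d}", "name": f"metabolite {i}", "chebi": _chebi(i),
             "compartment": "cytosol"}
            for i in range(n_mets)
        ],
        "proteins": [
            {"orf": orfs[i], "name": f"enzyme {i}", "uniprot": _uniprot(i)}
            for i in range(n_reactions)
        ],
        "reactions": [
            {"id": f"R{i + 1:03d}", "name": f"reaction {i + 1}",
             "compartment": "cytosol",
             "reactants": [{"metabolite": f"M{src:03d}", "stoichiometry": 1}],
             "products": [{"metabolite": f"M{dst:03d}", "stoichiometry": 1}],
             "enzymes": [orfs[i]],
             "pathways": [pathway_term],
             "reversible": False}
            for i, (src, dst) in enumerate(edges)
        ],
        "pathways": [pathway_term],
    }

    n_with_kinetics = round(n_reactions * kinetics_coverage)
    covered = sorted(rng.choice(n_reactions, size=n_with_kinetics,
                                replace=False).tolist())
    entries = []
    kinetics_truth: dict[str, dict[str, float]] = {}
    for i in covered:
        src, dst = edges[i]
        substrate = _chebi(src)
        if i % 2 == 0:
            vmax = float(np.round(rng.uniform(0.5, 5.0), 4))
            km = float(np.round(rng.uniform(0.1, 2.0), 4))
            entries.append({
                "id": f"K{i + 1:03d}",
                "reactants": [substrate], "products": [_chebi(dst)],
                "modifiers": [_uniprot(i)],
                "rate_law": f"Vmax*{substrate}/(Km+{substrate})",
                "parameters": {"Vmax": {"value": vmax, "unit": "mM/s"},
                               "Km": {"value": km, "unit": "mM"}},
                "conditions": {"pH": 7.0, "temperature": 30.0,
                               "organism": "synthetic"},
            })
            kinetics_truth[f"R{i + 1:03d}"] = {"Vmax": vmax, "Km": km}
        else:
            k = float(np.round(rng.uniform(0.2, 2.0), 4))
            entries.append({
                "id": f"K{i + 1:03d}",
                "reactants": [substrate], "products": [_chebi(dst)],
                "modifiers": [_uniprot(i)],
                "rate_law": f"k*{substrate}",
                "parameters": {"k": {"value": k, "unit": "1/s"}},
                "conditions": {"organism": "synthetic"},
            })
            kinetics_truth[f"R{i + 1:03d}"] = {"k": k}
    kinetics = {"entries": entries}

    # enzyme concentrations for every protein; metabolites only partially
    records = [
        {"accession": _uniprot(i),
         "value": float(np.round(rng.uniform(0.001, 0.1), 6)),
         "unit": "mM", "condition": "turbidostat"}
        for i in range(n_reactions)
    ]
    measured_mets = [i for i in range(n_mets) if i % 2 == 0]
    records += [
        {"accession": _chebi(i),
         "value": float(np.round(rng.uniform(0.2, 5.0), 6)),
         "unit": "mM", "condition": "turbidostat"}
        for i in measured_mets
    ]
    key_results = {"records": records}

    # seeded truth rate constants for reactions left without kinetics
    fallback = [i for i in range(n_reactions) if i not in covered]
    truth = {
        "seed": seed,
        "kinetics_params": kinetics_truth,
        "rate_constants": {
            f"R{i + 1:03d}": {"k_f": float(np.round(rng.uniform(0.2, 2.0), 4))}
            for i in fallback
        },
        "concentrations": {r["accession"]: r["value"] for r in records},
    }

    out = {"network": network, "kinetics": kinetics,
           "key_results": key_results, "truth": truth}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("network", "kinetics", "key_results", "truth"):
            p = out_dir / f"{name}.json"
            _dump(out[name], p)
            paths[name] = p
        out["paths"] = paths
    return out


def glycolysis_fixture(out_dir: Union[str, Path, None] = None,
                       seed: int = 0) -> dict:
    """Eleven-reaction glycolysis-shaped chain carrying the twelve ORFs.

    Both phosphofructokinase subunits (YGR240C, YMR205C) catalyse one
    reaction; kinetics entries exist only for the aldolase and pyruvate
    decarboxylase steps, so every other reaction exercises the mass-action
    failsafe.
    """
    # one catalysing ORF set per chain step, PFK subunits together
    step_orfs = [
        ["YFR053C"],              # hexokinase
        ["YBR196C"],              # phosphoglucose isomerase
        ["YGR240C", "YMR205C"],   # phosphofructokinase (two subunits)
        ["YKL060C"],              # aldolase (FBA1) -- kinetics deposited
        ["YDR050C"],              # triose phosphate isomerase
        ["YJL052W"],              # GAPDH
        ["YCR012W"],              # phosphoglycerate kinase
        ["YKL152C"],              # phosphoglycerate mutase
        ["YGR254W"],              # enolase
        ["YAL038W"],              # pyruvate kinase
        ["YLR044C"],              # pyruvate decarboxylase (PDC1) -- kinetics
    ]
    n = len(step_orfs)
    rng = np.random.default_rng(seed)
    uniprot = {orf: _uniprot(i + 100)
               for i, orf in enumerate(GLYCOLYSIS_ORFS)}

    network = {
        "compartments": [{"id": "cytosol", "name": "cytosol"}],
        "metabolites": [
            {"id": f"M{i:03d}", "name": f"glycolytic intermediate {i}",
             "chebi": _chebi(100 + i), "compartment": "cytosol"}
            for i in range(n + 1)
        ],
        "proteins": [
            {"orf": orf, "name": f"glycolytic enzyme {orf}",
             "uniprot": uniprot[orf]}
            for orf in GLYCOLYSIS_ORFS
        ],
        "reactions": [
            {"id": f"G{i + 1:03d}", "name": f"glycolysis step {i + 1}",
             "compartment": "cytosol",
             "reactants": [{"metabolite": f"M{i:03d}", "stoichiometry": 1}],
             "products": [{"metabolite": f"M{i + 1:03d}", "stoichiometry": 1}],
             "enzymes": step_orfs[i],
             "pathways": ["glycolysis"],
             "reversible": False}
            for i in range(n)
        ],
        "pathways": ["glycolysis"],
    }

    entries = []
    kinetics_truth = {}
    # kinetics deposited for the aldolase (step 4) and PDC (step 11) steps
    for step, orf in ((3, "YKL060C"), (10, "YLR044C")):
        substrate = _chebi(100 + step)
        vmax = float(np.round(rng.uniform(0.5, 5.0), 4))
        km = float(np.round(rng.uniform(0.1, 2.0), 4))
        entries.append({
            "id": f"KG{step + 1:03d}",
            "reactants": [substrate], "products": [_chebi(100 + step + 1)],
            "modifiers": [uniprot[orf]],
            "rate_law": f"Vmax*{substrate}/(Km+{substrate})",
            "parameters": {"Vmax": {"value": vmax, "unit": "mM/s"},
                           "Km": {"value": km, "unit": "mM"}},
            "conditions": {"pH": 6.8, "temperature": 30.0,
                           "organism": "synthetic"},
        })
        kinetics_truth[f"G{step + 1:03d}"] = {"Vmax": vmax, "Km": km}
    kinetics = {"entries": entries}

    records = [
        {"accession": uniprot[orf],
         "value": float(np.round(rng.uniform(0.001, 0.05), 6)),
         "unit": "mM", "condition": "turbidostat"}
        for orf in GLYCOLYSIS_ORFS
    ]
    records += [
        {"accession": _chebi(100 + i),
         "value": float(np.round(rng.uniform(0.2, 5.0), 6)),
         "unit": "mM", "condition": "turbidostat"}
        for i in range(0, n + 1, 2)
    ]
    key_results = {"records": records}

    truth = {
        "seed": seed,
        "kinetics_params": kinetics_truth,
        "rate_constants": {
            f"G{i + 1:03d}": {"k_f": float(np.round(rng.uniform(0.2, 2.0), 4))}
            for i in range(n) if f"G{i + 1:03d}" not in kinetics_truth
        },
        "concentrations": {r["accession"]: r["value"] for r in records},
    }

    out = {"network": network, "kinetics": kinetics,
           "key_results": key_results, "truth": truth}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("network", "kinetics", "key_results", "truth"):
            p = out_dir / f"{name}.json"
            _dump(out[name], p)
            paths[name] = p
        out["paths"] = paths
    return out


def generate_measurements(
    model: Model,
    t_end: float,
    n_timepoints: int,
    noise_cv: float = 0.0,
    seed: int = 0,
    species_ids: Optional[Sequence[str]] = None,
    out_path: Union[str, Path, None] = None,
) -> ResultSet:
    """Simulate *model* and perturb with multiplicative lognormal noise.

    The lognormal factor has unit mean and coefficient of variation
    *noise_cv* (``noise_cv=0`` reproduces the simulation exactly).
    Deterministic per seed.
    """
    tc = simulate(model, t_end=t_end, n_points=n_timepoints)
    rs = timecourse_to_resultset(tc, method="synthetic measurements")
    if species_ids is not None:
        keep = [i for i, cb in enumerate(rs.columns)
                if cb.entity in set(species_ids)]
        rs = ResultSet(model_ref=rs.model_ref, operation="experiment",
                       method=rs.method,
                       columns=[rs.columns[i] for i in keep],
                       times=rs.times, values=rs.values[:, keep])
    else:
        rs = ResultSet(model_ref=rs.model_ref, operation="experiment",
                       method=rs.method, columns=rs.columns,
                       times=rs.times, values=rs.values)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = float(np.sqrt(np.log1p(noise_cv ** 2)))
        factors = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma,
                                size=rs.values.shape)
        rs.values = rs.values * factors
    if out_path is not None:
        Path(out_path).write_text(write_sbrml(rs))
    return rs


def recovery_study(
    n_replicates: int,
    noise_cv: float,
    seed: int = 0,
    k_true: float = 0.7,
    t_end: float = 3.0,
    n_timepoints: int = 12,
    max_evaluations: int = 400,
) -> dict:
    """Repeated single-parameter recovery on a first-order decay model.

    Each replicate simulates A -> B at the hidden rate constant *k_true*,
    perturbs the trajectory with multiplicative lognormal noise of the
    given coefficient of variation, and refits the constant starting from
    the failsafe value of one.  Returns the per-replicate relative errors
    and whether every fit improved (or matched) its starting objective.
    """
    from fractions import Fraction

    from .calibrate import FitParameter, FitSpec, calibrate
    from .model import Compartment, Reaction, Species
    from .parameterise import mass_action_fallback

    def decay(k: float) -> Model:
        rxn = Reaction("r_1", reactants=[("s_A", Fraction(1))],
                       products=[("s_B", Fraction(1))], reversible=False)
        rxn.kinetic_law = mass_action_fallback(rxn)
        rxn.kinetic_law.local_parameters[0].value = k
        return Model(
            id="decay", compartments=[Compartment("c_c")],
            species=[Species("s_A", "A", "c_c", initial_concentration=1.0),
                     Species("s_B", "B", "c_c", initial_concentration=0.0)],
            reactions=[rxn])

    rel_errors: list[float] = []
    fitted_values: list[float] = []
    objective_decreased = True
    for i in range(n_replicates):
        data = generate_measurements(
            decay(k_true), t_end=t_end, n_timepoints=n_timepoints,
            noise_cv=noise_cv, seed=seed * 10_000 + i)
        spec = FitSpec(
            parameters=[FitParameter("r_1.k_f", 0.01, 10.0)],
            max_evaluations=max_evaluations, seed=seed + i)
        _, report = calibrate(decay(1.0), data, spec)
        k_hat = report.fitted["r_1.k_f"]
        fitted_values.append(k_hat)
        rel_errors.append(abs(k_hat - k_true) / k_true)
        objective_decreased &= (report.final_objective
                                <= report.initial_objective)
    return {
        "k_true": k_true,
        "noise_cv": noise_cv,
        "fitted": fitted_values,
        "relative_errors": rel_errors,
        "median_relative_error": float(np.median(rel_errors)),
        "objective_never_increased": objective_decreased,
    }
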