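# Methods

This document records the modelling conventions, matching semantics,
numerical choices and known limitations of the pipeline. Defaults quoted
here are the code's actual defaults.

## Units

All quantities are normalised at store-load time to package units:
**millimolar (mM)** for concentrations and **seconds** for time. Rate
parameters tagged `mM/s`, `1/s`, `mM`, `M`, `uM` or `dimensionless` in
store files are converted on ingestion (`units.py`); models therefore
never mix units internally. SBML documents declare matching unit
definitions (`mM`, `mM_per_s`, `per_s`).

## Stage 1 — qualitative assembly

The network store is a JSON file of compartments, metabolites (with ChEBI
accessions), proteins (ORF plus UniProt accession) and reactions
(stoichiometric participants, catalysing ORFs, pathway labels). Queries
select reactions either by an explicit ORF list or by exact
(case-insensitive) pathway name. Assembly is deterministic: records are
processed in reaction-id order and species are keyed by
(accession, compartment) so shared metabolites merge.

Annotation policy:

- metabolite species: `is` → ChEBI URI, SBO:0000247;
- enzyme species (added as reaction modifiers): `is` → UniProt URI,
  SBO:0000252;
- reactions: `isVersionOf` → the catalysing enzymes' UniProt URIs
  (falling back to `hasPart` ChEBI URIs when no enzyme is recorded).

Legacy `urn:miriam:...` identifiers are normalised to
`https://identifiers.org/...` URIs on input. The emitted SBML is Level 3
Version 1; documents are checked with the serialisation library's full
consistency validator, and writing refuses structurally invalid models
outright (duplicate ids, dangling references, negative quantities).

An ORF query that matches nothing warns and returns a valid empty model
rather than failing, and unknown ORFs are reported by name.

## Stage 2 — parameterisation

Each reaction is reduced to an **identifier signature**: the sorted
multiset of reactant accessions, the sorted multiset of product
accessions, and the set of modifier (enzyme) accessions. Kinetics-store
entries carry the same signature plus an infix rate law written over
accessions and parameter names. Matching never uses names, only
accessions. Candidates are ranked:

1. exact signature match;
2. reverse-direction match (substrates/products swapped);
3. same chemistry but a different enzyme (advisory; reported as a
   modifier mismatch).

An optional tolerance ignores ubiquitous cofactors (water and protons by
default) on both sides of the comparison. Within a rank, candidates are
ordered by entry id, and the default policy takes the first; a custom
chooser can be injected.

A matched law is bound by substituting species ids for accessions; a law
that references an accession absent from the reaction is a binding
error, upon which the next candidate is tried. If no candidate survives,
the **mass-action failsafe** applies:

```
v = k_f · ∏ reactant_i^stoich_i          (irreversible)
v = k_f · ∏ reactant^s − k_r · ∏ product^s   (reversible)
```

with every rate constant set to **1**. This guarantees a simulatable
model from any assembled network; the provenance report lists, per
reaction, whether its law was matched (and from which entry, at which
rank) or is the failsafe.

Starting concentrations come from the key-results store by accession
(UniProt for enzymes, ChEBI for metabolites). Metabolites without a
record default to 1 mM and are flagged; enzymes without a record are
listed separately.

## Stage 3 — calibration

Free parameters are named by locator — a global parameter id or
`reaction_id.local_id` — each with finite bounds. The objective is the
(optionally per-column inverse-variance weighted) sum of squared
residuals between the simulated trajectories sampled at the measurement
time points and the measured values.

The optimiser is a reproducible two-stage scheme: seeded differential
evolution (Sobol initialisation, deferred updating, no polish) followed
by bounded Nelder–Mead refinement. The best point ever evaluated —
including the starting point — is retained, so the final objective can
never exceed the initial one. A failed simulation inside the loop is
charged a large finite penalty (10¹²) instead of aborting the fit.
Defaults: 2000 objective evaluations, simulation tolerances relaxed to
rtol 10⁻⁶ / atol 10⁻⁹ inside the loop. The fit report records fitted
values, whether each landed on a bound (within 10⁻⁶ of the span),
initial/final objectives, the improvement trace, per-point residuals and
the evaluation count.

## Stage 4 — simulation

A model induces dx/dt = N·v(x) with N the species-by-reaction
stoichiometry matrix and v the compiled rate laws. Boundary species are
clamped (and emitted bit-identical to their initial values); species
appearing only as modifiers get all-zero stoichiometry rows and stay
constant. Integration uses LSODA with rtol 10⁻⁸ / atol 10⁻¹⁰. A
divergence guard aborts cleanly when the state exceeds 10¹² in magnitude
or turns non-finite, instead of letting step-size control stall on a
finite-time blow-up. Trajectories that dip below −atol trigger a warning
and are floored at zero. Accuracy is verified in the test suite against
the analytic solution of first-order decay (|error| < 10⁻⁶), linear
conservation laws (< 10⁻⁸ drift) and an independent fixed-step
fourth-order Runge–Kutta oracle (< 10⁻⁵ divergence).

## Results dialect

Time courses and measurements travel in a small XML results dialect
(namespace `https://pathwaykit.dev/sbrml-subset/1`): one 2-D table of
strictly increasing time against entity columns. Columns bind to model
species either by id or by annotation URI; unresolvable columns are
reported by name. Cell values are written with `repr`-level precision,
so write→read round-trips are exact. Tabular data (lists of dicts keyed
by accession) can be imported directly against a model, with unmatched
headers returned rather than silently dropped.

## Synthetic fixtures

`fixtures.py` generates chain- or branched-topology toy pathways with a
seeded ground-truth record of every parameter, using reserved accession
namespaces (`CHEBI:TEST…`, `TESTP…`) that cannot collide with curated
identifiers. A glycolysis-shaped fixture labels an 11-reaction chain
with the 12 canonical yeast glycolytic ORFs (both phosphofructokinase
subunits on one step) and deposits kinetics for exactly two steps, so
assembly, matching and the failsafe are all exercised. Measurement
generation perturbs simulated trajectories with multiplicative lognormal
noise of unit mean and specified coefficient of variation. All fixture
files are written with sorted keys and fixed formatting, making every
artefact byte-identical across reruns for a fixed seed.

## Limitations

- SBML support is deliberately a subset: events, rules, function
  definitions, constraints and initial assignments are rejected on read
  with a clear error rather than half-interpreted.
- Rate-law expressions support `+ − * / ^`, numbers and identifiers
  only; no piecewise functions or delays.
- Signature matching is exact on accession multisets (modulo the
  cofactor-ignore tolerance); there is no similarity scoring across
  different chemistries.
- The calibrator fits rate parameters only, not initial concentrations,
  and assumes independent Gaussian-like residuals in its least-squares
  objective.
- Simulations are deterministic ODE integrations; no stochastic kinetics.
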