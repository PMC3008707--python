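"""Calibration: objective correctness against an independent residual sum,
parameter recovery, bound handling, and seeded determinism."""

import copy
from fractions import Fraction

import numpy as np
import pytest

from pathwaykit.calibrate import (
    FitParameter,
    FitSpec,
    calibrate,
    objective,
)
from pathwaykit.fixtures import generate_measurements
from pathwaykit.model import Compartment, Model, Reaction, Species
from pathwaykit.ode import simulate
from pathwaykit.parameterise import mass_action_fallback
from pathwaykit.sbrml import ColumnBinding, ResultSet, timecourse_to_resultset


def decay_model(k: float = 1.0) -> Model:
    rxn = Reaction("r_1", reactants=[("s_A", Fraction(1))],
                   products=[("s_B", Fraction(1))], reversible=False)
    rxn.kinetic_law = mass_action_fallback(rxn)
    rxn.kinetic_law.local_parameters[0].value = k
    return Model(
        id="decay", compartments=[Compartment("c_c")],
        species=[Species("s_A", "A", "c_c", initial_concentration=1.0),
                 Species("s_B", "B", "c_c", initial_concentration=0.0)],
        reactions=[rxn])


def decay_spec(lower=0.01, upper=10.0, **kw) -> FitSpec:
    return FitSpec(parameters=[FitParameter("r_1.k_f", lower, upper)], **kw)


class TestObjective:
    def test_self_consistency_is_zero(self):
        m = decay_model(k=0.7)
        data = timecourse_to_resultset(simulate(m, t_end=2.0, n_points=9))
        spec = decay_spec(sim_rtol=1e-10, sim_atol=1e-12)
        assert objective(m, data, spec, np.array([0.7])) < 1e-10

    def test_single_datapoint_residual_two_gives_four(self):
        m = decay_model(k=1.0)
        # at t=0 the solver returns the initial state exactly: s_A = 1
        data = ResultSet(model_ref="decay",
                         columns=[ColumnBinding("s_A", "s_A")],
                         times=np.array([0.0]), values=np.array([[3.0]]))
        assert objective(m, data, decay_spec(),
                         np.array([1.0])) == pytest.approx(4.0)

    def test_matches_independent_residual_sum(self, glyco_quant):
        quant, report = glyco_quant
        data = generate_measurements(quant, t_end=5.0, n_timepoints=7,
                                     noise_cv=0.1, seed=3)
        fallback = [o.reaction_id for o in report.reactions
                    if o.provenance == "fallback_mass_action"]
        spec = FitSpec(parameters=[
            FitParameter(f"{fallback[0]}.k_f", 0.01, 10.0),
            FitParameter(f"{fallback[1]}.k_f", 0.01, 10.0)])
        rng = np.random.default_rng(11)
        for _ in range(3):
            theta = rng.uniform(0.1, 3.0, size=2)
            ours = objective(quant, data, spec, theta)
            # independent recomputation: set values, simulate, sum squares
            m2 = copy.deepcopy(quant)
            for fp, v in zip(spec.parameters, theta):
                rid, pid = fp.locator.split(".")
                for p in m2.reaction_by_id(rid).kinetic_law.local_parameters:
                    if p.id == pid:
                        p.value = v
            tc = simulate(m2, t_end=5.0, n_points=1000,
                          rtol=1e-10, atol=1e-12)
            expected = 0.0
            for j, cb in enumerate(data.columns):
                sim = np.interp(data.times, tc.times, tc.series(cb.entity))
                expected += float(np.sum((sim - data.values[:, j]) ** 2))
            assert ours == pytest.approx(expected, rel=1e-4)


class TestCalibrate:
    def test_noiseless_one_parameter_recovery(self):
        truth = decay_model(k=0.7)
        data = timecourse_to_resultset(simulate(truth, t_end=3.0, n_points=15))
        start = decay_model(k=1.0)
        fitted, report = calibrate(start, data, decay_spec(seed=4))
        assert report.fitted["r_1.k_f"] == pytest.approx(0.7, rel=0.01)
        assert not report.bounds_hit["r_1.k_f"]

    def test_bounds_excluding_truth_hit_the_boundary(self):
        truth = decay_model(k=0.7)
        data = timecourse_to_resultset(simulate(truth, t_end=3.0, n_points=15))
        start = decay_model(k=2.0)
        fitted, report = calibrate(start, data, decay_spec(lower=1.0, seed=4))
        assert report.fitted["r_1.k_f"] == pytest.approx(1.0, abs=1e-6)
        assert report.bounds_hit["r_1.k_f"]

    def test_final_objective_never_exceeds_initial(self):
        truth = decay_model(k=0.7)
        data = generate_measurements(truth, t_end=3.0, n_timepoints=10,
                                     noise_cv=0.2, seed=8)
        _, report = calibrate(decay_model(k=5.0), data, decay_spec(seed=1))
        assert report.final_objective <= report.initial_objective

    def test_seeded_determinism(self):
        truth = decay_model(k=0.4)
        data = generate_measurements(truth, t_end=3.0, n_timepoints=8,
                                     noise_cv=0.05, seed=2)
        spec = decay_spec(seed=9, max_evaluations=300)
        _, r1 = calibrate(decay_model(k=1.0), data, spec)
        _, r2 = calibrate(decay_model(k=1.0), data, spec)
        assert r1.fitted == r2.fitted
        assert r1.final_objective == r2.final_objective

    def test_no_free_parameters_is_an_error(self):
        data = timecourse_to_resultset(
            simulate(decay_model(), t_end=1.0, n_points=3))
        with pytest.raises(ValueError, match="no free parameters"):
            calibrate(decay_model(), data, FitSpec(parameters=[]))

    def test_unresolvable_data_binding_is_an_error(self):
        from pathwaykit.sbrml import SbrmlError
        data = ResultSet(model_ref="decay",
                         columns=[ColumnBinding("ghost", "s_ghost")],
                         times=np.array([0.0]), values=np.array([[1.0]]))
        with pytest.raises(SbrmlError, match="ghost"):
            calibrate(decay_model(), data, decay_spec())

    def test_bad_locator_is_an_error(self):
        data = timecourse_to_resultset(
            simulate(decay_model(), t_end=1.0, n_points=3))
        spec = FitSpec(parameters=[FitParameter("r_1.nope", 0.1, 1.0)])
        with pytest.raises(KeyError, match="nope"):
            calibrate(decay_model(), data, spec)

    def test_fitted_model_carries_the_fitted_values(self):
        truth = decay_model(k=0.7)
        data = timecourse_to_resultset(simulate(truth, t_end=3.0, n_points=15))
        fitted, report = calibrate(decay_model(k=1.0), data,
                                   decay_spec(seed=4))
        k = fitted.reaction_by_id("r_1").kinetic_law.local_parameters[0]
        assert k.value == report.fitted["r_1.k_f"]


def test_invalid_bounds_rejected():
    with pytest.raises(ValueError, match="bound"):
        FitParameter("k", 2.0, 1.0)
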