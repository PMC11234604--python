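"""Cost function, ensemble optimization and BSA indexing."""

import numpy as np
import pytest

from cardiofit.cv_models import SolverConfig, simulate
from cardiofit.personalization import (
    PENALTY_COST,
    CostWeights,
    MeasurementSet,
    PersonalizationModel,
    bsa,
    cost,
    default_bounds,
    denormalize_by_bsa,
    ensemble_estimate,
    normalize_by_bsa,
    optimize_single,
    typical_parameters,
)


def _perfect_measurement(theta, kind, sv=None, sbp=None, dbp=None):
    """Measurement whose every field equals the model's own output."""
    sim = simulate(theta, kind, SolverConfig(n_samples=100))
    s = sim.summary
    return MeasurementSet(
        waveform=sim.waveform,
        P_sys_m=sbp if sbp is not None else s.P_sys,
        P_dia_m=dbp if dbp is not None else s.P_dia,
        SV_m=sv if sv is not None else s.SV,
        ESV_m=s.ESV_model + 15.0,
        T=theta.T,
        height=174.3,
        weight=85.9,
    )


class TestCost:
    def test_zero_at_perfect_match_open_loop(self, open_params):
        m = _perfect_measurement(open_params, "open")
        assert cost(open_params, m, model_kind="open") == pytest.approx(0.0, abs=1e-9)

    def test_closed_loop_residual_is_only_the_venous_term(self, closed_params):
        # with a perfect waveform match, J reduces to the MVP soft constraint
        m = _perfect_measurement(closed_params, "closed")
        w = CostWeights()
        sim = simulate(closed_params, "closed", SolverConfig(n_samples=100))
        n = m.waveform.N
        expected = (7.5 * n / 40.0) ** 2 / 9.0 * ((6.0 - sim.summary.MVP) / w.K_MVP) ** 2
        assert cost(closed_params, m, w, "closed") == pytest.approx(expected, rel=1e-6)

    def test_stroke_volume_mismatch_of_one_k_sv(self, open_params):
        # SV residual equal to K_SV contributes exactly 7.5²N²/40² = 351.5625
        w = CostWeights()
        sim = simulate(open_params, "open", SolverConfig(n_samples=100))
        m = _perfect_measurement(open_params, "open", sv=sim.summary.SV + w.K_SV)
        n = m.waveform.N
        assert n == 100
        assert cost(open_params, m, w, "open") == pytest.approx(
            7.5**2 * n**2 / 40.0**2, rel=1e-9
        )
        assert 7.5**2 * 100**2 / 40.0**2 == pytest.approx(351.5625)

    def test_uniform_pressure_offset_contributes_n(self, open_params):
        # each sample off by exactly K_p: the waveform pressure term sums to N,
        # while the extrema terms add (7.5N/40)²·(K_p/K_sys)²·2
        w = CostWeights()
        m = _perfect_measurement(open_params, "open")
        m.waveform.P_ao += w.K_p
        m.P_sys_m += w.K_p
        m.P_dia_m += w.K_p
        n = m.waveform.N
        extrema = (7.5 * n / 40.0) ** 2 * (
            (w.K_p / w.K_p_sys) ** 2 + (w.K_p / w.K_p_dia) ** 2
        )
        assert cost(open_params, m, w, "open") == pytest.approx(n + extrema, rel=1e-9)

    def test_penalty_for_non_convergent_simulation(self, open_params):
        m = _perfect_measurement(open_params, "open")
        j = cost(open_params, m, model_kind="open", solver=SolverConfig(max_cycles=1))
        assert j == PENALTY_COST


class TestOptimization:
    def test_start_at_truth_stays_at_truth(self, open_measurement):
        m, truth = open_measurement
        bounds = default_bounds("open")
        est = optimize_single(m, truth.replace(T=m.T), bounds, model_kind="open")
        assert est.converged
        assert est.final_cost < 1e-4
        assert est.theta.R_sys == pytest.approx(truth.R_sys, rel=0.01)

    def test_perturbed_start_recovers_resistance(self, open_measurement):
        m, truth = open_measurement
        bounds = default_bounds("open")
        x0 = truth.replace(T=m.T, R_sys=truth.R_sys * 1.2, C_ao=truth.C_ao * 0.8)
        est = optimize_single(m, x0, bounds, model_kind="open")
        assert est.theta.R_sys == pytest.approx(truth.R_sys, rel=0.05)

    def test_start_outside_bounds_is_an_input_error(self, open_measurement):
        m, truth = open_measurement
        bounds = default_bounds("open")
        lo, _ = bounds["R_sys"]
        x0 = truth.replace(T=m.T, R_sys=lo * 0.5)
        with pytest.raises(ValueError, match="R_sys"):
            optimize_single(m, x0, bounds, model_kind="open")

    def test_filter_rule_keeps_costs_within_twice_best(self, open_measurement):
        costs = np.array([1.0, 1.5, 10.0])
        converged = np.array([True, True, True])
        best = costs[converged].min()
        kept = converged & (costs <= 2.0 * best)
        assert kept.tolist() == [True, True, False]

    def test_ensemble_determinism(self, open_measurement):
        m, _ = open_measurement
        kw = dict(n_starts=2, seed=5, model_kind="open", maxfev=150)
        a = ensemble_estimate(m, **kw)
        b = ensemble_estimate(m, **kw)
        assert a.theta_mean.to_dict() == b.theta_mean.to_dict()
        assert np.array_equal(a.kept_mask, b.kept_mask)
        assert [x.final_cost for x in a.members] == [x.final_cost for x in b.members]

    def test_ensemble_filtering_and_averaging(self, open_measurement):
        m, truth = open_measurement
        ens = ensemble_estimate(m, n_starts=4, seed=2, model_kind="open")
        assert 1 <= ens.n_kept <= 4
        kept_members = [mm for mm, k in zip(ens.members, ens.kept_mask) if k]
        mean_rsys = np.mean([mm.theta.R_sys for mm in kept_members])
        assert ens.theta_mean.R_sys == pytest.approx(mean_rsys)
        best = min(mm.final_cost for mm in ens.members if mm.converged)
        assert all(mm.final_cost <= 2.0 * best for mm in kept_members)
        lo, hi = default_bounds("open")["R_sys"]
        assert lo <= ens.theta_mean.R_sys <= hi
        # spread over identical members would be zero; here it is finite
        assert all(v >= 0 for v in ens.spread.values())

    def test_model_results_summary_mentions_parameters(self, open_measurement):
        m, _ = open_measurement
        res = PersonalizationModel(m, model_kind="open").fit(n_starts=2, seed=0, maxfev=200)
        text = res.summary()
        assert "R_sys" in text and "C_ao" in text
        assert res.params_indexed.bsa_indexed


class TestBSA:
    def test_printed_population_mean(self):
        # mean height 174.3 cm and weight 85.9 kg give a BSA that prints as 2.0 m²
        assert bsa(174.3, 85.9) == pytest.approx(2.039, abs=0.001)
        assert round(bsa(174.3, 85.9), 1) == 2.0

    def test_unit_and_exact_cases(self):
        assert bsa(60.0, 60.0) == pytest.approx(1.0)
        assert bsa(180.0, 80.0) == pytest.approx(2.0)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            bsa(0.0, 80.0)

    def test_normalization_divides_mechanical_parameters(self, closed_params):
        indexed = normalize_by_bsa(closed_params, 2.0)
        assert indexed.R_sys == pytest.approx(closed_params.R_sys / 2.0)
        assert indexed.C_ao == pytest.approx(closed_params.C_ao / 2.0)
        assert indexed.V_tot == pytest.approx(closed_params.V_tot / 2.0)
        assert indexed.T == closed_params.T  # timing parameters untouched
        assert indexed.t_peak == closed_params.t_peak
        assert indexed.bsa_indexed

    def test_identity_at_unit_bsa(self, open_params):
        indexed = normalize_by_bsa(open_params, 1.0)
        assert indexed.R_sys == open_params.R_sys

    def test_round_trip_is_exact(self, closed_params):
        b = bsa(174.3, 85.9)
        back = denormalize_by_bsa(normalize_by_bsa(closed_params, b), b)
        for name in ("R_sys", "C_ao", "E_max", "V_tot"):
            assert getattr(back, name) == pytest.approx(getattr(closed_params, name), rel=1e-12)
        assert not back.bsa_indexed

    def test_double_normalization_rejected(self, closed_params):
        indexed = normalize_by_bsa(closed_params, 2.0)
        with pytest.raises(ValueError):
            normalize_by_bsa(indexed, 2.0)
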