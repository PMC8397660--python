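"""Coupled PK -> PD -> life-cycle simulation of patients and cohorts."""

import numpy as np
import pytest

from neutrosim.endpoints import daily_anc
from neutrosim.pkpd import PDParams, Regimen
from neutrosim.simulate import ANCSeries, SolverError, simulate_cohort, simulate_patient

from conftest import SCREEN


class TestANCSeries:
    def test_validation(self):
        with pytest.raises(ValueError):
            ANCSeries(np.array([0.0, 0.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            ANCSeries(np.array([0.0, 1.0]), np.array([1.0, -2.0]))

    def test_censoring_excludes_points(self):
        s = ANCSeries(np.array([0.0, 24.0, 48.0]), np.array([3e9, 2e9, 1e9]),
                      censored_after=40.0)
        u = s.uncensored()
        assert u.times.tolist() == [0.0, 24.0]


class TestSinglePatient:
    def test_zero_dose_holds_baseline(self, dlbcl_traits, pk_default, pd_default):
        res = simulate_patient(dlbcl_traits, pk_default, pd_default,
                               Regimen(0.0, 28, 0))
        assert np.all(np.abs(res.series.anc / dlbcl_traits.circ0 - 1) < 1e-3)
        # and every compartment stays within 0.1% of its starting level
        y0 = res.params.initial_state().as_array()
        assert np.all(np.abs(res.states / y0 - 1) < 1e-3)

    def test_zero_emax_equals_zero_dose(self, dlbcl_traits, pk_default, pd_default):
        no_pd = PDParams(emax=0.0, ec50=pd_default.ec50, n_hill=pd_default.n_hill)
        res_drug = simulate_patient(dlbcl_traits, pk_default, no_pd,
                                    Regimen(6.0, 28, 0))
        res_none = simulate_patient(dlbcl_traits, pk_default, pd_default,
                                    Regimen(0.0, 28, 0))
        assert np.allclose(res_drug.series.anc, res_none.series.anc, rtol=1e-9)

    def test_bit_identical_reruns(self, dlbcl_traits, pk_default, pd_default):
        reg = Regimen(4.0, 5, 2)
        a = simulate_patient(dlbcl_traits, pk_default, pd_default, reg)
        b = simulate_patient(dlbcl_traits, pk_default, pd_default, reg)
        assert np.array_equal(a.series.anc, b.series.anc)
        assert np.array_equal(a.states, b.states)

    def test_median_lymphoma_profile_shape(self, dlbcl_traits, pk_default, pd_default):
        """Daily dosing at 3 mg: ANC stable through day 8, clearly dropping
        by mid-cycle, with the nadir after day 15."""
        res = simulate_patient(dlbcl_traits, pk_default, pd_default,
                               Regimen(3.0, 28, 0))
        daily = daily_anc(res.series)
        c0 = dlbcl_traits.circ0
        assert daily[7] > 0.85 * c0         # near-baseline at day 8
        assert daily[19] < 0.65 * c0        # dropped by day 20
        assert int(np.argmin(daily)) + 1 >= 15

    def test_stiff_solution_matches_fixed_step_rk4_oracle(
        self, dlbcl_traits, pk_default, pd_default
    ):
        """LSODA trajectory vs an independently coded fixed-step RK4 of the
        same equations at h=0.01 h over 48 h, drug-free and at constant
        half-block."""
        from neutrosim.lifecycle import derive_homeostatic_parameters

        p = derive_homeostatic_parameters(dlbcl_traits)

        def deriv(y, eff):
            prol, t1, t2, t3, res, circ = y
            fb_p = min((p.transit2_homeostatic / max(t2, 1.0)) ** p.gamma, 1e3)
            fb_e = min((p.circ_homeostatic / max(circ, 1.0)) ** p.beta, 1e3)
            mm = p.v_max * eff * t2 / (p.k_m + t2)
            return np.array([
                p.k_prol * fb_p * prol - p.k_tr1 * prol,
                p.k_tr1 * prol - (p.k_tr2 + p.k_d) * t1,
                p.k_tr2 * t1 - mm - p.k_d * t2,
                mm - (p.k_tr4 + p.k_d) * t3,
                p.k_tr4 * t3 - p.k_d * res - p.k_out * fb_e * res,
                p.k_out * fb_e * res - p.k_elim * circ,
            ])

        for eff_const in (1.0, 0.5):
            h = 0.01
            y = p.initial_state().as_array()
            rk4 = [y.copy()]
            for step in range(4800):
                k1 = deriv(y, eff_const)
                k2 = deriv(y + h / 2 * k1, eff_const)
                k3 = deriv(y + h / 2 * k2, eff_const)
                k4 = deriv(y + h * k3, eff_const)
                y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                if (step + 1) % 100 == 0:
                    rk4.append(y.copy())
            rk4 = np.array(rk4)

            grid = np.arange(0.0, 48.5, 1.0)
            res = simulate_patient(
                dlbcl_traits, pk_default, pd_default, Regimen(0.0, 28, 0),
                horizon_days=28,
                effect_grid=np.full(673, eff_const),
            )
            lsoda = res.states[:49]
            assert np.max(np.abs(lsoda - rk4) / rk4) < 1e-4

    def test_nadir_nonincreasing_in_dose(self, dlbcl_traits, pk_default, pd_default):
        nadirs = []
        for dose in (2.0, 4.0, 6.0, 8.0):
            res = simulate_patient(dlbcl_traits, pk_default, pd_default,
                                   Regimen(dose, 5, 2), **SCREEN)
            nadirs.append(res.series.anc.min())
        assert all(a >= b for a, b in zip(nadirs, nadirs[1:]))

    def test_anc_monotone_in_dose_at_fixed_late_times(
        self, dlbcl_traits, pk_default, pd_default
    ):
        """Under daily dosing the simulated ANC at any fixed day >= 15 must
        not increase with dose."""
        dailies = []
        for dose in (2.0, 4.0, 6.0, 8.0):
            res = simulate_patient(dlbcl_traits, pk_default, pd_default,
                                   Regimen(dose, 28, 0), **SCREEN)
            dailies.append(daily_anc(res.series))
        for day_idx in (14, 17, 20, 27):
            vals = [d[day_idx] for d in dailies]
            assert all(a >= b * (1 - 1e-6) for a, b in zip(vals, vals[1:]))

    def test_reservoir_depletion_precedes_anc_decline(
        self, dlbcl_traits, pk_default, pd_default
    ):
        for dose in (3.0, 6.0):
            res = simulate_patient(dlbcl_traits, pk_default, pd_default,
                                   Regimen(dose, 28, 0), **SCREEN)
            reserv = res.states[:, 4]
            circ = res.states[:, 5]
            t = res.series.times
            t_res = t[np.argmax(reserv < 0.5 * reserv[0])]
            below = circ < 0.9 * circ[0]
            assert below.any()
            t_circ = t[np.argmax(below)]
            assert t_res <= t_circ


class TestCohort:
    def test_identical_patients_identical_series(self, dlbcl_traits, pk_default,
                                                 pd_default):
        results = simulate_cohort([dlbcl_traits] * 3, pk_default, pd_default,
                                  Regimen(4.0, 5, 2), **SCREEN)
        assert np.array_equal(results[0].series.anc, results[1].series.anc)
        assert np.array_equal(results[1].series.anc, results[2].series.anc)

    def test_empty_cohort_rejected(self, pk_default, pd_default):
        with pytest.raises(ValueError):
            simulate_cohort([], pk_default, pd_default, Regimen(4.0, 5, 2))

    def test_failure_reports_patient_index(self, dlbcl_traits, pk_default,
                                           pd_default, monkeypatch):
        import neutrosim.simulate as sim

        def boom(*args, **kwargs):
            raise RuntimeError("synthetic failure")

        monkeypatch.setattr(sim, "simulate_patient", boom)
        with pytest.raises(SolverError, match="patient 0"):
            sim.simulate_cohort([dlbcl_traits], pk_default, pd_default,
                                Regimen(4.0, 5, 2))

    def test_interrupted_schedule_recovers_after_last_dose(
        self, small_cohort, pk_default, pd_default
    ):
        """21-on/7-off: cohort-median ANC at day 28 exceeds day 21 (recovery
        once dosing stops), and 21/28 reaches a deeper median nadir than 5/7
        at equal dose with a larger post-day-21 rebound."""
        res_21 = simulate_cohort(small_cohort, pk_default, pd_default,
                                 Regimen(6.0, 21, 7), **SCREEN)
        res_57 = simulate_cohort(small_cohort, pk_default, pd_default,
                                 Regimen(6.0, 5, 2), **SCREEN)
        daily_21 = np.array([daily_anc(r.series) for r in res_21])
        daily_57 = np.array([daily_anc(r.series) for r in res_57])
        med_21 = np.median(daily_21, axis=0)
        med_57 = np.median(daily_57, axis=0)
        assert med_21[27] > med_21[20]
        assert med_21.min() < med_57.min()
        rebound_21 = med_21[27] - med_21.min()
        rebound_57 = med_57[27] - med_57.min()
        assert rebound_21 > rebound_57
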