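"""SPR steady-state/kinetic and ITC one-set-of-sites models and fits."""

import numpy as np
import pytest
from scipy.optimize import bisect

from pipflank.binding import (
    AffinityRecord,
    Injection,
    ITCExperiment,
    SPRSeries,
    bound_complex,
    itc_fit,
    itc_one_site_model,
    spr_kinetic_fit,
    spr_kinetic_model,
    spr_steady_state_fit,
    spr_steady_state_model,
    thermodynamics,
)
from pipflank.errors import FitConvergenceError, UnreliableFitWarning
from pipflank.simulate import gen_itc, gen_sensorgram, gen_steady_state

P21_KON, P21_KOFF = 1.7e6, 0.14
P21_KD_KIN = P21_KOFF / P21_KON  # ~82 nM


class TestSteadyStateModel:
    def test_high_concentration_plateau_is_rmax_over_n(self):
        assert spr_steady_state_model(1e3, ka=1e7, rmax=100, n=3) \
            == pytest.approx(100 / 3, rel=1e-6)

    def test_half_saturation_at_inverse_ka_n(self):
        c = 1.0 / (1e7 * 2.0)
        assert spr_steady_state_model(c, ka=1e7, rmax=100, n=2.0) \
            == pytest.approx(100 / 2.0 / 2.0)

    def test_direct_evaluation(self):
        assert spr_steady_state_model(1e-7, ka=1e7, rmax=100, n=1) \
            == pytest.approx(50.0)

    def test_strictly_increasing_and_concave_in_c(self):
        c = np.logspace(-9, -4, 60)
        r = spr_steady_state_model(c, ka=1e7, rmax=100, n=1)
        assert (np.diff(r) > 0).all()
        assert (np.diff(np.diff(r) / np.diff(c)) < 0).all()


class TestSteadyStateFit:
    def test_noiseless_self_consistency(self):
        s = gen_steady_state(kd=3e-6, rmax=80.0, rel_noise=0.0)
        rec, rmax = spr_steady_state_fit(s)
        assert rec.kd == pytest.approx(3e-6, rel=1e-6)
        assert rmax == pytest.approx(80.0, rel=1e-6)

    def test_kd_invariant_to_response_rescaling(self):
        s = gen_steady_state(kd=3e-6, rel_noise=0.01, seed=5)
        rec1, _ = spr_steady_state_fit(s)
        scaled = SPRSeries(conc=s.conc, response=s.response * 7.5)
        rec2, _ = spr_steady_state_fit(scaled)
        assert rec2.kd == pytest.approx(rec1.kd, rel=1e-6)

    def test_noisy_msh6_like_recovery(self):
        s = gen_steady_state(kd=3.0e-6, rel_noise=0.01, seed=42)
        rec, _ = spr_steady_state_fit(s)
        assert rec.kd == pytest.approx(3.0e-6, rel=0.10)

    def test_flat_responses_flagged_unreliable(self):
        s = SPRSeries(conc=np.array([1e-7, 1e-6, 1e-5, 1e-4]),
                      response=np.full(4, 50.0))
        with pytest.warns(UnreliableFitWarning):
            rec, _ = spr_steady_state_fit(s)
        assert rec.warnings


class TestKineticModel:
    def test_long_contact_plateau_matches_steady_state(self):
        sched = (Injection(0.0, 500.0, 1e-7),)
        t = np.array([499.9])
        r = spr_kinetic_model(t, sched, kon=1e6, koff=0.1, rmax=100)
        assert r[0] == pytest.approx(
            spr_steady_state_model(1e-7, ka=1e7, rmax=100, n=1), rel=1e-3)

    def test_dissociation_is_exponential(self):
        sched = (Injection(0.0, 90.0, 1e-6),)
        t = np.array([90.0, 100.0, 150.0])
        r = spr_kinetic_model(t, sched, kon=1e6, koff=0.1, rmax=100)
        assert r[1] == pytest.approx(r[0] * np.exp(-0.1 * 10.0), rel=1e-9)
        assert r[2] == pytest.approx(r[0] * np.exp(-0.1 * 60.0), rel=1e-9)

    def test_plateaus_consistent_with_kd(self):
        # p21-like rates: plateau concentration dependence follows KD
        for c in (2e-8, 8.2e-8, 4e-7):
            sched = (Injection(0.0, 5000.0, c),)
            r = spr_kinetic_model(np.array([4999.0]), sched,
                                  P21_KON, P21_KOFF, 100.0)
            assert r[0] == pytest.approx(100.0 * c / (c + P21_KD_KIN),
                                         rel=1e-3)

    def test_continuity_across_injection_boundaries(self):
        s = gen_sensorgram(noise_sigma=0.0)
        eps = 1e-7
        for inj in s.schedule:
            for edge in (inj.t_start, inj.t_end):
                if edge == 0.0:
                    continue
                lo, hi = spr_kinetic_model(
                    np.array([edge - eps, edge + eps]), s.schedule,
                    P21_KON, P21_KOFF, 100.0)
                assert hi == pytest.approx(lo, abs=1e-4)


class TestKineticFit:
    def test_noiseless_rate_recovery(self):
        s = gen_sensorgram(noise_sigma=0.0)
        rec = spr_kinetic_fit(s)
        assert rec.kon == pytest.approx(P21_KON, rel=1e-4)
        assert rec.koff == pytest.approx(P21_KOFF, rel=1e-4)
        assert rec.kd == pytest.approx(rec.koff / rec.kon, rel=1e-9)

    def test_noisy_p21_like_kd_within_5_percent(self):
        s = gen_sensorgram(noise_sigma=2.0, seed=1)  # 2% of Rmax
        rec = spr_kinetic_fit(s)
        assert rec.kd == pytest.approx(P21_KD_KIN, rel=0.05)

    def test_pure_noise_trace_raises(self):
        rng = np.random.default_rng(3)
        s = gen_sensorgram(noise_sigma=0.0)
        noise_only = SPRSeries(
            time=s.time, response=rng.normal(0, 1, len(s.time)),
            schedule=s.schedule)
        with pytest.raises(FitConvergenceError):
            spr_kinetic_fit(noise_only)


def p21_design(**kw):
    return gen_itc(**kw)


class TestItcModel:
    def test_quadratic_matches_bisection(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            p = 10 ** rng.uniform(-7, -3)
            s = 10 ** rng.uniform(-7, -3)
            kd = 10 ** rng.uniform(-10, -3)
            b = bound_complex(p, s, kd)
            root = bisect(lambda x: (p - x) * (s - x) - kd * x,
                          0.0, min(p, s), xtol=1e-20, rtol=8.9e-16)
            assert abs(b - root) <= 1e-10

    def test_stoichiometric_limit_total_heat(self):
        exp = p21_design()
        heats = itc_one_site_model(exp, n=3.0, ka=1e16, dh=-230e3)
        # track the final diluted totals with the same recursion
        p, x = exp.cell_conc, 0.0
        for dv in exp.inj_volumes:
            f = 1 - dv / exp.v0
            p, x = p * f, x * f + exp.syringe_conc * dv / exp.v0
        expected = -230e3 * exp.v0 * min(3.0 * x, p)
        # complex formed then expelled adds slightly to the total magnitude
        assert heats.sum() == pytest.approx(expected, rel=0.2)
        assert abs(heats.sum()) >= abs(expected)

    def test_inflection_near_one_third_trimer_per_peptide(self):
        exp = p21_design(n_injections=60, inj_vol=0.5e-6)
        heats = itc_one_site_model(exp, n=3.0, ka=1 / 67e-9, dh=-230e3)
        # steepest heat change where sites ~ peptide, i.e. trimer:peptide ~ 1:3
        x, p, ratios = 0.0, exp.cell_conc, []
        for dv in exp.inj_volumes:
            f = 1 - dv / exp.v0
            p, x = p * f, x * f + exp.syringe_conc * dv / exp.v0
            ratios.append(x / p)
        drop = np.argmax(np.abs(np.diff(heats)))
        assert ratios[drop] == pytest.approx(1.0 / 3.0, abs=0.12)

    def test_heat_conserved_under_injection_splitting(self):
        def total(vols):
            exp = ITCExperiment(v0=200e-6, cell_conc=10e-6,
                                syringe_conc=40e-6, inj_volumes=vols,
                                heats=np.zeros(len(vols)))
            return itc_one_site_model(exp, 3.0, 1 / 67e-9, -230e3).sum()

        coarse = total(np.full(20, 0.02e-6))
        fine = total(np.full(40, 0.01e-6))
        assert abs(coarse - fine) / abs(coarse) < 1e-6


class TestItcFit:
    def test_noiseless_exact_recovery(self):
        exp = p21_design(rel_noise=0.0)
        rec = itc_fit(exp)
        assert rec.n == pytest.approx(3.0, abs=1e-4)
        assert rec.kd == pytest.approx(67e-9, rel=1e-3)
        assert rec.dH == pytest.approx(-230e3, rel=1e-3)

    def test_noisy_recovery_with_free_n(self):
        exp = p21_design(rel_noise=0.02, seed=8)
        rec = itc_fit(exp)
        assert rec.n == pytest.approx(3.0, abs=0.2)
        assert rec.kd == pytest.approx(67e-9, rel=0.3)

    def test_fix_n_honoured(self):
        exp = p21_design(rel_noise=0.02, seed=9)
        rec = itc_fit(exp, fix_n=3.0)
        assert rec.n == 3.0

    def test_truncated_pre_saturation_requires_fix_n(self):
        exp = p21_design(n_injections=19, syringe_conc=4e-6)  # never saturates
        with pytest.raises(FitConvergenceError, match="fix_n"):
            itc_fit(exp)
        rec = itc_fit(exp, fix_n=3.0)  # the recommended route converges
        assert rec.n == 3.0

    def test_thermodynamic_bookkeeping_identity(self):
        exp = p21_design(rel_noise=0.01, seed=2)
        rec = itc_fit(exp, fix_n=3.0)
        assert rec.dG == pytest.approx(rec.dH + rec.minus_TdS, abs=1e-6)


class TestThermodynamics:
    def test_reference_state_kd_of_one_molar(self):
        dg, _ = thermodynamics(1.0, dh=-1e3)
        assert dg == 0.0

    def test_p21_printed_values(self):
        dg, mtds = thermodynamics(6.7e-8, dh=-230e3, temp_K=298.15)
        assert dg / 1e3 == pytest.approx(-40.9, abs=0.05)
        assert mtds / 1e3 == pytest.approx(189.1, abs=0.1)
        assert abs(dg / 1e3 - (-40.0)) < 17.0  # inside the printed error bar

    def test_kinetic_record_requires_kd_equals_koff_over_kon(self):
        with pytest.raises(ValueError):
            AffinityRecord(ligand_id="x", method="SPR_kinetic",
                           kd=1e-7, kon=1e6, koff=0.2)
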