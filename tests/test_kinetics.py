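"""TAC fitting, TIACs, red marrow, voiding bladder and gut transit models."""

import math

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from ludose.kinetics import (MAX_TIAC_H, ExpFit, RedMarrowParams, auc_inf,
                             bladder_tiac, fit_tac, gut_tiacs,
                             red_marrow_activity, red_marrow_tac_from_blood,
                             remainder_tiac, tiac)
from ludose.nuclide import LN2, NuclideData, lu177

NUC = lu177()
IMAGING_T = np.array([0.0, 2.0, 24.0, 48.0, 168.0])


def biexp(t, a1, te1, a2, te2):
    return a1 * np.exp(-LN2 / te1 * t) + a2 * np.exp(-LN2 / te2 * t)


class TestFitTac:
    def test_kidney_phases_recovered_from_exact_samples(self):
        y = biexp(IMAGING_T, 50.0, 7.0, 10.0, 43.0)
        fit = fit_tac(IMAGING_T, y, n_phases=2)
        assert fit.t_eff_h[0] == pytest.approx(7.0, rel=0.01)
        assert fit.t_eff_h[1] == pytest.approx(43.0, rel=0.01)
        assert fit.t_bio_h[1] == pytest.approx(1 / (1 / 43.0 - 1 / 161.6), rel=0.01)

    def test_constant_tac_flagged_non_physical(self):
        fit = fit_tac(np.array([2.0, 24.0, 48.0, 168.0]), np.full(4, 5.0),
                      n_phases=1)
        assert "non-physical-rate" in fit.flags or "slower-than-physical-decay" in fit.flags

    def test_auto_mode_prefers_mono_for_mono_data(self):
        t = np.array([0.0, 2.0, 8.0, 24.0, 48.0, 96.0, 168.0])
        y = 20.0 * np.exp(-LN2 / 40.0 * t)
        fit = fit_tac(t, y, n_phases="auto")
        assert fit.n_phases == 1
        assert fit.t_eff_h[0] == pytest.approx(40.0, rel=1e-6)

    def test_auto_mode_finds_two_phases_in_rich_biexp_data(self):
        t = np.array([0.0, 1.0, 2.0, 4.0, 8.0, 24.0, 48.0, 96.0, 168.0])
        fit = fit_tac(t, biexp(t, 50.0, 7.0, 10.0, 43.0), n_phases="auto")
        assert fit.n_phases == 2

    def test_slower_than_physical_phase_has_no_t_bio(self):
        t = np.array([2.0, 24.0, 48.0, 168.0])
        y = 10.0 * np.exp(-LN2 / 300.0 * t)  # slower than physical decay
        fit = fit_tac(t, y, n_phases=1)
        assert fit.t_bio_h[0] is None
        assert "slower-than-physical-decay" in fit.flags

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_tac([2.0, 24.0], [5.0, 3.0], n_phases=2)

    def test_nonpositive_activity_rejected(self):
        with pytest.raises(ValueError):
            fit_tac([2.0, 24.0, 48.0], [5.0, 0.0, 1.0], n_phases=1)


class TestAucAndTiac:
    def test_single_phase_closed_form(self):
        fit = ExpFit(1, (10.0,), (0.1,), (LN2 / 0.1,), (None,), 100.0)
        assert auc_inf(fit) == pytest.approx(100.0)

    def test_additivity(self):
        fit = ExpFit(2, (10.0, 2.0), (0.1, 0.01), (LN2 / 0.1, LN2 / 0.01),
                     (None, None), 300.0)
        assert auc_inf(fit) == pytest.approx(300.0)

    def test_matches_numerical_quadrature(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            amps = rng.uniform(1.0, 100.0, size=2)
            rates = rng.uniform(0.005, 0.5, size=2)
            fit = ExpFit(2, tuple(amps), tuple(rates), (0.0, 0.0), (None, None), 0.0)
            num, _ = quad(lambda t: fit.predict(t), 0.0, np.inf)
            assert auc_inf(fit) == pytest.approx(num, rel=1e-6)

    def test_total_body_scale_fixture(self):
        assert tiac(236800.0, 7400.0) == pytest.approx(32.0)

    def test_zero_and_homogeneity(self):
        assert tiac(0.0, 7400.0) == 0.0
        assert tiac(100.0, 50.0) == tiac(200.0, 100.0)

    def test_fitted_tiac_within_physical_limit(self):
        # activity that only decays physically sits exactly at the ceiling
        t = np.array([2.0, 24.0, 48.0, 168.0])
        y = 7400.0 * np.exp(-NUC.lambda_phys * t)
        fit = fit_tac(t, y, n_phases=1, nuclide=NUC)
        assert tiac(auc_inf(fit), 7400.0) <= MAX_TIAC_H * (1 + 1e-9)


class TestRedMarrow:
    def test_zero_blood_activity(self):
        assert red_marrow_activity(0.0) == 0.0

    def test_constructed_cancellation(self):
        p = RedMarrowParams(rmblr=1.0, m_rm_g=1060.0, rho_blood_g_ml=1.06)
        assert red_marrow_activity(1.0, p) == pytest.approx(1000.0)

    def test_printed_constants_evaluation(self):
        assert red_marrow_activity(2.5, RedMarrowParams()) == pytest.approx(
            2.5 * 1170.0 / 1.06, rel=1e-12)

    def test_tac_from_blood_carries_physical_decay(self):
        t = np.array([0.0, 161.6])
        pct_dc = np.array([0.01, 0.005])  # halves biologically
        tt, a = red_marrow_tac_from_blood(t, pct_dc, 7400.0)
        # after one physical half-life the measured activity halves again
        assert a[1] / a[0] == pytest.approx(0.25, rel=1e-9)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RedMarrowParams(m_rm_g=-1.0)


def bladder_ode_oracle(f_u, phases, interval, lam, n_intervals=400):
    """Independent ODE integration of the voiding bladder model.

    Between voids the content b obeys b' = input(t) - lam * b with the
    physically decayed urinary inflow input(t) = f_u * sum f_i mu_i
    exp(-(mu_i + lam) t); b resets to 0 at each void and the integral of b
    over all intervals is the TIAC.
    """
    def rhs(t, y):
        inflow = f_u * sum(f * mu * math.exp(-(mu + lam) * t) for f, mu in phases)
        return [inflow - lam * y[0], y[0]]

    total = 0.0
    for k in range(n_intervals):
        t0 = k * interval
        sol = solve_ivp(rhs, (t0, t0 + interval), [0.0, total],
                        rtol=1e-10, atol=1e-14)
        total = float(sol.y[1, -1])
    return total


class TestBladder:
    PHASES = ((0.775, LN2 / 7.865), (0.225, LN2 / 133.2))

    def test_zero_urinary_fraction(self):
        assert bladder_tiac(0.0, self.PHASES, 3.5, NUC) == 0.0

    def test_vanishing_interval_limit(self):
        big = bladder_tiac(0.9, self.PHASES, 3.5, NUC)
        tiny = bladder_tiac(0.9, self.PHASES, 0.01, NUC)
        assert tiny < big / 100.0

    def test_single_phase_against_ode_oracle(self):
        phases = ((1.0, LN2 / 8.0),)
        ours = bladder_tiac(0.5, phases, 3.5, NUC)
        oracle = bladder_ode_oracle(0.5, phases, 3.5, NUC.lambda_phys)
        assert ours == pytest.approx(oracle, rel=1e-4)

    def test_monotone_in_interval_and_fraction(self):
        vals = [bladder_tiac(0.9, self.PHASES, iv, NUC)
                for iv in (1.0, 2.0, 3.5, 6.0)]
        assert vals == sorted(vals)
        fracs = [bladder_tiac(f, self.PHASES, 3.5, NUC) for f in (0.2, 0.5, 0.9)]
        assert fracs == sorted(fracs)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            bladder_tiac(1.5, self.PHASES, 3.5, NUC)
        with pytest.raises(ValueError):
            bladder_tiac(0.5, self.PHASES, 0.0, NUC)
        with pytest.raises(ValueError):
            bladder_tiac(0.5, ((0.5, 0.1),), 3.5, NUC)  # fractions don't sum to 1


def gut_ode_oracle(f_g, transit_means, lam, t_end=5000.0):
    k = [1.0 / m for m in transit_means]

    def rhs(t, y):
        q1, q2, q3, i1, i2, i3 = y
        return [-(k[0] + lam) * q1,
                k[0] * q1 - (k[1] + lam) * q2,
                k[1] * q2 - (k[2] + lam) * q3,
                q1, q2, q3]

    sol = solve_ivp(rhs, (0.0, t_end), [f_g, 0.0, 0.0, 0.0, 0.0, 0.0],
                    rtol=1e-10, atol=1e-14)
    return sol.y[3:, -1]


class TestGut:
    def test_zero_fraction(self):
        assert all(v == 0.0 for v in gut_tiacs(0.0, (12, 12, 12), NUC).values())

    def test_no_decay_limit_is_residence_time(self):
        stable = NuclideData(name="stable-ish", t_phys_h=1e12)
        out = gut_tiacs(0.5, (10.0, 20.0, 30.0), stable)
        assert out["right colon"] == pytest.approx(0.5 * 10.0, rel=1e-6)
        assert out["left colon"] == pytest.approx(0.5 * 20.0, rel=1e-6)
        assert out["rectosigmoid"] == pytest.approx(0.5 * 30.0, rel=1e-6)

    def test_defaults_match_ode_oracle(self):
        ours = gut_tiacs(0.061, (12.0, 12.0, 12.0), NUC)
        oracle = gut_ode_oracle(0.061, (12.0, 12.0, 12.0), NUC.lambda_phys)
        for got, want in zip(ours.values(), oracle):
            assert got == pytest.approx(want, rel=1e-4)

    def test_decay_shrinks_each_segment(self):
        stable = NuclideData(name="stable-ish", t_phys_h=1e12)
        with_decay = gut_tiacs(0.3, (12, 12, 12), NUC)
        without = gut_tiacs(0.3, (12, 12, 12), stable)
        for seg in with_decay:
            assert with_decay[seg] < without[seg]


class TestRemainder:
    def test_table_scale_fixture(self):
        assert remainder_tiac(32.0, {"sources": 6.8}) == pytest.approx(25.2)

    def test_no_sources(self):
        assert remainder_tiac(32.0, {}) == 32.0

    def test_negative_remainder_rejected(self):
        with pytest.raises(ValueError):
            remainder_tiac(5.0, {"a": 4.0, "b": 2.0})
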