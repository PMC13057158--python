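"""Virtual-patient generator: determinism, defaults, conservation, noise model."""

import numpy as np
import pandas as pd
import pytest

from ludose import synthetic
from ludose.nuclide import lu177
from ludose.planar import BACKGROUND, EnergyWindowSet, tew_scatter_correct
from ludose.synthetic import (BloodKinetics, GammaCounter, generate_cohort,
                              generate_patient, simulate_blood_samples,
                              simulate_planar_scans, solve_phase_amplitudes)

NUC = lu177()


class TestGeneratePatient:
    def test_deterministic_for_fixed_seed(self):
        a = generate_patient(seed=1)
        b = generate_patient(seed=1)
        assert a == b

    def test_default_kidney_uptake_at_2h(self, default_patient):
        assert default_patient.organ_params["kidneys"].activity_fraction(2.0) \
            == pytest.approx(0.037, rel=1e-12)

    def test_default_kidney_phases(self, default_patient):
        assert default_patient.organ_params["kidneys"].t_eff_h == (7.0, 43.0)

    def test_total_body_starts_at_100_pct(self, default_patient):
        assert default_patient.total_body.activity_fraction(0.0) == pytest.approx(1.0)

    def test_administered_within_protocol_window(self):
        for seed in range(20):
            p = generate_patient(seed=seed)
            assert 6660.0 <= p.administered_mbq <= 8140.0

    def test_overloaded_uptake_rejected(self):
        from ludose.synthetic import OrganKinetics
        big = {"liver": OrganKinetics(fractions=(0.9, 0.3), t_eff_h=(8.0, 50.0))}
        with pytest.raises(ValueError, match="sum"):
            generate_patient({"organ_params": big, "administered_mbq": 7400.0}, seed=0)

    def test_cohort_varies_between_patients(self):
        cohort = generate_cohort(3, seed=5)
        uptakes = {p.organ_params["kidneys"].activity_fraction(2.0) for p in cohort}
        assert len(uptakes) == 3


class TestAmplitudeSolver:
    def test_tiac_and_uptake_constraints_both_hit(self):
        amps = solve_phase_amplitudes(3.7, (7.0, 43.0), tiac_target=1.8)
        kin = synthetic.OrganKinetics(fractions=amps, t_eff_h=(7.0, 43.0))
        assert kin.activity_fraction(2.0) == pytest.approx(0.037, rel=1e-12)
        assert kin.tiac_h == pytest.approx(1.8, rel=1e-12)

    def test_infeasible_combination_raises(self):
        # short half-lives cannot carry this much time-integrated activity
        with pytest.raises(ValueError, match="infeasible"):
            solve_phase_amplitudes(2.6, (10.0, 40.0), tiac_target=2.0)


class TestConservation:
    @pytest.mark.parametrize("t", [0.0, 2.0, 24.0, 48.0, 168.0, 500.0])
    def test_body_plus_urine_is_100_after_decay_correction(self, default_patient, t):
        total = (default_patient.body_retention_pct_dc(t)
                 + default_patient.urine_cumulative_pct_dc(t))
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_organ_sum_never_exceeds_total_body(self, default_patient):
        t = np.linspace(0.0, 168.0, 200)
        organ_sum = sum(k.activity_fraction(t)
                        for k in default_patient.organ_params.values())
        assert np.all(organ_sum <= default_patient.total_body.activity_fraction(t))


class TestBloodSimulator:
    def test_zero_activity_patient_reads_background(self, default_patient):
        from dataclasses import replace
        quiet = replace(default_patient, blood=BloodKinetics(c0_pct_ia_per_ml=0.0))
        s = simulate_blood_samples(quiet, noise=False)
        post = s[s["type"] == "postdose"]
        assert (post["cpm"] == GammaCounter().background_cpm).all()

    def test_noiseless_counts_match_expectation(self, default_patient):
        cnt = GammaCounter()
        s = simulate_blood_samples(default_patient, noise=False)
        row = s[(s["type"] == "postdose") & (s["time_h"] == 24.0)].iloc[0]
        conc_bq_ml = (default_patient.blood.conc_pct_ia_per_ml(
            24.0, NUC, decay_corrected=False) / 100.0
            * default_patient.administered_mbq * 1e6)
        expected = (conc_bq_ml / row["dilution"] * cnt.aliquot_ml
                    * cnt.efficiency_cpm_per_bq + cnt.background_cpm)
        assert row["cpm"] == pytest.approx(expected, rel=1e-12)

    def test_poisson_mean_matches_expectation(self, default_patient):
        # 1e4 replicate draws of the 24 h sample: empirical mean within 3 SE
        expected = simulate_blood_samples(default_patient, schedule=[24.0],
                                          noise=False)
        mu = float(expected.loc[expected["type"] == "postdose", "cpm"].iloc[0])
        draws = np.array([
            simulate_blood_samples(default_patient, schedule=[24.0], noise=True,
                                   seed=seed)
            .loc[lambda d: d["type"] == "postdose", "cpm"].iloc[0]
            for seed in range(200)])
        se = np.sqrt(mu / len(draws))
        assert abs(draws.mean() - mu) <= 3.0 * se

    def test_determinism(self, default_patient):
        a = simulate_blood_samples(default_patient, seed=9)
        b = simulate_blood_samples(default_patient, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_schedule_outside_protocol_rejected(self, default_patient):
        with pytest.raises(ValueError):
            simulate_blood_samples(default_patient, schedule=[200.0])


class TestPlanarSimulator:
    def test_zero_scatter_gives_background_only_flanks(self, default_patient):
        scans = simulate_planar_scans(default_patient, scatter_fraction=0.0,
                                      noise=False)
        df = scans.counts
        kid = df[(df["roi"] == "kidneys") & (df["time_h"] == 2.0)]
        area = kid["roi_area_px"].iloc[0]
        dur = kid["duration_s"].iloc[0]
        low = kid.loc[kid["window"] == "low", "counts"].iloc[0]
        assert low == pytest.approx(0.012 * area * dur)

    def test_noiseless_tew_inverts_the_scatter_model(self, default_patient,
                                                     noiseless_scans):
        # after background removal, TEW recovers the geometric counts exactly
        df = noiseless_scans.counts
        bkg = df[df["roi"] == BACKGROUND].set_index(["time_h", "window"])["counts"]
        kid = df[(df["roi"] == "kidneys") & (df["time_h"] == 24.0)]
        area = kid["roi_area_px"].iloc[0]
        bkg_area = df.loc[df["roi"] == BACKGROUND, "roi_area_px"].iloc[0]
        net = {w: (kid.loc[kid["window"] == w, "counts"].iloc[0]
                   - bkg.loc[(24.0, w)] / bkg_area * area)
               for w in ("main", "low", "upper")}
        c_sc = tew_scatter_correct(net["main"], net["low"], net["upper"],
                                   EnergyWindowSet()).c_sc
        truth = (10.0 * default_patient.organ_activity_mbq("kidneys", 24.0)
                 * noiseless_scans.duration_s)
        assert c_sc == pytest.approx(truth, rel=1e-10)

    def test_seed_reproducibility(self, default_patient):
        a = simulate_planar_scans(default_patient, seed=4).counts
        b = simulate_planar_scans(default_patient, seed=4).counts
        pd.testing.assert_frame_equal(a, b)

    def test_reference_source_activity_in_band(self, default_patient):
        scans = simulate_planar_scans(default_patient, seed=11)
        assert 50.0 <= scans.reference_activity_mbq_t0 <= 100.0

    def test_invalid_scatter_fraction_rejected(self, default_patient):
        with pytest.raises(ValueError):
            simulate_planar_scans(default_patient, scatter_fraction=1.2)
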