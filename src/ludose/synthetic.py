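"""Virtual-patient simulator for the Lu-177 radioligand dosimetry protocol.

A virtual patient carries ground-truth kinetics for every quantity the
pipeline later estimates: multi-phase exponential organ time-activity curves
parameterised by 2-h fractional uptakes and effective half-lives of the
magnitudes reported for Lu-177-PSMA-617 (kidneys 3.7 %IA at 2 h with t_eff
7/43 h, bi-exponential total body with terminal t_eff 73 h, tri-phasic
blood), an administered activity of 7400 MBq +/- 10%, and a 50-100 MBq
sealed reference source.

From the ground truth the simulator produces exactly the raw data the
analysis stages consume: gamma-counter blood records (with calibration
standards and a blank) on the blood schedule (EOI, 20 min, 60 min, 2, 4, 24,
48, 72, 168 h) and three-energy-window planar ROI counts on the imaging
schedule (2, 24, 48, 168 h) with Poisson counting noise.  Scatter is
simulated with a per-window leak model constructed so that the
triple-energy-window estimate is unbiased: the flanking-window expectations
are chosen to make the TEW scatter estimate equal the true scatter in
expectation, hence noiseless simulation inverts exactly.

Physical bookkeeping: activity excreted to urine decays at the same physical
rate as activity in the body, so at every time decay-corrected body
retention plus cumulative voided urine equals 100 %IA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .nuclide import LN2, NuclideData, lu177
from .planar import (BACKGROUND, REFERENCE_SOURCE, TOTAL_BODY, URINE_CONTAINER,
                     EnergyWindowSet)

__all__ = [
    "OrganKinetics",
    "BloodKinetics",
    "VirtualPatient",
    "GammaCounter",
    "PlanarScanSet",
    "BLOOD_SCHEDULE_H",
    "IMAGING_SCHEDULE_H",
    "DEFAULT_ORGAN_TABLE",
    "solve_phase_amplitudes",
    "generate_patient",
    "generate_cohort",
    "simulate_blood_samples",
    "simulate_planar_scans",
]

#: Blood sampling schedule, hours post injection start (EOI, 20 min, 60 min, ...).
BLOOD_SCHEDULE_H = (0.083, 0.333, 1.0, 2.0, 4.0, 24.0, 48.0, 72.0, 168.0)

#: Whole-body planar imaging schedule, hours post injection.
IMAGING_SCHEDULE_H = (2.0, 24.0, 48.0, 168.0)

#: Canonical per-organ defaults: 2-h uptake (%IA), phase t_eff (h), and either
#: a target TIAC (MBq*h/MBq) or a fixed fast-phase amplitude share used to
#: pin down the phase amplitudes.
DEFAULT_ORGAN_TABLE = {
    # organ: (uptake_2h_pct, t_eff_phases_h, tiac_target, fast_share)
    "liver": (4.2, (8.0, 50.0), 1.2, None),
    "kidneys": (3.7, (7.0, 43.0), 1.8, None),
    "bowel": (2.6, (52.0,), None, None),
    "heart wall": (2.2, (7.0, 45.0), 0.74, None),
    "lungs": (1.8, (7.0, 45.0), 0.50, None),
    "salivary glands": (0.86, (14.0, 60.0), None, 0.5),
    "spleen": (0.59, (8.0, 50.0), None, 0.5),
    "thyroid": (0.42, (5.7, 62.0), 0.13, None),
    "left lacrimal gland": (0.087, (14.0, 60.0), None, 0.5),
    "right lacrimal gland": (0.077, (14.0, 60.0), None, 0.5),
}

#: Relative spread (lognormal CV) of 2-h uptake used for inter-patient
#: variability, from the reported SD/mean ratios (capped at 0.6).
_UPTAKE_CV = {
    "liver": 0.38, "kidneys": 0.17, "bowel": 0.27, "heart wall": 0.40,
    "lungs": 0.60, "salivary glands": 0.49, "spleen": 0.49, "thyroid": 0.60,
    "left lacrimal gland": 0.46, "right lacrimal gland": 0.55,
}
_T_EFF_CV = 0.25

_TB_FRACTIONS = (0.775, 0.225)
_TB_T_EFF = (7.5, 73.0)


@dataclass(frozen=True)
class OrganKinetics:
    """Ground-truth organ TAC: fractions of IA per phase at t=0 and t_eff (h).

    The TAC is the physically decaying activity fraction
    a(t) = sum_i fractions[i] * exp(-ln2 / t_eff[i] * t).
    """

    fractions: tuple
    t_eff_h: tuple

    def __post_init__(self) -> None:
        if len(self.fractions) != len(self.t_eff_h):
            raise ValueError("one t_eff per phase required")
        if any(f < 0 for f in self.fractions) or any(te <= 0 for te in self.t_eff_h):
            raise ValueError("fractions must be >= 0 and t_eff > 0")

    @property
    def rates(self) -> tuple:
        return tuple(LN2 / te for te in self.t_eff_h)

    def activity_fraction(self, t):
        t = np.asarray(t, dtype=float)
        return sum(f * np.exp(-r * t) for f, r in zip(self.fractions, self.rates))

    @property
    def tiac_h(self) -> float:
        """Closed-form TIAC (MBq*h/MBq): sum of fraction / effective rate."""
        return float(sum(f / r for f, r in zip(self.fractions, self.rates)))


@dataclass(frozen=True)
class BloodKinetics:
    """Tri-phasic decay-corrected blood concentration, %IA/mL.

    c(t) = c0 * sum_i fractions[i] * exp(-ln2 / t_bio[i] * t); the default
    terminal t_bio of 52.6 h corresponds to an effective half-life near 40 h.
    """

    c0_pct_ia_per_ml: float = 0.011778
    fractions: tuple = (0.62, 0.25, 0.13)
    t_bio_h: tuple = (0.32, 5.0, 52.6)

    def conc_pct_ia_per_ml(self, t, nuclide: NuclideData | None = None,
                           decay_corrected: bool = True):
        t = np.asarray(t, dtype=float)
        c = self.c0_pct_ia_per_ml * sum(
            f * np.exp(-LN2 / tb * t) for f, tb in zip(self.fractions, self.t_bio_h))
        if not decay_corrected:
            c = c * np.exp(-(nuclide or lu177()).lambda_phys * t)
        return c


def solve_phase_amplitudes(uptake_2h_pct: float, t_eff_h: tuple,
                           tiac_target: float | None = None,
                           fast_share: float | None = None) -> tuple:
    """Solve phase amplitudes (fractions of IA at t=0) from study constraints.

    Mono-exponential: the amplitude follows from the 2-h uptake alone.
    Bi-exponential: either pin the time-integral (TIAC) as the second
    constraint and solve the 2x2 linear system, or fix the fast-phase
    amplitude share.  Infeasible constraint combinations (negative
    amplitudes) raise.
    """
    u = uptake_2h_pct / 100.0
    rates = [LN2 / te for te in t_eff_h]
    e2 = [math.exp(-r * 2.0) for r in rates]
    if len(rates) == 1:
        return (u / e2[0],)
    if len(rates) != 2:
        raise ValueError("amplitude solving supports 1 or 2 phases")
    if tiac_target is not None:
        a = np.linalg.solve(np.array([e2, [1.0 / rates[0], 1.0 / rates[1]]]),
                            np.array([u, tiac_target]))
        if np.any(a <= 0):
            raise ValueError(
                f"infeasible kinetics: uptake {uptake_2h_pct} %IA at 2 h with "
                f"t_eff {t_eff_h} cannot reach TIAC {tiac_target}")
        return tuple(float(v) for v in a)
    share = 0.5 if fast_share is None else fast_share
    if not 0.0 <= share <= 1.0:
        raise ValueError("fast_share must lie in [0, 1]")
    c = u / (share * e2[0] + (1.0 - share) * e2[1])
    return (share * c, (1.0 - share) * c)


@dataclass(frozen=True)
class VirtualPatient:
    """Ground-truth virtual participant.

    All organ TACs are physically decaying activity fractions; the total-body
    curve is bi-exponential and bounds the organ sum at every time.
    """

    administered_mbq: float
    organ_params: dict
    total_body: OrganKinetics
    blood: BloodKinetics
    organ_masses_g: dict
    urinary_fraction: float
    gut_fraction: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.gut_fraction <= 1.0 or not 0.0 <= self.urinary_fraction <= 1.0:
            raise ValueError("excretion fractions must lie in [0, 1]")
        uptake_2h = sum(k.activity_fraction(2.0) for k in self.organ_params.values())
        if uptake_2h > 1.0:
            raise ValueError(f"organ uptakes at 2 h sum to {uptake_2h:.3f} > 1")

    # -- ground truth ------------------------------------------------------
    def organ_activity_mbq(self, organ: str, t):
        return self.administered_mbq * self.organ_params[organ].activity_fraction(t)

    def total_body_activity_mbq(self, t):
        return self.administered_mbq * self.total_body.activity_fraction(t)

    def body_retention_pct_dc(self, t, nuclide: NuclideData | None = None):
        """Decay-corrected whole-body retention, %IA."""
        lam = (nuclide or lu177()).lambda_phys
        t = np.asarray(t, dtype=float)
        return 100.0 * self.total_body.activity_fraction(t) * np.exp(lam * t)

    def urine_cumulative_pct_dc(self, t, nuclide: NuclideData | None = None):
        """Cumulative voided urine, decay-corrected %IA (conservation complement)."""
        return 100.0 - self.body_retention_pct_dc(t, nuclide)

    def true_tiac(self, organ: str) -> float:
        return self.organ_params[organ].tiac_h

    @property
    def true_total_body_tiac(self) -> float:
        return self.total_body.tiac_h


def _default_organ_params() -> dict:
    return {
        organ: OrganKinetics(
            fractions=solve_phase_amplitudes(u, te, tiac, share), t_eff_h=te)
        for organ, (u, te, tiac, share) in DEFAULT_ORGAN_TABLE.items()
    }


def generate_patient(config: dict | None = None, seed: int = 0) -> VirtualPatient:
    """Build a virtual patient; defaults reproduce the canonical study values.

    Without overrides the patient is deterministic apart from the
    administered activity, drawn uniformly within the protocol window
    7400 MBq +/- 10% (pass ``administered_mbq`` to fix it).  With
    ``vary=True`` organ amplitudes and half-lives receive seeded lognormal
    inter-patient jitter so cohorts show realistic spread.
    """
    cfg = dict(config or {})
    rng = np.random.default_rng(seed)
    administered = cfg.get("administered_mbq")
    if administered is None:
        administered = rng.uniform(7400.0 * 0.9, 7400.0 * 1.1)
    organ_params = _default_organ_params()
    total_body = OrganKinetics(fractions=_TB_FRACTIONS, t_eff_h=_TB_T_EFF)
    blood = BloodKinetics()
    if cfg.get("vary", False):
        new = {}
        for organ, kin in organ_params.items():
            amp = float(np.exp(rng.normal(0.0, _UPTAKE_CV.get(organ, 0.4))))
            tes = tuple(float(te * np.exp(rng.normal(0.0, _T_EFF_CV)))
                        for te in kin.t_eff_h)
            new[organ] = OrganKinetics(
                fractions=tuple(f * amp for f in kin.fractions), t_eff_h=tes)
        organ_params = new
        tb_slow = _TB_FRACTIONS[1] * float(np.exp(rng.normal(0.0, 0.2)))
        tb_slow = min(tb_slow, 0.6)
        total_body = OrganKinetics(
            fractions=(1.0 - tb_slow, tb_slow),
            t_eff_h=tuple(float(te * np.exp(rng.normal(0.0, 0.15)))
                          for te in _TB_T_EFF))
        blood = replace(blood,
                        c0_pct_ia_per_ml=blood.c0_pct_ia_per_ml
                        * float(np.exp(rng.normal(0.0, 0.3))))
    if "organ_params" in cfg:
        organ_params.update(cfg["organ_params"])
    masses = {"red marrow": 1170.0}
    masses.update(cfg.get("organ_masses_g", {}))
    return VirtualPatient(
        administered_mbq=float(administered),
        organ_params=organ_params,
        total_body=cfg.get("total_body", total_body),
        blood=cfg.get("blood", blood),
        organ_masses_g=masses,
        urinary_fraction=cfg.get("urinary_fraction", 1.0 - cfg.get("gut_fraction", 0.061)),
        gut_fraction=cfg.get("gut_fraction", 0.061),
        seed=int(seed),
    )


def generate_cohort(n: int, seed: int = 0, config: dict | None = None) -> list:
    """n virtual patients with inter-patient variability, seeded reproducibly."""
    cfg = dict(config or {})
    cfg.setdefault("vary", True)
    children = np.random.SeedSequence(seed).spawn(n)
    return [generate_patient(cfg, seed=int(c.generate_state(1)[0] % (2**31)))
            for c in children]


@dataclass(frozen=True)
class GammaCounter:
    """Well-counter model: net efficiency, background and counting time."""

    efficiency_cpm_per_bq: float = 12.0
    background_cpm: float = 50.0
    aliquot_ml: float = 1.0
    count_minutes: float = 1.0

    #: Standard-series activities (kBq per counted aliquot), ~0.1-700 kBq/mL.
    standard_levels_kbq: tuple = (0.1, 0.5, 2.0, 10.0, 50.0, 200.0, 700.0)


def simulate_blood_samples(patient: VirtualPatient, schedule=BLOOD_SCHEDULE_H,
                           counter: GammaCounter | None = None,
                           noise: bool = True, seed: int | None = None,
                           nuclide: NuclideData | None = None) -> pd.DataFrame:
    """Raw gamma-counter records: standards, blank, pre-dose and post-dose.

    Post-dose counts are Poisson draws around (decayed activity x efficiency
    + background) x counting time; early samples are auto-diluted to keep the
    measured concentration inside the standard range.  ``noise=False``
    returns the exact expected values.
    """
    nuc = nuclide or lu177()
    cnt = counter or GammaCounter()
    rng = np.random.default_rng(patient.seed if seed is None else seed)

    def draw(expected_counts: float) -> float:
        if not noise:
            return expected_counts
        return float(rng.poisson(expected_counts))

    rows = []
    for i, level in enumerate(cnt.standard_levels_kbq):
        for rep in range(3):
            expected = (level * 1e3 * cnt.efficiency_cpm_per_bq
                        + cnt.background_cpm) * cnt.count_minutes
            rows.append({"sample_id": f"std-{i}-{rep}", "time_h": 0.0,
                         "cpm": draw(expected) / cnt.count_minutes,
                         "volume_ml": cnt.aliquot_ml, "dilution": 1.0,
                         "type": "standard", "known_kBq": level})
    rows.append({"sample_id": "blank", "time_h": 0.0,
                 "cpm": draw(cnt.background_cpm * cnt.count_minutes) / cnt.count_minutes,
                 "volume_ml": cnt.aliquot_ml, "dilution": 1.0,
                 "type": "blank", "known_kBq": 0.0})
    rows.append({"sample_id": "predose", "time_h": -0.25,
                 "cpm": draw(cnt.background_cpm * cnt.count_minutes) / cnt.count_minutes,
                 "volume_ml": cnt.aliquot_ml, "dilution": 1.0,
                 "type": "predose", "known_kBq": np.nan})
    for j, t in enumerate(schedule):
        if not 0.0 <= t <= 168.0:
            raise ValueError("blood schedule must lie within 0-168 h")
        conc_bq_ml = (patient.blood.conc_pct_ia_per_ml(t, nuc, decay_corrected=False)
                      / 100.0 * patient.administered_mbq * 1e6)
        dilution = 1.0
        while conc_bq_ml / dilution / 1e3 > 600.0:
            dilution *= 10.0
        bq_counted = conc_bq_ml / dilution * cnt.aliquot_ml
        expected = (bq_counted * cnt.efficiency_cpm_per_bq
                    + cnt.background_cpm) * cnt.count_minutes
        rows.append({"sample_id": f"post-{j}", "time_h": float(t),
                     "cpm": draw(expected) / cnt.count_minutes,
                     "volume_ml": cnt.aliquot_ml, "dilution": dilution,
                     "type": "postdose", "known_kBq": np.nan})
    return pd.DataFrame(rows)


#: Nominal ROI areas in pixels for the simulated planar views.
DEFAULT_ROI_AREAS_PX = {
    TOTAL_BODY: 50000, URINE_CONTAINER: 1500, REFERENCE_SOURCE: 400,
    BACKGROUND: 5000, "liver": 2500, "kidneys": 1200, "bowel": 3000,
    "heart wall": 900, "lungs": 2500, "salivary glands": 300, "spleen": 700,
    "thyroid": 150, "left lacrimal gland": 30, "right lacrimal gland": 30,
}


@dataclass
class PlanarScanSet:
    """Three-window planar ROI count tables on the imaging schedule.

    ``counts`` has columns time_h, roi, window (main|low|upper), counts,
    roi_area_px, duration_s; the reference-source activity at injection time
    is recorded for QC truth.
    """

    counts: pd.DataFrame
    reference_activity_mbq_t0: float
    duration_s: float

    def __post_init__(self) -> None:
        if (self.counts["counts"] < 0).any():
            raise ValueError("counts must be non-negative")
        if not 50.0 <= self.reference_activity_mbq_t0 <= 100.0:
            raise ValueError("reference source must be 50-100 MBq")


def simulate_planar_scans(patient: VirtualPatient,
                          windows: EnergyWindowSet | None = None,
                          scatter_fraction: float = 0.25,
                          sensitivity_cps_per_mbq: float = 10.0,
                          duration_s: float = 300.0,
                          times=IMAGING_SCHEDULE_H,
                          background_cps_per_px=(0.02, 0.012, 0.008),
                          roi_areas_px: dict | None = None,
                          noise: bool = True, seed: int | None = None,
                          nuclide: NuclideData | None = None) -> PlanarScanSet:
    """Simulate three-energy-window planar ROI counts for every scan time.

    The main window holds geometric (unscattered) counts G plus scatter
    S = scatter_fraction * G; the lower/upper windows hold (W_low/W_main) * S
    and (W_upper/W_main) * S respectively, so the TEW estimate recovers S --
    and hence G -- exactly in expectation.  Flat per-pixel background rates
    are added per window and a matching background ROI is emitted.
    """
    if not 0.0 <= scatter_fraction < 1.0:
        raise ValueError("scatter fraction must lie in [0, 1)")
    nuc = nuclide or lu177()
    win = windows or EnergyWindowSet()
    areas = dict(DEFAULT_ROI_AREAS_PX)
    areas.update(roi_areas_px or {})
    rng = np.random.default_rng((patient.seed if seed is None else seed) + 7)
    ref_mbq = float(rng.uniform(50.0, 100.0))
    b_main, b_low, b_up = background_cps_per_px
    leak_low = win.lower.width_kev / win.main.width_kev
    leak_up = win.upper.width_kev / win.main.width_kev

    def draw(expected: float) -> float:
        return float(rng.poisson(expected)) if noise else expected

    t_sorted = sorted(float(t) for t in times)
    if len(set(t_sorted)) != len(t_sorted):
        raise ValueError("imaging time points must be strictly increasing")
    rows = []

    def emit(t, roi, activity_mbq):
        area = areas[roi]
        g = sensitivity_cps_per_mbq * activity_mbq * duration_s
        s = scatter_fraction * g
        expected = {"main": g + s + b_main * area * duration_s,
                    "low": leak_low * s + b_low * area * duration_s,
                    "upper": leak_up * s + b_up * area * duration_s}
        for wname, e in expected.items():
            rows.append({"time_h": t, "roi": roi, "window": wname,
                         "counts": draw(e), "roi_area_px": area,
                         "duration_s": duration_s})

    for t in t_sorted:
        decay = math.exp(-nuc.lambda_phys * t)
        for organ in patient.organ_params:
            emit(t, organ, patient.organ_activity_mbq(organ, t))
        emit(t, TOTAL_BODY, patient.total_body_activity_mbq(t))
        if t == t_sorted[0]:
            urine_mbq = (patient.administered_mbq * decay
                         * float(patient.urine_cumulative_pct_dc(t, nuc)) / 100.0)
            emit(t, URINE_CONTAINER, urine_mbq)
        emit(t, REFERENCE_SOURCE, ref_mbq * decay)
        for wname, b in zip(("main", "low", "upper"), (b_main, b_low, b_up)):
            rows.append({"time_h": t, "roi": BACKGROUND, "window": wname,
                         "counts": draw(b * areas[BACKGROUND] * duration_s),
                         "roi_area_px": areas[BACKGROUND],
                         "duration_s": duration_s})
    return PlanarScanSet(counts=pd.DataFrame(rows),
                         reference_activity_mbq_t0=ref_mbq, duration_s=duration_s)
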