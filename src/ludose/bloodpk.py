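"""Gamma-counter calibration, blood concentrations and non-compartmental PK.

The calibration converts counts-per-minute to activity by blank-subtracted
ordinary least squares against a standard series (nominally ~0.1-700 kBq/mL).
Quantification limits are defined by back-calculated accuracy/precision:
LLOQ is the lowest standard within +/-20%, ULOQ the highest within +/-15%.

Blood concentrations are decay-corrected to the injection time and expressed
both as %IA/mL and, via the administered peptide mass, as ng/mL.  The NCA
follows the usual IV conventions: Cmax/Tmax observed, linear trapezoidal
AUC on actual times, log-linear terminal fit with adjusted-r2 window
selection, AUC_inf = AUC_last + C_last/lambda_z, CL = dose/AUC_inf,
Vz = CL/lambda_z, MRT from AUMC/AUC with analytic tail terms, Vss = CL*MRT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .nuclide import LN2, NuclideData, decay_correct, lu177

__all__ = [
    "CalibrationCurve",
    "BloodProfile",
    "NCAResult",
    "fit_calibration",
    "counts_to_concentration",
    "build_blood_profile",
    "run_nca",
    "urine_excretion_pct",
]

FLAG_OK = "ok"
FLAG_BELOW = "below-lloq"
FLAG_ABOVE = "above-uloq"


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear cpm-vs-Bq calibration with quantification limits (kBq/mL)."""

    slope_cpm_per_bq: float
    intercept_cpm: float
    blank_cpm: float
    lloq_kbq_ml: float
    uloq_kbq_ml: float
    r_squared: float

    def cpm_to_kbq(self, cpm: float) -> float:
        """Blank-subtracted counts to activity in kBq (per counted aliquot)."""
        return (cpm - self.blank_cpm) / self.slope_cpm_per_bq / 1000.0


def fit_calibration(standards: Sequence[tuple], blank_cpm: float,
                    aliquot_ml: float = 1.0,
                    lloq_tolerance: float = 0.20,
                    uloq_tolerance: float = 0.15) -> CalibrationCurve:
    """Fit the counts-to-activity calibration from a triplicate standard series.

    ``standards`` is a sequence of ``(known_kbq, [cpm, cpm, cpm])`` with known
    activity per counted aliquot.  Back-calculated accuracy (relative bias)
    and precision (CV) per level define the LLOQ (+/-20%) and ULOQ (+/-15%).
    """
    if len(standards) < 3:
        raise ValueError("need at least 3 standard levels")
    known = np.array([k for k, _ in standards], dtype=float)
    if np.any(known <= 0) or len(np.unique(known)) < 3:
        raise ValueError("standards must have >= 3 distinct positive levels")
    order = np.argsort(known)
    known = known[order]
    reps = [np.asarray(standards[i][1], dtype=float) for i in order]

    x = np.concatenate([np.full(r.size, k * 1000.0) for k, r in zip(known, reps)])  # Bq
    y = np.concatenate(reps) - blank_cpm
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise ValueError("degenerate calibration: non-positive slope")
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    def level_ok(k: float, r: np.ndarray, tol: float) -> bool:
        back = (r - blank_cpm) / slope / 1000.0  # kBq
        acc = abs(back.mean() - k) / k
        cv = back.std(ddof=1) / back.mean() if r.size > 1 and back.mean() > 0 else math.inf
        return acc <= tol and cv <= tol

    lloq = next((k / aliquot_ml for k, r in zip(known, reps) if level_ok(k, r, lloq_tolerance)),
                None)
    uloq = next((k / aliquot_ml for k, r in zip(known[::-1], reps[::-1])
                 if level_ok(k, r, uloq_tolerance)), None)
    if lloq is None or uloq is None or lloq >= uloq:
        raise ValueError("calibration standards do not define a quantifiable range")
    return CalibrationCurve(slope_cpm_per_bq=float(slope), intercept_cpm=float(intercept),
                            blank_cpm=float(blank_cpm), lloq_kbq_ml=float(lloq),
                            uloq_kbq_ml=float(uloq), r_squared=float(r2))


def counts_to_concentration(cpm: float, time_h: float, volume_ml: float, dilution: float,
                            curve: CalibrationCurve, administered_mbq: float,
                            nuclide: NuclideData | None = None) -> dict:
    """One gamma-counter record to a decay-corrected blood concentration.

    Returns measured and decay-corrected kBq/mL plus %IA/mL; the LLOQ/ULOQ
    flag is assigned on the measured (pre-correction) concentration.
    """
    if volume_ml <= 0:
        raise ValueError("sample volume must be positive")
    if administered_mbq <= 0:
        raise ValueError("administered activity must be positive")
    nuc = nuclide or lu177()
    measured_kbq_ml = curve.cpm_to_kbq(cpm) / volume_ml
    # quantification limits apply to the concentration as counted, before
    # the dilution factor scales it back to the undiluted sample
    if measured_kbq_ml < curve.lloq_kbq_ml:
        flag = FLAG_BELOW
    elif measured_kbq_ml > curve.uloq_kbq_ml:
        flag = FLAG_ABOVE
    else:
        flag = FLAG_OK
    kbq_ml = max(measured_kbq_ml, 0.0) * dilution
    kbq_ml_dc = decay_correct(kbq_ml, time_h, nuc)
    pct_ia_ml = kbq_ml_dc * 1e3 / (administered_mbq * 1e6) * 100.0
    return {"time_h": time_h, "kbq_ml": kbq_ml, "kbq_ml_dc": kbq_ml_dc,
            "pct_ia_per_ml": pct_ia_ml, "flag": flag}


@dataclass
class BloodProfile:
    """Decay-corrected blood concentration vs time (hours post injection).

    Flagged (below-LLOQ / above-ULOQ) points are retained but excluded from
    terminal fits; pre-dose below-LLOQ values are zero by convention.
    """

    times_h: np.ndarray
    conc_pct_ia_per_ml: np.ndarray
    conc_ng_ml: np.ndarray
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("blood sample times must be strictly increasing")

    def quantifiable(self) -> np.ndarray:
        return np.array([f == FLAG_OK for f in self.flags])


def build_blood_profile(samples: pd.DataFrame, curve: CalibrationCurve,
                        administered_mbq: float, peptide_ug: float,
                        nuclide: NuclideData | None = None) -> BloodProfile:
    """Convert post-dose gamma-counter records into a BloodProfile.

    ``samples`` needs columns time_h, cpm, volume_ml, dilution and type
    (rows with type ``postdose`` are used).  ng/mL is derived from %IA/mL via
    the administered peptide mass: conc_ng_ml = frac_IA_per_mL * mass_ng.
    """
    post = samples[samples["type"] == "postdose"].sort_values("time_h")
    recs = [counts_to_concentration(r.cpm, r.time_h, r.volume_ml, r.dilution,
                                    curve, administered_mbq, nuclide)
            for r in post.itertuples()]
    times = np.array([r["time_h"] for r in recs])
    pct = np.array([r["pct_ia_per_ml"] for r in recs])
    ng = pct / 100.0 * peptide_ug * 1000.0
    flags = [r["flag"] for r in recs]
    return BloodProfile(times_h=times, conc_pct_ia_per_ml=pct, conc_ng_ml=ng, flags=flags)


def urine_excretion_pct(conc_kbq_ml_dc: float, volume_ml: float,
                        administered_mbq: float) -> float:
    """%IA excreted in a urine collection from its decay-corrected concentration."""
    return conc_kbq_ml_dc * volume_ml / (administered_mbq * 1e3) * 100.0


@dataclass(frozen=True)
class NCAResult:
    cmax: float
    tmax: float
    auc_last: float
    auc_inf: float | None
    auc_extrap_pct: float | None
    lambda_z: float | None
    terminal_t_half: float | None
    cl: float | None
    vz: float | None
    vss: float | None
    mrt_inf: float | None
    n_lambda_z_points: int


def _select_lambda_z(t: np.ndarray, c: np.ndarray, tmax: float,
                     min_adj_r2: float = 0.80):
    """Best adjusted-r2 log-linear terminal window of >= 3 points after Tmax.

    Windows spanning >= 2 fitted half-lives are preferred; ties favour more
    points.  Returns (lambda_z, n_points, adj_r2) or None.
    """
    mask = (t > tmax) & (c > 0)
    tt, cc = t[mask], c[mask]
    candidates = []
    for n in range(3, tt.size + 1):
        ts, cs = tt[-n:], np.log(cc[-n:])
        slope, intercept = np.polyfit(ts, cs, 1)
        if slope >= 0:
            continue
        pred = slope * ts + intercept
        ss_res = float(np.sum((cs - pred) ** 2))
        ss_tot = float(np.sum((cs - cs.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if adj < min_adj_r2:
            continue
        lam = -slope
        spans2 = (ts[-1] - ts[0]) >= 2.0 * LN2 / lam
        candidates.append((spans2, adj, n, lam))
    if not candidates:
        return None
    preferred = [c for c in candidates if c[0]] or candidates
    _, adj, n, lam = max(preferred, key=lambda c: (round(c[1], 10), c[2]))
    return lam, n, adj


def run_nca(profile: BloodProfile, dose_ng: float,
            min_adj_r2: float = 0.80) -> NCAResult:
    """Non-compartmental analysis of a blood concentration-time profile (ng/mL).

    ``dose_ng`` is the administered peptide mass; CL comes out in L/h,
    volumes in L.  If no terminal window meets the adjusted-r2 criterion the
    terminal-phase fields are None and AUC_last is still reported.
    """
    ok = profile.quantifiable()
    if ok.sum() < 3:
        raise ValueError("need at least 3 quantifiable post-dose points")
    t = profile.times_h[ok]
    c = profile.conc_ng_ml[ok]

    imax = int(np.argmax(c))
    cmax, tmax = float(c[imax]), float(t[imax])
    auc_last = float(np.trapezoid(c, t))
    aumc_last = float(np.trapezoid(c * t, t))

    sel = _select_lambda_z(t, c, tmax, min_adj_r2)
    if sel is None:
        return NCAResult(cmax=cmax, tmax=tmax, auc_last=auc_last, auc_inf=None,
                         auc_extrap_pct=None, lambda_z=None, terminal_t_half=None,
                         cl=None, vz=None, vss=None, mrt_inf=None, n_lambda_z_points=0)
    lam, n_pts, _ = sel
    c_last, t_last = float(c[-1]), float(t[-1])
    auc_inf = auc_last + c_last / lam
    aumc_inf = aumc_last + c_last * t_last / lam + c_last / lam**2
    mrt = aumc_inf / auc_inf
    cl_ml_h = dose_ng / auc_inf            # (ng) / (h*ng/mL) = mL/h
    cl = cl_ml_h / 1000.0                  # L/h
    return NCAResult(
        cmax=cmax, tmax=tmax, auc_last=auc_last, auc_inf=float(auc_inf),
        auc_extrap_pct=float(100.0 * (auc_inf - auc_last) / auc_inf),
        lambda_z=float(lam), terminal_t_half=float(LN2 / lam),
        cl=float(cl), vz=float(cl / lam), vss=float(cl * mrt),
        mrt_inf=float(mrt), n_lambda_z_points=int(n_pts),
    )
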