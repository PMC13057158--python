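"""Quantification of three-energy-window planar ROI counts.

Turns raw (main, lower, upper) window counts per ROI and time point into
decay-corrected organ activities: triple-energy-window (TEW) scatter
correction, reference-source half-life QC, total-body calibration at the
first imaging time, and %IA time series.

The quantification scheme is single-view and self-calibrating: the camera
sensitivity is fixed by requiring that total body + urine container at the
first scan equal the administered activity decayed to that time.  Any global
rescaling of detector sensitivity therefore cancels out of %IA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nuclide import LN2, NuclideData, decay_correct, lu177

__all__ = [
    "EnergyWindow",
    "EnergyWindowSet",
    "TewResult",
    "QuantifiedActivitySet",
    "tew_scatter_correct",
    "reference_source_qc",
    "calibrate_and_quantify",
]

TOTAL_BODY = "total body"
URINE_CONTAINER = "urine container"
REFERENCE_SOURCE = "reference source"
BACKGROUND = "background"


@dataclass(frozen=True)
class EnergyWindow:
    center_kev: float
    width_kev: float

    def __post_init__(self) -> None:
        if self.width_kev <= 0:
            raise ValueError("window width must be positive")


@dataclass(frozen=True)
class EnergyWindowSet:
    """Photopeak plus flanking scatter windows for Lu-177 planar imaging.

    Defaults: main 208 keV / 15% width (31.2 keV), lower 170 keV / 15%
    (25.5 keV), upper 240 keV / 10% (24.0 keV).
    """

    main: EnergyWindow = EnergyWindow(208.0, 31.2)
    lower: EnergyWindow = EnergyWindow(170.0, 25.5)
    upper: EnergyWindow = EnergyWindow(240.0, 24.0)


@dataclass(frozen=True)
class TewResult:
    c_sc: np.ndarray | float
    clamped: np.ndarray | bool


def tew_scatter_correct(c_main, c_low, c_upper, windows: EnergyWindowSet | None = None) -> TewResult:
    """Triple-energy-window scatter correction.

    C_SC = C_main - 1/2 * (W_main/W_low * C_low + W_main/W_upper * C_upper).
    Negative results are clamped to zero and flagged (over-subtraction is
    expected at low counts and must not silently propagate into fits).
    """
    w = windows or EnergyWindowSet()
    cm = np.asarray(c_main, dtype=float)
    cl = np.asarray(c_low, dtype=float)
    cu = np.asarray(c_upper, dtype=float)
    if np.any(cm < 0) or np.any(cl < 0) or np.any(cu < 0):
        raise ValueError("window counts must be non-negative")
    scatter = 0.5 * (w.main.width_kev / w.lower.width_kev * cl
                     + w.main.width_kev / w.upper.width_kev * cu)
    raw = cm - scatter
    clamped = raw < 0
    c_sc = np.where(clamped, 0.0, raw)
    if c_sc.ndim == 0:
        return TewResult(float(c_sc), bool(clamped))
    return TewResult(c_sc, clamped)


@dataclass(frozen=True)
class ReferenceSourceQC:
    fitted_t_half_h: float
    deviation_pct: float
    passed: bool
    tolerance_pct: float


def reference_source_qc(times_h, c_sc_counts, nuclide: NuclideData | None = None,
                        tolerance: float = 0.05) -> ReferenceSourceQC:
    """Camera QC from the co-imaged sealed reference source.

    Mono-exponential (log-linear) fit of the scatter-corrected reference
    counts vs time; passes iff the fitted half-life is within ``tolerance``
    (relative) of the physical half-life.  Constant or rising counts yield an
    infinite/negative fitted half-life and fail.
    """
    nuc = nuclide or lu177()
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(c_sc_counts, dtype=float)
    if t.size < 2:
        raise ValueError("reference-source QC needs at least 2 time points")
    if np.any(c <= 0):
        raise ValueError("non-positive reference-source counts after scatter correction")
    slope, _ = np.polyfit(t, np.log(c), 1)
    rate = -slope
    t_half = LN2 / rate if rate > 0 else math.inf
    dev = abs(t_half - nuc.t_phys_h) / nuc.t_phys_h if math.isfinite(t_half) else math.inf
    return ReferenceSourceQC(
        fitted_t_half_h=t_half,
        deviation_pct=100.0 * dev if math.isfinite(dev) else math.inf,
        passed=bool(dev <= tolerance),
        tolerance_pct=100.0 * tolerance,
    )


@dataclass
class QuantifiedActivitySet:
    """Per time point, per ROI: scatter-corrected rate, activity and %IA.

    ``table`` columns: time_h, roi, c_sc (counts/s), activity_MBq
    (as measured, i.e. physically decayed), pct_ia_measured (same, as %IA),
    pct_ia (decay-corrected to injection), flags.  ``calibration_factor`` is
    MBq per (count/s).
    """

    table: pd.DataFrame
    calibration_factor: float
    qc: ReferenceSourceQC | None
    partially_observed: dict = field(default_factory=dict)

    def organ_series(self, roi: str) -> pd.DataFrame:
        sub = self.table[self.table["roi"] == roi].sort_values("time_h")
        if sub.empty:
            raise KeyError(f"no quantified ROI {roi!r}")
        return sub.reset_index(drop=True)


def _pivot_windows(scans: pd.DataFrame) -> pd.DataFrame:
    required = {"time_h", "roi", "window", "counts", "roi_area_px", "duration_s"}
    missing = required - set(scans.columns)
    if missing:
        raise ValueError(f"planar counts table missing columns: {sorted(missing)}")
    wide = scans.pivot_table(index=["time_h", "roi", "roi_area_px", "duration_s"],
                             columns="window", values="counts").reset_index()
    for w in ("main", "low", "upper"):
        if w not in wide.columns:
            raise ValueError(f"missing energy window {w!r} in planar counts")
    return wide


def calibrate_and_quantify(
    scans: pd.DataFrame,
    administered_mbq: float,
    nuclide: NuclideData | None = None,
    windows: EnergyWindowSet | None = None,
    qc_tolerance: float = 0.05,
    expected_n_timepoints: int | None = None,
) -> QuantifiedActivitySet:
    """Quantify a three-window planar count table into organ %IA series.

    Steps: per-window background-density subtraction (background ROI rate per
    pixel scaled by each ROI's area), TEW scatter correction, total-body +
    urine-container calibration at the first imaging time, activity scaling
    and decay correction to the injection time.

    The first time point must contain total-body and urine-container ROIs.
    An organ missing a time point is marked partially observed (fits proceed
    downstream if at least 3 points remain).
    """
    if administered_mbq <= 0:
        raise ValueError("administered activity must be positive")
    nuc = nuclide or lu177()
    win = windows or EnergyWindowSet()
    wide = _pivot_windows(scans)
    times = np.sort(wide["time_h"].unique())

    # background count-rate density per pixel, per window and time point
    bkg = wide[wide["roi"] == BACKGROUND].set_index("time_h")
    rows = []
    for _, r in wide[wide["roi"] != BACKGROUND].iterrows():
        t = r["time_h"]
        corrected = {}
        for w in ("main", "low", "upper"):
            rate = r[w] / r["duration_s"]
            if t in bkg.index:
                b = bkg.loc[t]
                rate -= (b[w] / b["duration_s"]) / b["roi_area_px"] * r["roi_area_px"]
            corrected[w] = max(rate, 0.0)
        tew = tew_scatter_correct(corrected["main"], corrected["low"], corrected["upper"], win)
        rows.append({"time_h": t, "roi": r["roi"], "c_sc": tew.c_sc,
                     "flags": "tew-clamped" if tew.clamped else ""})
    rates = pd.DataFrame(rows)

    t1 = times[0]
    first = rates[rates["time_h"] == t1].set_index("roi")
    if TOTAL_BODY not in first.index:
        raise ValueError("first imaging time point lacks a total-body ROI")
    if URINE_CONTAINER not in first.index:
        raise ValueError("first imaging time point lacks a urine-container ROI; "
                         "cannot calibrate")
    denom = first.loc[TOTAL_BODY, "c_sc"] + first.loc[URINE_CONTAINER, "c_sc"]
    if denom <= 0:
        raise ValueError("zero scatter-corrected counts in calibration ROIs")
    administered_at_t1 = decay_correct(administered_mbq, t1, nuc, "to-measurement")
    factor = administered_at_t1 / denom

    out = rates.copy()
    out["activity_MBq"] = out["c_sc"] * factor
    # both series are reported: as-measured %IA (carries physical decay, used
    # for t_eff fits) and decay-corrected %IA (tracer view, used for t_bio)
    out["pct_ia_measured"] = out["activity_MBq"] / administered_mbq * 100.0
    out["pct_ia"] = (decay_correct(out["activity_MBq"].to_numpy(), out["time_h"].to_numpy(), nuc)
                     / administered_mbq * 100.0)

    qc = None
    ref = out[out["roi"] == REFERENCE_SOURCE]
    if len(ref) >= 2:
        qc = reference_source_qc(ref["time_h"].to_numpy(), ref["c_sc"].to_numpy(),
                                 nuc, qc_tolerance)

    n_expected = expected_n_timepoints or len(times)
    partial = {}
    for roi, grp in out.groupby("roi"):
        if roi in (URINE_CONTAINER, REFERENCE_SOURCE):
            continue
        n_missing = n_expected - grp["time_h"].nunique()
        if n_missing > 0:
            partial[roi] = n_missing
    return QuantifiedActivitySet(table=out, calibration_factor=factor, qc=qc,
                                 partially_observed=partial)
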