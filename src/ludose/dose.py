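"""MIRD-schema organ dosimetry: S-value matrix, sphere model, effective dose.

Absorbed dose to a target region is the MIRD sum over source regions,
D(target) = sum_s TIAC(s) * S(target <- s), with S in mGy per MBq*h.  The
S-value matrix is an explicit, user-auditable CSV input; a bundled toy
phantom matrix (built from Lu-177 non-penetrating energy deposited locally
plus a small uniform photon cross-fire term) makes the pipeline runnable
end-to-end without proprietary phantom tables.

Small unit-density spheres (used for the 0.7 g lacrimal glands) get their
self-dose S-value from a power-function (log-log) interpolation of a knot
table; with the default photon-free table this is exactly E_np * kappa / m.

For the beta/gamma emissions considered here the radiation weighting factor
is 1, so absorbed dose in mGy and equivalent dose in mSv are numerically
equal; the ICRP 103 tissue-weighted sum of equivalent doses gives the
effective dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple

import numpy as np
import pandas as pd

from .nuclide import NuclideData, lu177

__all__ = [
    "MEV_PER_DECAY_TO_MGY_G_PER_MBQ_H",
    "SValueMatrix",
    "TissueWeights",
    "DoseReport",
    "SixCycleDose",
    "DEFAULT_ORGAN_MASSES_G",
    "toy_phantom_smatrix",
    "organ_dose",
    "sphere_svalue",
    "default_sphere_table",
    "icrp103_weights",
    "effective_dose",
    "six_cycle_dose",
    "round_2sf",
    "SIX_CYCLE_MBQ",
]

# 1 MeV = 1.602e-13 J; per gram -> 1.602e-7 mGy*g; 1 MBq*h = 3.6e9 decays.
MEV_PER_DECAY_TO_MGY_G_PER_MBQ_H = 1.602e-13 * 1e3 * 1e3 * 3.6e9  # = 576.72

#: Maximal cumulative administered activity over six treatment cycles, MBq.
SIX_CYCLE_MBQ = 44_400.0

#: Toy reference masses (g) for the bundled phantom; configuration-exposed.
DEFAULT_ORGAN_MASSES_G = {
    "kidneys": 310.0,
    "liver": 1800.0,
    "spleen": 150.0,
    "heart wall": 330.0,
    "lungs": 1000.0,
    "right colon": 150.0,
    "left colon": 145.0,
    "rectosigmoid": 70.0,
    "red marrow": 1170.0,
    "thyroid": 20.0,
    "salivary glands": 85.0,
    "urinary bladder contents": 200.0,
    "urinary bladder wall": 50.0,
    "remainder": 50000.0,
    "total body": 73000.0,
}

#: Source region -> target region receiving its locally deposited electrons.
_SELF_TARGET = {
    "kidneys": "kidneys",
    "liver": "liver",
    "spleen": "spleen",
    "heart wall": "heart wall",
    "lungs": "lungs",
    "right colon": "right colon",
    "left colon": "left colon",
    "rectosigmoid": "rectum",
    "red marrow": "red marrow",
    "thyroid": "thyroid",
    "salivary glands": "salivary glands",
    "remainder": "remainder",
    "total body": "total body",
}


@dataclass
class SValueMatrix:
    """S-values (mGy per MBq*h) as a targets x sources table.

    ``table`` is a DataFrame indexed by target with one column per source
    region.  CSV round-trips use the long format
    ``source,target,S_mGy_per_MBq_h,phantom_label``.
    """

    table: pd.DataFrame
    phantom_label: str = "unlabelled"
    organ_masses_g: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.table.to_numpy() < 0).any():
            raise ValueError("S-values must be non-negative")
        for m in self.organ_masses_g.values():
            if m <= 0:
                raise ValueError("organ masses must be positive")

    @property
    def sources(self) -> list:
        return list(self.table.columns)

    @property
    def targets(self) -> list:
        return list(self.table.index)

    def to_csv(self, path) -> None:
        long = self.table.stack().rename("S_mGy_per_MBq_h").reset_index()
        long.columns = ["target", "source", "S_mGy_per_MBq_h"]
        long["phantom_label"] = self.phantom_label
        long[["source", "target", "S_mGy_per_MBq_h", "phantom_label"]].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, organ_masses_g: dict | None = None) -> "SValueMatrix":
        long = pd.read_csv(path)
        required = {"source", "target", "S_mGy_per_MBq_h"}
        if not required <= set(long.columns):
            raise ValueError(f"S-matrix CSV needs columns {sorted(required)}")
        label = str(long["phantom_label"].iloc[0]) if "phantom_label" in long else "unlabelled"
        table = long.pivot_table(index="target", columns="source",
                                 values="S_mGy_per_MBq_h", fill_value=0.0)
        return cls(table=table, phantom_label=label,
                   organ_masses_g=dict(organ_masses_g or {}))


def toy_phantom_smatrix(nuclide: NuclideData | None = None,
                        organ_masses_g: dict | None = None,
                        photon_absorbed_fraction: float = 0.3) -> SValueMatrix:
    """Build the bundled synthetic (toy) phantom S-value matrix.

    Electron (non-penetrating) energy is absorbed entirely in the source
    region itself: S_self = E_np * kappa / m_target.  Photons are treated as
    uniformly mixed over the whole body with a single absorbed fraction, so
    every source adds the same small cross-fire term E_ph * phi * kappa /
    m_total_body to every target.  The bladder wall receives half the
    contents' surface electron dose.  This is a documented stand-in geometry,
    not a Monte-Carlo phantom.
    """
    nuc = nuclide or lu177()
    masses = dict(DEFAULT_ORGAN_MASSES_G)
    masses.update(organ_masses_g or {})
    kappa = MEV_PER_DECAY_TO_MGY_G_PER_MBQ_H
    sources = list(_SELF_TARGET) + ["urinary bladder contents"]
    targets = sorted({*(_SELF_TARGET.values()), "urinary bladder wall"})
    cross = nuc.photon_energy_mev * photon_absorbed_fraction * kappa / masses["total body"]
    table = pd.DataFrame(cross, index=pd.Index(targets, name="target"),
                         columns=pd.Index(sources, name="source"))
    for src, tgt in _SELF_TARGET.items():
        table.loc[tgt, src] += nuc.e_np_mev * kappa / masses[tgt if tgt != "rectum" else "rectosigmoid"]
    table.loc["urinary bladder wall", "urinary bladder contents"] += (
        0.5 * nuc.e_np_mev * kappa / masses["urinary bladder contents"])
    return SValueMatrix(table=table, phantom_label="ludose-toy-phantom-v1",
                        organ_masses_g=masses)


def organ_dose(tiacs: dict, s: SValueMatrix) -> dict:
    """MIRD dose sum: D(target) = sum_source TIAC(source) * S(target <- source).

    Every TIAC region must map to a source column of the matrix; an unmapped
    region is an error naming it.  Output in mGy/MBq (TIACs in MBq*h/MBq).
    """
    unmapped = [r for r in tiacs if r not in s.table.columns]
    if unmapped:
        raise KeyError(f"TIAC regions not in S-matrix sources: {unmapped}")
    doses = {}
    for tgt in s.targets:
        doses[tgt] = float(sum(s.table.loc[tgt, src] * v for src, v in tiacs.items()))
    return doses


def default_sphere_table(nuclide: NuclideData | None = None,
                         photon_term_mgy_per_mbq_h=None) -> pd.DataFrame:
    """Knot table of unit-density-sphere self-dose S-values for Lu-177.

    Local non-penetrating absorption S_np(m) = E_np * kappa / m at knot
    masses spanning 0.1-10 g, plus an optional per-knot photon term
    (default 0: photon self-absorption is negligible for sub-10 g spheres).
    """
    nuc = nuclide or lu177()
    masses = np.array([0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0])
    s = nuc.e_np_mev * MEV_PER_DECAY_TO_MGY_G_PER_MBQ_H / masses
    if photon_term_mgy_per_mbq_h is not None:
        s = s + np.asarray(photon_term_mgy_per_mbq_h, dtype=float)
    return pd.DataFrame({"mass_g": masses, "S_mGy_per_MBq_h": s})


def sphere_svalue(mass_g: float, table: pd.DataFrame | None = None) -> float:
    """Sphere-model self-dose S-value by power-function interpolation.

    Log-log linear interpolation between bracketing knots, i.e. locally
    S(m) = a * m^b; valid for masses within the table range extended one
    decade to each side (power-law extrapolation from the end segments).
    """
    if mass_g <= 0:
        raise ValueError("sphere mass must be positive")
    tab = table if table is not None else default_sphere_table()
    m = tab["mass_g"].to_numpy(dtype=float)
    s = tab["S_mGy_per_MBq_h"].to_numpy(dtype=float)
    if np.any(m <= 0) or np.any(s <= 0) or np.any(np.diff(m) <= 0):
        raise ValueError("sphere table must have increasing positive masses and positive S")
    if not (m[0] / 10.0 <= mass_g <= m[-1] * 10.0):
        raise ValueError(f"mass {mass_g} g outside interpolable range "
                         f"[{m[0] / 10.0}, {m[-1] * 10.0}] g")
    logm = np.log(m)
    x = math.log(mass_g)
    i = int(np.clip(np.searchsorted(logm, x) - 1, 0, m.size - 2))
    b = (math.log(s[i + 1]) - math.log(s[i])) / (logm[i + 1] - logm[i])
    return float(s[i] * math.exp(b * (x - logm[i])))


#: ICRP Publication 103 tissue weighting factors (sum exactly 1.0).
_ICRP103_WT = {
    "red marrow": 0.12,
    "colon": 0.12,
    "lung": 0.12,
    "stomach": 0.12,
    "breast": 0.12,
    "gonads": 0.08,
    "bladder": 0.04,
    "oesophagus": 0.04,
    "liver": 0.04,
    "thyroid": 0.04,
    "bone surface": 0.01,
    "brain": 0.01,
    "salivary glands": 0.01,
    "skin": 0.01,
    "remainder": 0.12,
}

#: The 13 named remainder tissues (male set) averaged for the remainder dose.
_ICRP103_REMAINDER = (
    "adrenals", "extrathoracic region", "gall bladder", "heart wall",
    "kidneys", "lymphatic nodes", "muscle", "oral mucosa", "pancreas",
    "prostate", "small intestine", "spleen", "thymus",
)


@dataclass(frozen=True)
class TissueWeights:
    """ICRP 103 tissue weighting factors w_T plus the remainder rule."""

    weights: dict
    remainder_tissues: tuple

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"tissue weights must sum to 1, got {total}")


def icrp103_weights() -> TissueWeights:
    return TissueWeights(weights=dict(_ICRP103_WT),
                         remainder_tissues=_ICRP103_REMAINDER)


def effective_dose(equivalent_doses: dict, weights: TissueWeights | None = None) -> float:
    """Tissue-weighted effective dose E = sum_T w_T * H_T, in mSv.

    ``equivalent_doses`` maps ICRP 103 tissue labels (weighted tissues and/or
    named remainder tissues) to equivalent dose in mSv.  A ``"remainder"``
    entry acts as the fallback for weighted tissues without an explicit dose
    and for unnamed remainder tissues; the remainder H_T is the arithmetic
    mean over the 13 named remainder tissues.  Unknown labels raise.
    """
    w = weights or icrp103_weights()
    known = set(w.weights) | set(w.remainder_tissues)
    unknown = [t for t in equivalent_doses if t not in known]
    if unknown:
        raise KeyError(f"unknown tissue labels: {unknown}")
    fallback = equivalent_doses.get("remainder")

    def dose_for(tissue: str) -> float:
        if tissue in equivalent_doses:
            return equivalent_doses[tissue]
        if fallback is None:
            raise KeyError(f"no dose for tissue {tissue!r} and no remainder fallback")
        return fallback

    e = 0.0
    for tissue, wt in w.weights.items():
        if tissue == "remainder":
            h = float(np.mean([dose_for(t) for t in w.remainder_tissues]))
        else:
            h = dose_for(tissue)
        e += wt * h
    return float(e)


def round_2sf(x: float) -> float:
    """Round to 2 significant figures, half-up (report-table convention)."""
    if x == 0:
        return 0.0
    d = Decimal(repr(float(x)))
    exp = d.adjusted()  # position of the leading digit
    q = Decimal(1).scaleb(exp - 1)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


class SixCycleDose(NamedTuple):
    gy: float
    gy_2sf: float


def six_cycle_dose(normalized_mgy_per_mbq: float) -> SixCycleDose:
    """Cumulative six-cycle absorbed dose from a cycle-1 normalized dose.

    normalized (mGy/MBq) * 44,400 MBq -> mGy -> Gy; reported raw and rounded
    to 2 significant figures (half-up).
    """
    if normalized_mgy_per_mbq < 0:
        raise ValueError("normalized dose must be non-negative")
    gy = normalized_mgy_per_mbq * SIX_CYCLE_MBQ / 1000.0
    return SixCycleDose(gy=gy, gy_2sf=round_2sf(gy))


@dataclass
class DoseReport:
    """Per-target absorbed doses with effective dose and six-cycle estimates.

    ``normalized_mgy_per_mbq`` maps target region -> mGy/MBq for cycle 1;
    ``absolute_mgy`` scales by the administered activity; ``six_cycle_gy``
    holds (raw, 2-significant-figure) cumulative doses.
    """

    normalized_mgy_per_mbq: dict
    absolute_mgy: dict
    effective_dose_msv: float
    six_cycle_gy: dict

    @classmethod
    def from_doses(cls, normalized: dict, administered_mbq: float,
                   effective_dose_msv: float) -> "DoseReport":
        if administered_mbq <= 0:
            raise ValueError("administered activity must be positive")
        if any(v < 0 for v in normalized.values()):
            raise ValueError("doses must be non-negative")
        return cls(
            normalized_mgy_per_mbq=dict(normalized),
            absolute_mgy={k: v * administered_mbq for k, v in normalized.items()},
            effective_dose_msv=effective_dose_msv,
            six_cycle_gy={k: six_cycle_dose(v) for k, v in normalized.items()},
        )
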