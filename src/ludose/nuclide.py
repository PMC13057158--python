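"""Physical decay constants, half-life algebra and geometric summary statistics.

All time quantities are in hours; activities keep whatever unit they come in
with (decay correction is a pure scale factor).  The bundled Lu-177 record
fixes the physical half-life at 161.6 h, the value used consistently by every
decay correction in this package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

LN2 = math.log(2.0)

__all__ = [
    "LN2",
    "NuclideData",
    "GeoStats",
    "lu177",
    "decay_correct",
    "effective_half_life",
    "biological_half_life",
    "geo_stats",
]


@dataclass(frozen=True)
class NuclideData:
    """Single-nuclide decay data.

    Parameters
    ----------
    name : str
        Nuclide label, e.g. ``"Lu-177"``.
    t_phys_h : float
        Physical half-life in hours.
    e_np_mev : float
        Mean non-penetrating (electron) energy emitted per decay, MeV.
    photon_lines : tuple of (float, float)
        Principal gamma lines as ``(energy_keV, yield_per_decay)``.
    """

    name: str
    t_phys_h: float
    e_np_mev: float = 0.0
    photon_lines: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.t_phys_h > 0:
            raise ValueError("physical half-life must be positive")
        for _, y in self.photon_lines:
            if not 0.0 <= y <= 1.0:
                raise ValueError("photon yields must lie in [0, 1]")

    @property
    def lambda_phys(self) -> float:
        """Physical decay constant, 1/h (= ln 2 / t_phys)."""
        return LN2 / self.t_phys_h

    @property
    def photon_energy_mev(self) -> float:
        """Mean photon energy emitted per decay (sum of line energy x yield), MeV."""
        return sum(e * y for e, y in self.photon_lines) / 1000.0


def lu177() -> NuclideData:
    """Load the bundled Lu-177 record (t_phys = 161.6 h)."""
    raw = json.loads(resources.files("ludose.data").joinpath("lu177.json").read_text())
    return NuclideData(
        name=raw["name"],
        t_phys_h=raw["t_phys_h"],
        e_np_mev=raw["E_np_MeV"],
        photon_lines=tuple((ln["keV"], ln["yield"]) for ln in raw["photon_lines"]),
    )


def decay_correct(activity, t_h, nuclide: NuclideData, direction: str = "to-reference"):
    """Correct a measured activity for physical decay over ``t_h`` hours.

    ``direction="to-reference"`` back-corrects a measurement made ``t_h`` hours
    after the reference time (multiplies by ``exp(+lambda * t)``);
    ``"to-measurement"`` is the inverse.  Works on scalars and arrays.
    """
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since reference must be non-negative")
    factor = np.exp(nuclide.lambda_phys * t)
    if direction == "to-reference":
        out = np.asarray(activity, dtype=float) * factor
    elif direction == "to-measurement":
        out = np.asarray(activity, dtype=float) / factor
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(out) if np.isscalar(activity) and out.ndim == 0 else out


def effective_half_life(t_bio_h: float, t_phys_h: float) -> float:
    """Combine biological and physical half-lives: 1/t_eff = 1/t_bio + 1/t_phys."""
    if not (t_bio_h > 0 and t_phys_h > 0):
        raise ValueError("half-lives must be positive")
    return 1.0 / (1.0 / t_bio_h + 1.0 / t_phys_h)


def biological_half_life(t_eff_h: float, t_phys_h: float) -> float:
    """Invert the effective half-life relation: 1/t_bio = 1/t_eff - 1/t_phys.

    Raises for ``t_eff >= t_phys`` (no biological clearance resolvable).
    """
    if not (t_eff_h > 0 and t_phys_h > 0):
        raise ValueError("half-lives must be positive")
    if t_eff_h >= t_phys_h:
        raise ValueError(
            f"effective half-life ({t_eff_h} h) must be shorter than the "
            f"physical half-life ({t_phys_h} h)"
        )
    return 1.0 / (1.0 / t_eff_h - 1.0 / t_phys_h)


@dataclass(frozen=True)
class GeoStats:
    """Geometric mean / geometric CV% summary of a positive sample."""

    geo_mean: float
    geo_cv_pct: float
    n: int


def geo_stats(values: Sequence[float] | Iterable[float]) -> GeoStats:
    """Geometric mean and geometric CV% of strictly positive values.

    geo_mean = exp(mean(ln x)); geo_cv% = 100 * sqrt(exp(s^2) - 1) with s^2
    the (n-1)-denominator sample variance of ln x (lognormal-exact convention).
    A single value has geo_cv% = 0.  Any non-positive value is an error, never
    a silent drop.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("need at least one value")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("geometric statistics require strictly positive finite values")
    logs = np.log(x)
    gm = float(np.exp(logs.mean()))
    if x.size == 1:
        return GeoStats(geo_mean=gm, geo_cv_pct=0.0, n=1)
    s2 = float(np.var(logs, ddof=1))
    return GeoStats(geo_mean=gm, geo_cv_pct=100.0 * math.sqrt(math.expm1(s2)), n=int(x.size))
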