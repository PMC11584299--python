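"""Aggregated canopy model (ACM-1): daily GPP from leaf area and weather.

The canopy is treated as a single big leaf whose photosynthesis is
co-limited by light and by CO2 diffusion through an empirically
parameterised canopy conductance.  The inputs are leaf area index,
minimum/maximum air temperature, incident shortwave radiation, atmospheric
CO2 and day length; the output is daily gross primary productivity in
gC m-2 d-1.  The ten empirical coefficients (and the two fixed hydraulic
constants psi_d and r_tot) are shipped as versioned YAML data so a
different calibrated vintage can be substituted without touching code.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from . import _kernel

__all__ = [
    "AcmConstants",
    "load_acm_constants",
    "day_length",
    "internal_co2",
    "acm_gpp",
]


@dataclass(frozen=True)
class AcmConstants:
    """Empirical coefficient set of the canopy model.

    ``e1`` is the canopy-efficiency slot; it is calibrated per site (the
    ``c_eff`` process parameter) and is not part of the fixed set.
    """

    e2: float
    e3: float
    e4: float
    e5: float
    e6: float
    e7: float
    e8: float
    e9: float
    e10: float
    psi_d: float
    r_tot: float
    name: str = "acm1_default"
    checksum: str = ""

    def as_array(self) -> np.ndarray:
        """Flat [e1..e10, psi_d, r_tot] layout consumed by the kernel."""
        return np.array(
            [np.nan, self.e2, self.e3, self.e4, self.e5, self.e6, self.e7,
             self.e8, self.e9, self.e10, self.psi_d, self.r_tot]
        )


def load_acm_constants(path=None) -> AcmConstants:
    """Load a coefficient set from YAML (default: the shipped acm1 set).

    The SHA-256 checksum of the raw file is recorded on the returned object
    so a run's provenance can be pinned bit-exactly.
    """
    if path is None:
        raw = resources.files("fenfusion.data").joinpath("acm1.yaml").read_bytes()
    else:
        with open(path, "rb") as fh:
            raw = fh.read()
    doc = yaml.safe_load(raw)
    checksum = hashlib.sha256(raw).hexdigest()
    fields = {k: float(doc[k]) for k in
              ("e2", "e3", "e4", "e5", "e6", "e7", "e8", "e9", "e10",
               "psi_d", "r_tot")}
    return AcmConstants(name=str(doc.get("name", "custom")),
                        checksum=checksum, **fields)


def day_length(latitude: float, doy: float) -> float:
    """Hours of daylight from standard solar declination geometry.

    Parameters
    ----------
    latitude : degrees north (-90..90)
    doy : day of year (1..366)
    """
    if not (-90.0 <= latitude <= 90.0):
        raise ValueError(f"latitude out of range: {latitude}")
    if not (1.0 <= doy <= 366.0):
        raise ValueError(f"day of year out of range: {doy}")
    dec = -23.45 * math.cos(2.0 * math.pi * (doy + 10.0) / 365.25)
    cos_h = -math.tan(math.radians(latitude)) * math.tan(math.radians(dec))
    cos_h = min(1.0, max(-1.0, cos_h))
    hour_angle = math.degrees(math.acos(cos_h))
    return 2.0 * hour_angle / 15.0


def internal_co2(ca: float, pp: float, qq: float, e3: float) -> float:
    """Internal CO2 from the canopy supply/demand quadratic.

    Solves ``ci^2 - (ca + qq - pp) ci + (ca*qq - pp*e3) = 0`` and returns
    the physically meaningful (larger) root, which lies in ``(0, ca]`` for
    valid coefficient sets; ``ci -> ca`` as photosynthetic demand
    ``pp -> 0`` (no drawdown).
    """
    if ca <= 0:
        raise ValueError("ambient CO2 must be positive")
    b = ca + qq - pp
    disc = b * b - 4.0 * (ca * qq - pp * e3)
    if disc < 0:
        raise ArithmeticError(
            f"negative discriminant in internal-CO2 quadratic "
            f"(ca={ca}, pp={pp}, qq={qq}, e3={e3})"
        )
    return 0.5 * (b + math.sqrt(disc))


def acm_gpp(lai: float, met, c_eff: float,
            constants: AcmConstants | None = None) -> float:
    """Daily GPP (gC m-2 d-1) for one week's mean meteorology.

    ``met`` needs attributes ``t_min, t_max, sw_rad, co2, day_length``
    (a MeteoWeek, a driver-table row, or anything duck-typed alike).
    Returns 0 when there is no leaf area or no light.
    """
    if lai < 0:
        raise ValueError("leaf area index must be non-negative")
    if constants is None:
        constants = load_acm_constants()
    out = _kernel.acm_gpp_scalar(
        float(lai), float(met.t_min), float(met.t_max), float(met.sw_rad),
        float(met.co2), float(met.day_length), float(c_eff),
        constants.as_array(),
    )
    if math.isnan(out):
        raise ArithmeticError("canopy model produced a non-finite GPP")
    return out
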