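"""Single-point HPLC quantitation against the time-zero reference peak.

Concentrations are obtained by comparing a well's peak area with the donor
peak area measured at time zero, assuming a linear detector response shared
by donor and acceptor wells (same analyte, same chromatographic method):

    C = C_D0_nominal * area / area_t0

No calibration curve, peak integration or baseline handling is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

__all__ = ["PeakAreaRecord", "peak_area_to_concentration"]


@dataclass(frozen=True)
class PeakAreaRecord:
    """One detector response: which well it came from and its peak area."""

    compound_id: str
    well_role: Literal["donor_t0", "donor_t", "acceptor_t"]
    area: float

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("peak area must be ≥ 0")
        if self.well_role not in ("donor_t0", "donor_t", "acceptor_t"):
            raise ValueError(f"unknown well role {self.well_role!r}")


def peak_area_to_concentration(
    area: float, area_t0: float, C_D0_nominal: float
) -> float:
    """Convert a peak area to a concentration via the t0 reference ratio.

    Parameters
    ----------
    area : float
        Peak area of the measured well (arbitrary detector units, ≥ 0).
    area_t0 : float
        Peak area of the donor well at time zero (> 0), same units.
    C_D0_nominal : float
        Nominal donor concentration at t0 (mol·cm⁻³).

    Returns
    -------
    float
        Concentration in mol·cm⁻³; linear in ``area`` and invariant to any
        common rescaling of both areas.
    """
    if not area_t0 > 0:
        raise ValueError("area_t0 must be > 0 (no reference peak)")
    if area < 0:
        raise ValueError("peak area must be ≥ 0")
    return C_D0_nominal * area / area_t0
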