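"""Core PAMPA data reduction.

From one well's three concentrations the pipeline derives:

* the retention factor ``R`` — the mole fraction lost to the membrane and
  plate materials (mass balance over both compartments);
* the permeation parameter ``C_A(t)/C_D(0)`` — the fraction of the initial
  donor amount found in the acceptor;
* the effective permeability ``Pe`` (cm/s) from the integrated two-compartment
  first-order transport model with a steady-state lag time, the acceptor
  equilibrium corrected for membrane retention;
* the predicted human-skin permeability ``log Kp`` from a published linear
  regression on ``log Pe``.

Two volume conventions are provided. ``"actual"`` (the default) is the exact
unequal-volume solution of the two-compartment model:

    Pe = −[V_A·V_D / ((V_A+V_D)·A_eff·(t−τ))]
         · ln(1 − (V_A+V_D)/((1−R)·V_D) · C_A(t)/C_D(0))

``"equal"`` is the commonly quoted equal-volume form (V = V_D):

    Pe = −[V / (2·A_eff·(t−τ))] · ln(1 − 2·(C_A(t)/C_D(0))/(1−R))

The two agree exactly when V_A = V_D. ``A_eff`` is the filter area multiplied
by the nominal porosity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, NamedTuple, Optional, Sequence

import numpy as np

from .plate_model import (
    AssayGeometry,
    CompoundSummary,
    PermeabilityResult,
    PlateValidationError,
    WellMeasurement,
    BELOW_DETECTION_R,
)

__all__ = [
    "KpRegression",
    "Retention",
    "retention_factor",
    "permeation_parameter",
    "effective_permeability",
    "log_kp_from_log_pe",
    "round_half_up",
    "analyze_measurement",
    "aggregate_triplicates",
]

logger = logging.getLogger(__name__)

#: Tolerance band for clamping slightly out-of-range raw retention values
#: caused by measurement noise; beyond it the mass balance is inconsistent.
R_CLAMP_TOL = 0.05

VolumeMode = Literal["actual", "equal"]


@dataclass(frozen=True)
class KpRegression:
    """Linear map from membrane log Pe to human-skin log Kp.

    Defaults are the published correlation for the 70% silicone / 30% IPM
    membrane at 7 h incubation (r² = 0.81, 31 compounds):
    log Kp = (1.34 ± 0.12)·log Pe + (0.28 ± 0.56).
    """

    slope: float = 1.34
    slope_se: float = 0.12
    intercept: float = 0.28
    intercept_se: float = 0.56

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("regression slope must be nonzero")


class Retention(NamedTuple):
    """Retention fraction plus whether it was clamped into [0, 1]."""

    value: float
    clamped: bool


def _check_mode(volume_mode: str) -> None:
    if volume_mode not in ("actual", "equal"):
        raise ValueError(f"unknown volume_mode {volume_mode!r}")


def retention_factor(
    m: WellMeasurement,
    g: AssayGeometry,
    volume_mode: VolumeMode = "actual",
) -> Retention:
    """Mole fraction of compound retained in the membrane and plate.

    ``"actual"`` mode balances moles with the true well volumes:
    ``R = 1 − C_Dt/C_D0 − (V_A/V_D)·C_At/C_D0``; ``"equal"`` mode uses the
    equal-volume simplification ``R = 1 − C_Dt/C_D0 − C_At/C_D0``.

    Raw values within ``R_CLAMP_TOL`` outside [0, 1] — expected from detector
    noise on nearly-unretained or nearly-fully-retained compounds — are
    clamped and flagged; values further out raise, since they signal
    inconsistent measurements rather than noise.
    """
    _check_mode(volume_mode)
    if not m.C_D0 > 0:
        raise PlateValidationError("C_D0 must be > 0")
    ratio_d = m.C_Dt / m.C_D0
    ratio_a = m.C_At / m.C_D0
    if volume_mode == "actual":
        raw = 1.0 - ratio_d - (g.V_A / g.V_D) * ratio_a
    else:
        raw = 1.0 - ratio_d - ratio_a
    if raw < -R_CLAMP_TOL or raw > 1.0 + R_CLAMP_TOL:
        raise PlateValidationError(
            f"{m.compound_id}/{m.replicate_id}: raw retention {raw:.4f} "
            f"outside [-{R_CLAMP_TOL}, 1+{R_CLAMP_TOL}] — inconsistent "
            "mass balance")
    if raw < 0.0:
        return Retention(0.0, True)
    if raw > 1.0:
        return Retention(1.0, True)
    return Retention(raw, False)


def permeation_parameter(m: WellMeasurement) -> float:
    """Fraction of the initial donor amount found in the acceptor: C_At/C_D0."""
    if not m.C_D0 > 0:
        raise PlateValidationError("C_D0 must be > 0")
    return m.C_At / m.C_D0


def effective_permeability(
    perm_param: float,
    R: float,
    g: AssayGeometry,
    volume_mode: VolumeMode = "actual",
) -> Optional[float]:
    """Effective permeability coefficient Pe (cm/s).

    Returns ``None`` (rather than raising) when the log argument is ≤ 0,
    i.e. the acceptor concentration is at or past the retention-corrected
    equilibrium and the first-order rate is unidentifiable at this
    incubation time; batch plate processing flags and continues.
    """
    _check_mode(volume_mode)
    if perm_param < 0:
        raise PlateValidationError("perm_param must be ≥ 0")
    if R >= 1:
        raise PlateValidationError(
            "R = 1: fully retained compound has no defined permeability")
    if R < 0:
        raise PlateValidationError("R must be ≥ 0")
    t_eff = g.t_transport
    if t_eff <= 0:
        raise PlateValidationError("t_incubation − tau_lag must be > 0")
    A_eff = g.A_eff
    if volume_mode == "actual":
        arg = 1.0 - (g.V_A + g.V_D) / ((1.0 - R) * g.V_D) * perm_param
        prefactor = (g.V_A * g.V_D) / ((g.V_A + g.V_D) * A_eff * t_eff)
    else:
        arg = 1.0 - 2.0 * perm_param / (1.0 - R)
        prefactor = g.V_D / (2.0 * A_eff * t_eff)
    if arg <= 0.0:
        return None
    return -prefactor * math.log(arg)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (ties away from zero), as printed tables use."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def log_kp_from_log_pe(
    log_Pe: float, reg: KpRegression | None = None
) -> float:
    """Predicted human-skin log Kp (log10 cm/s) from membrane log Pe."""
    if reg is None:
        reg = KpRegression()
    if not math.isfinite(log_Pe):
        raise ValueError("log_Pe must be finite")
    return reg.slope * log_Pe + reg.intercept


def analyze_measurement(
    m: WellMeasurement,
    g: AssayGeometry,
    volume_mode: VolumeMode = "actual",
    regression: KpRegression | None = None,
) -> PermeabilityResult:
    """Full per-replicate reduction: R, C_A(t)/C_D(0), Pe, log Pe, log Kp."""
    ret = retention_factor(m, g, volume_mode)
    perm = permeation_parameter(m)
    perm = min(perm, 1.0)  # noise guard at the reporting boundary
    pe = effective_permeability(perm, ret.value, g, volume_mode) \
        if ret.value < 1 else None
    if pe is None or pe <= 0:
        log_pe = log_kp = None
        pe_out = pe
    else:
        log_pe = math.log10(pe)
        log_kp = log_kp_from_log_pe(log_pe, regression)
        pe_out = pe
    return PermeabilityResult(
        compound_id=m.compound_id,
        replicate_id=m.replicate_id,
        R=ret.value,
        perm_param=perm,
        Pe=pe_out,
        log_Pe=log_pe,
        log_Kp=log_kp,
        R_clamped=ret.clamped,
    )


def _mean_sd(values: Sequence[float]) -> tuple[float, Optional[float]]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return mean, sd


def aggregate_triplicates(
    results: Sequence[PermeabilityResult],
    regression: KpRegression | None = None,
) -> list[CompoundSummary]:
    """Aggregate per-replicate results into one summary per compound.

    Means and sample SDs (n−1) are taken over replicates; log Pe statistics
    are computed in the log10 domain. Replicates whose Pe is undefined
    (acceptor at equilibrium, or zero transfer) are excluded from the log Pe
    statistics but still counted in ``n_replicates`` and contribute to the
    R and permeation means. ``log Kp`` is the regression applied to the mean
    log Pe. Compound order follows first appearance in the input.
    """
    if not results:
        raise ValueError("no results to aggregate")
    order: list[str] = []
    by_compound: dict[str, list[PermeabilityResult]] = {}
    for r in results:
        if r.compound_id not in by_compound:
            order.append(r.compound_id)
            by_compound[r.compound_id] = []
        by_compound[r.compound_id].append(r)

    out: list[CompoundSummary] = []
    for cid in order:
        reps = by_compound[cid]
        r_mean, r_sd = _mean_sd([r.R for r in reps])
        p_mean, p_sd = _mean_sd([r.perm_param for r in reps])
        log_pes = [r.log_Pe for r in reps if r.log_Pe is not None]
        if log_pes:
            lp_mean, lp_sd = _mean_sd(log_pes)
            lkp = log_kp_from_log_pe(lp_mean, regression)
        else:
            lp_mean = lp_sd = lkp = None
            logger.warning(
                "%s: no replicate with a defined Pe; permeability "
                "fields left undefined", cid)
        out.append(CompoundSummary(
            compound_id=cid,
            n_replicates=len(reps),
            R_mean=r_mean,
            R_sd=r_sd,
            perm_mean=p_mean,
            perm_sd=p_sd,
            logPe_mean=lp_mean,
            logPe_sd=lp_sd,
            logKp_mean=lkp,
            n_pe_defined=len(log_pes),
            below_detection_R=r_mean < BELOW_DETECTION_R,
        ))
    return out
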