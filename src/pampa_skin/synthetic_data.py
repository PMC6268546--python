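"""Synthetic PAMPA plates from known ground truth.

The generator solves the same two-compartment transport picture the analysis
inverts, so noise-free simulated plates round-trip exactly:

* membrane retention is an instantaneous mole-fraction sink applied at the
  lag boundary — after τ_LAG a fraction ``R_true`` of the donor load is
  held by the membrane and plate, leaving ``(1−R_true)·C_D0`` mobile;
* the mobile compound then relaxes first-order between donor and acceptor
  with rate ``k = Pe·A_eff·(1/V_A + 1/V_D)`` towards the shared equilibrium
  ``C_eq = (1−R_true)·C_D0·V_D/(V_A+V_D)`` in the acceptor;
* HPLC readout is emulated as ``area = response_factor·C·(1+ε)`` with ε
  drawn i.i.d. normal (mean 0, SD = noise_cv) per measurement and areas
  truncated at zero — multiplicative noise, as detector area error scales
  with signal.

The module also ships the packaged 26-compound reference measurement table
(20 corticosteroid C-21 esters + 6 standards) used throughout the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .permeability_core import KpRegression, log_kp_from_log_pe
from .plate_model import AssayGeometry, CompoundSummary

__all__ = [
    "SimulationParams",
    "simulate_well_timecourse",
    "simulate_plate",
    "table1_fixture",
    "ESTER_IDS",
    "STANDARD_IDS",
]

#: Default peak-area coefficient of variation for noisy plates. No measured
#: value exists for this detector model; 2% is a typical HPLC-UV area
#: repeatability and is a synthetic assumption, not a measured quantity.
DEFAULT_NOISE_CV = 0.02


@dataclass(frozen=True)
class SimulationParams:
    """Ground truth and noise model for one simulated compound.

    Parameters
    ----------
    Pe_true : float
        True effective permeability (cm/s), ≥ 0.
    R_true : float
        True retention fraction in [0, 1).
    geometry : AssayGeometry
        Sandwich geometry shared by all replicates.
    noise_cv : float
        Coefficient of variation of the multiplicative peak-area noise
        (fraction; 0 disables noise).
    n_replicates : int
        Wells per compound (the reference design uses triplicates).
    seed : int
        Seed of the pseudo-random stream (one stream per plate).
    response_factor : float
        Detector response per unit concentration (arbitrary units).
    """

    Pe_true: float
    R_true: float
    geometry: AssayGeometry = field(default_factory=AssayGeometry)
    noise_cv: float = 0.0
    n_replicates: int = 3
    seed: int = 0
    response_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.Pe_true < 0:
            raise ValueError("Pe_true must be ≥ 0")
        if not 0 <= self.R_true < 1:
            raise ValueError("R_true must lie in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be ≥ 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be ≥ 1")
        if self.response_factor <= 0:
            raise ValueError("response_factor must be > 0")

    @property
    def rate_constant(self) -> float:
        """First-order relaxation rate k = Pe·A_eff·(1/V_A + 1/V_D) (s⁻¹)."""
        g = self.geometry
        return self.Pe_true * g.A_eff * (1.0 / g.V_A + 1.0 / g.V_D)

    @property
    def C_eq(self) -> float:
        """Acceptor equilibrium concentration after retention (mol·cm⁻³)."""
        g = self.geometry
        return (1.0 - self.R_true) * g.C_D0_nominal * g.V_D / (g.V_A + g.V_D)


def simulate_well_timecourse(
    p: SimulationParams, t_query: float
) -> tuple[float, float]:
    """Noise-free (C_Dt, C_At) at time ``t_query`` (s) for one well.

    For ``t_query ≤ τ_LAG`` the acceptor is empty and retention has already
    claimed its share of the donor; afterwards the acceptor relaxes
    exponentially towards ``C_eq``. Donor follows from exact mole balance:
    ``C_Dt·V_D + C_At·V_A + R_true·C_D0·V_D = C_D0·V_D`` at every time.
    """
    if t_query < 0:
        raise ValueError("t_query must be ≥ 0")
    g = p.geometry
    mobile = (1.0 - p.R_true) * g.C_D0_nominal
    if t_query <= g.tau_lag or p.Pe_true == 0:
        return mobile, 0.0
    c_at = p.C_eq * (-math.expm1(-p.rate_constant * (t_query - g.tau_lag)))
    c_dt = mobile - (g.V_A / g.V_D) * c_at
    return c_dt, c_at


def simulate_plate(
    params: Sequence[tuple[str, SimulationParams]],
    path: str | Path | None = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate a plate of peak-area measurements.

    Produces ``n_replicates`` rows per compound with columns ``compound,
    replicate, area_donor_t0, area_donor_t, area_acceptor_t`` — directly
    readable by ``plate_model.read_plate_table(mode="areas")``. One shared
    pseudo-random stream drives the whole plate (seeded from ``seed`` if
    given, else from the first compound's ``SimulationParams.seed``);
    noise draws happen in row-major order (per row: t0, donor-t, acceptor-t)
    so output is fully reproducible.

    Parameters
    ----------
    params : sequence of (compound_id, SimulationParams)
        Compound ids must be unique.
    path : path-like, optional
        If given, also write the table as CSV.
    seed : int, optional
        Overrides the per-params seeds for the plate-level stream.

    Returns
    -------
    pandas.DataFrame
    """
    if not params:
        raise ValueError("no compounds to simulate")
    ids = [cid for cid, _ in params]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids in plate")
    plate_seed = seed if seed is not None else params[0][1].seed
    rng = np.random.default_rng(plate_seed)
    rows = []
    for cid, p in params:
        g = p.geometry
        c_dt, c_at = simulate_well_timecourse(p, g.t_incubation)
        true_concs = (g.C_D0_nominal, c_dt, c_at)
        for rep in range(1, p.n_replicates + 1):
            areas = []
            for c in true_concs:
                eps = rng.normal(0.0, p.noise_cv) if p.noise_cv > 0 else 0.0
                areas.append(max(0.0, p.response_factor * c * (1.0 + eps)))
            rows.append({
                "compound": cid,
                "replicate": rep,
                "area_donor_t0": areas[0],
                "area_donor_t": areas[1],
                "area_acceptor_t": areas[2],
            })
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df


ESTER_IDS = (
    "FA-21-MP", "FA-21-EP", "FA-21-PhP", "FA-21-MB", "FA-21-EB",
    "DEX-21-MP", "DEX-21-EP", "DEX-21-PhP", "DEX-21-MB", "DEX-21-EB",
    "TA-21-MP", "TA-21-EP", "TA-21-PhP", "TA-21-MB", "TA-21-EB",
    "H-21-MP", "H-21-EP", "H-21-PhP", "H-21-MB", "H-21-EB",
)
STANDARD_IDS = ("FA", "DEX", "TA", "H", "H-21-Ac", "MF")


def table1_fixture(
    regression: KpRegression | None = None,
) -> list[CompoundSummary]:
    """The packaged 26-compound reference measurement table as summaries.

    Twenty corticosteroid C-21 ester prodrug candidates plus six standards,
    each with triplicate-mean retention (%), permeation (%) and log Pe and
    their SDs as printed in the source measurement table. Retentions reported
    only as "below 1%" carry ``below_detection_R=True`` and the numeric
    placeholder 0.5% (the midpoint of the reportable band) for computations
    that need a number. ``log Kp`` is computed from the mean log Pe via the
    default regression; ``group`` is left unset.
    """
    with resources.files("pampa_skin.data").joinpath("table1.csv").open("r") as fh:
        df = pd.read_csv(fh)
    out = []
    for _, row in df.iterrows():
        r_sd = row["R_sd_pct"]
        log_pe = float(row["log_pe"])
        out.append(CompoundSummary(
            compound_id=str(row["compound"]),
            n_replicates=3,
            R_mean=float(row["R_pct"]) / 100.0,
            R_sd=None if pd.isna(r_sd) else float(r_sd) / 100.0,
            perm_mean=float(row["perm_pct"]) / 100.0,
            perm_sd=float(row["perm_sd_pct"]) / 100.0,
            logPe_mean=log_pe,
            logPe_sd=float(row["log_pe_sd"]),
            logKp_mean=log_kp_from_log_pe(log_pe, regression),
            n_pe_defined=3,
            below_detection_R=bool(row["below_detection_R"]),
        ))
    return out
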