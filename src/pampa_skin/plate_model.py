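"""Domain types, geometry configuration and tabular I/O for PAMPA plate data.

All internal quantities are SI-like: volumes in cm³, areas in cm², times in
seconds, concentrations in mol·cm⁻³. Percentages appear only at the reporting
boundary (the results CSV stores retention and permeation as percent; every
in-memory object holds fractions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
import yaml

__all__ = [
    "AssayGeometry",
    "WellMeasurement",
    "PermeabilityResult",
    "CompoundSummary",
    "PlateSchemaError",
    "PlateValidationError",
    "default_geometry",
    "load_geometry",
    "read_plate_table",
    "write_results_table",
    "read_results_table",
]

#: Display convention: mean retention below this fraction prints as "<1".
BELOW_DETECTION_R = 0.01


class PlateSchemaError(ValueError):
    """A required column is missing or the table layout is unusable."""


class PlateValidationError(ValueError):
    """A value violates a physical or numerical constraint."""


@dataclass(frozen=True)
class AssayGeometry:
    """Physical constants of one PAMPA sandwich.

    Parameters
    ----------
    V_D, V_A : float
        Donor and acceptor well volumes (cm³).
    A_filter : float
        Filter area (cm²). The transport area is ``A_filter * porosity``.
    porosity : float
        Nominal filter porosity, a fraction in (0, 1].
    t_incubation : float
        Total incubation time (s).
    tau_lag : float
        Steady-state lag time τ_LAG (s): acceptor accumulation is modelled as
        starting only after the transmembrane gradient has stabilised.
    C_D0_nominal : float
        Nominal donor concentration at t = 0 (mol·cm⁻³).
    """

    V_D: float = 0.3
    V_A: float = 0.4
    A_filter: float = 0.28
    porosity: float = 0.7
    t_incubation: float = 25200.0
    tau_lag: float = 1200.0
    C_D0_nominal: float = 1.0e-7

    def __post_init__(self) -> None:
        for name in ("V_D", "V_A", "A_filter", "t_incubation", "tau_lag",
                     "C_D0_nominal"):
            if not getattr(self, name) > 0:
                raise PlateValidationError(f"{name} must be strictly positive")
        if not 0 < self.porosity <= 1:
            raise PlateValidationError("porosity must lie in (0, 1]")
        if not self.tau_lag < self.t_incubation:
            raise PlateValidationError("tau_lag must be smaller than t_incubation")

    @property
    def A_eff(self) -> float:
        """Effective transport area: filter area times nominal porosity (cm²)."""
        return self.A_filter * self.porosity

    @property
    def t_transport(self) -> float:
        """Post-lag transport time t − τ_LAG (s)."""
        return self.t_incubation - self.tau_lag

    def with_overrides(self, **kwargs) -> "AssayGeometry":
        """Return a copy with the given fields replaced (validation re-runs)."""
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        return {
            "V_D": self.V_D, "V_A": self.V_A, "A_filter": self.A_filter,
            "porosity": self.porosity, "t_incubation": self.t_incubation,
            "tau_lag": self.tau_lag, "C_D0_nominal": self.C_D0_nominal,
        }


@dataclass(frozen=True)
class WellMeasurement:
    """One replicate's concentrations: donor at t0, donor at t, acceptor at t."""

    compound_id: str
    replicate_id: str
    C_D0: float
    C_Dt: float
    C_At: float

    def __post_init__(self) -> None:
        if not self.C_D0 > 0:
            raise PlateValidationError(
                f"{self.compound_id}/{self.replicate_id}: C_D0 must be > 0")
        for name in ("C_Dt", "C_At"):
            if getattr(self, name) < 0:
                raise PlateValidationError(
                    f"{self.compound_id}/{self.replicate_id}: {name} must be ≥ 0")


@dataclass
class PermeabilityResult:
    """Per-replicate derived quantities.

    ``Pe`` is ``None`` when the acceptor is at or past its equilibrium
    concentration, where the first-order model cannot identify a rate
    (the log argument hits zero or goes negative).
    """

    compound_id: str
    replicate_id: str
    R: float
    perm_param: float
    Pe: Optional[float]
    log_Pe: Optional[float]
    log_Kp: Optional[float]
    R_clamped: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.R <= 1:
            raise PlateValidationError("R must lie in [0, 1] after clamping")
        if not 0 <= self.perm_param <= 1:
            raise PlateValidationError("perm_param must lie in [0, 1]")
        if (self.log_Kp is None) != (self.log_Pe is None):
            raise PlateValidationError("log_Kp must be present iff log_Pe is")


@dataclass
class CompoundSummary:
    """Triplicate-aggregated results for one compound (one results-table row).

    SD fields are ``None`` when fewer than two replicates contributed; the
    reported spread of replicates is the sample standard deviation (n−1).
    """

    compound_id: str
    n_replicates: int
    R_mean: float
    R_sd: Optional[float]
    perm_mean: float
    perm_sd: Optional[float]
    logPe_mean: Optional[float]
    logPe_sd: Optional[float]
    logKp_mean: Optional[float]
    n_pe_defined: int = 0
    group: Optional[str] = None
    below_detection_R: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 2 and (self.R_sd is not None
                                      or self.perm_sd is not None):
            raise PlateValidationError("sd requires at least two replicates")


# ---------------------------------------------------------------------------
# Geometry configuration


def default_geometry() -> AssayGeometry:
    """The packaged default sandwich geometry (300/400 µL, 0.28 cm² @ 70%,
    7 h incubation, 20 min lag, 100 µM donor)."""
    with resources.files("pampa_skin.data").joinpath(
            "geometry_default.yaml").open("r") as fh:
        return _geometry_from_mapping(yaml.safe_load(fh))


def load_geometry(path: str | Path) -> AssayGeometry:
    """Load an assay geometry from a YAML file.

    Keys missing from the file fall back to the packaged defaults; every key
    present overrides them.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise PlateSchemaError(f"{path}: geometry config must be a mapping")
    base = default_geometry().as_dict()
    unknown = set(data) - set(base)
    if unknown:
        raise PlateSchemaError(f"{path}: unknown geometry keys {sorted(unknown)}")
    base.update(data)
    return _geometry_from_mapping(base)


def _geometry_from_mapping(data: dict) -> AssayGeometry:
    try:
        return AssayGeometry(**{k: float(v) for k, v in data.items()})
    except TypeError as exc:  # unexpected key
        raise PlateSchemaError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Plate table input

_CONC_COLUMNS = ("compound", "replicate", "C_D0", "C_Dt", "C_At")
_AREA_COLUMNS = ("compound", "replicate", "area_donor_t0", "area_donor_t",
                 "area_acceptor_t")


def read_plate_table(
    path: str | Path,
    geometry: AssayGeometry,
    mode: Literal["areas", "concentrations"] = "areas",
) -> list[WellMeasurement]:
    """Read a per-well plate table into measurements.

    ``mode="concentrations"`` expects columns ``compound, replicate, C_D0,
    C_Dt, C_At`` (mol·cm⁻³), passed through verbatim.  ``mode="areas"``
    expects ``compound, replicate, area_donor_t0, area_donor_t,
    area_acceptor_t`` and converts detector responses to concentrations by
    single-point comparison with the time-zero donor peak (the t0 reference
    may therefore differ per replicate).

    Row order is preserved; every input row yields exactly one measurement or
    an error — rows are never silently dropped.
    """
    from . import hplc_quant  # local import avoids a cycle at module load

    if mode not in ("areas", "concentrations"):
        raise ValueError(f"unknown mode {mode!r}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise PlateSchemaError(f"{path}: empty plate table") from exc
    if df.empty:
        raise PlateSchemaError(f"{path}: plate table has no data rows")

    required = _CONC_COLUMNS if mode == "concentrations" else _AREA_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PlateSchemaError(
            f"{path}: missing required column(s) {missing} for mode {mode!r}")

    out: list[WellMeasurement] = []
    for idx, row in df.iterrows():
        try:
            if mode == "concentrations":
                m = WellMeasurement(
                    compound_id=str(row["compound"]),
                    replicate_id=str(row["replicate"]),
                    C_D0=float(row["C_D0"]),
                    C_Dt=float(row["C_Dt"]),
                    C_At=float(row["C_At"]),
                )
            else:
                a0 = float(row["area_donor_t0"])
                m = WellMeasurement(
                    compound_id=str(row["compound"]),
                    replicate_id=str(row["replicate"]),
                    C_D0=hplc_quant.peak_area_to_concentration(
                        a0, a0, geometry.C_D0_nominal),
                    C_Dt=hplc_quant.peak_area_to_concentration(
                        float(row["area_donor_t"]), a0, geometry.C_D0_nominal),
                    C_At=hplc_quant.peak_area_to_concentration(
                        float(row["area_acceptor_t"]), a0,
                        geometry.C_D0_nominal),
                )
        except (PlateValidationError, ValueError) as exc:
            raise PlateValidationError(f"{path} row {idx}: {exc}") from exc
        out.append(m)
    return out


# ---------------------------------------------------------------------------
# Results table output

RESULTS_COLUMNS = [
    "compound", "n", "R_pct_mean", "R_pct_sd", "perm_pct_mean", "perm_pct_sd",
    "logPe_mean", "logPe_sd", "logKp", "group", "R_display", "n_pe_defined",
    "below_detection_R",
]


def _fmt(x: Optional[float]) -> str:
    # repr round-trips float64 exactly; empty cell encodes None
    return "" if x is None else repr(float(x))


def write_results_table(
    summaries: Sequence[CompoundSummary], path: str | Path
) -> None:
    """Write per-compound summaries as CSV (one row per compound).

    Retention and permeation are written as percent. A mean retention below
    1% is rendered ``<1`` in the ``R_display`` column; the numeric
    ``R_pct_mean`` column always retains the value.
    """
    if not summaries:
        raise ValueError("write_results_table: empty summary collection")
    rows = []
    for s in summaries:
        r_pct = s.R_mean * 100.0
        rows.append({
            "compound": s.compound_id,
            "n": s.n_replicates,
            "R_pct_mean": _fmt(r_pct),
            "R_pct_sd": _fmt(None if s.R_sd is None else s.R_sd * 100.0),
            "perm_pct_mean": _fmt(s.perm_mean * 100.0),
            "perm_pct_sd": _fmt(None if s.perm_sd is None else s.perm_sd * 100.0),
            "logPe_mean": _fmt(s.logPe_mean),
            "logPe_sd": _fmt(s.logPe_sd),
            "logKp": _fmt(s.logKp_mean),
            "group": "" if s.group is None else s.group,
            "R_display": "<1" if s.R_mean < BELOW_DETECTION_R else _fmt(r_pct),
            "n_pe_defined": s.n_pe_defined,
            "below_detection_R": s.below_detection_R,
        })
    try:
        pd.DataFrame(rows, columns=RESULTS_COLUMNS).to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write results table to {path}: {exc}") from exc


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def read_results_table(path: str | Path) -> list[CompoundSummary]:
    """Read a CSV written by :func:`write_results_table` back into summaries."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise PlateSchemaError(f"{path}: empty results table") from exc
    missing = [c for c in RESULTS_COLUMNS if c not in df.columns
               and c not in ("R_display", "n_pe_defined", "below_detection_R")]
    if missing:
        raise PlateSchemaError(f"{path}: missing results column(s) {missing}")
    out = []
    for _, row in df.iterrows():
        group = row.get("group")
        if isinstance(group, float) and math.isnan(group):
            group = None
        r_sd = _opt(row["R_pct_sd"])
        p_sd = _opt(row["perm_pct_sd"])
        r_mean = float(row["R_pct_mean"]) / 100.0
        out.append(CompoundSummary(
            compound_id=str(row["compound"]),
            n_replicates=int(row["n"]),
            R_mean=r_mean,
            R_sd=None if r_sd is None else r_sd / 100.0,
            perm_mean=float(row["perm_pct_mean"]) / 100.0,
            perm_sd=None if p_sd is None else p_sd / 100.0,
            logPe_mean=_opt(row["logPe_mean"]),
            logPe_sd=_opt(row["logPe_sd"]),
            logKp_mean=_opt(row["logKp"]),
            n_pe_defined=int(row["n_pe_defined"])
            if "n_pe_defined" in df.columns else 0,
            group=None if group is None else str(group),
            below_detection_R=bool(row["below_detection_R"])
            if "below_detection_R" in df.columns
            else r_mean < BELOW_DETECTION_R,
        ))
    return out
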