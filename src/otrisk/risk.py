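"""Linear cancer-risk extrapolation for o-toluidine.

The dose-response anchor is a benchmark dose for 10% extra bladder-tumour
incidence in female rats, BMD10 = 42.2 mg/kg bw/d.  Two points of
departure (PODs) derive from it:

* occupational: the BMD10 converted to a rat-equivalent 8-h TWA air level
  (840 mg/m3, using 70 kg, 10 m3/working day and an explicit
  continuous-to-working-schedule duration adjustment), then scaled rat to
  human by the default allometric factor 4, giving 210 mg/m3, equivalently
  an intake of 30 mg/kg bw per working day;
* general population: BMD10 / 4 = 10.6 mg/kg bw/d (continuous oral
  feeding in the source study, so no duration adjustment).

Risk is extrapolated linearly through the origin: risk(d) = 0.1 * d / POD.
Helpers regenerate the published occupational and general-population
risk-level tables, including their steady-state urinary equivalents via
the mass-balance model and the tables' printed rounding conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .massbalance import (MassBalanceParams, round_half_up, round_sig_half_up,
                          spot_from_intake)

__all__ = [
    "RiskModel",
    "DEFAULT_DURATION_ADJUSTMENT",
    "occupational_risk",
    "general_population_risk",
    "derive_occupational_pod",
    "risk_table",
    "format_risk_per_million",
]

#: continuous-vs-working schedule (7*52 over 5*48 exposure days) times
#: lifetime-vs-working-years (75/40); reconstructs the published
#: occupational airborne POD from the BMD10 to 3 significant figures.
DEFAULT_DURATION_ADJUSTMENT = (7.0 * 52.0) / (5.0 * 48.0) * (75.0 / 40.0)


@dataclass(frozen=True)
class RiskModel:
    """Points of departure and the linear risk slopes they induce."""

    bmd10_rat: float = 42.2                 # mg/kg bw/d
    allometric_factor: float = 4.0
    pod_general_intake: float = 10.6        # mg/kg bw/d
    pod_occupational_air: float = 210.0     # mg/m3 (8-h TWA)
    pod_occupational_intake: float = 30.0   # mg/kg bw/working day
    risk_at_pod: float = 0.1
    duration_adjustment: float = DEFAULT_DURATION_ADJUSTMENT

    def __post_init__(self) -> None:
        if min(self.bmd10_rat, self.allometric_factor, self.pod_general_intake,
               self.pod_occupational_air, self.pod_occupational_intake,
               self.duration_adjustment) <= 0:
            raise ValidationError("all risk-model parameters must be positive")
        if not 0 < self.risk_at_pod <= 1:
            raise ValidationError("risk_at_pod must lie in (0, 1]")
        scaled = self.bmd10_rat / self.allometric_factor
        if abs(scaled - self.pod_general_intake) > 0.05 * self.pod_general_intake:
            raise ValidationError(
                f"pod_general_intake {self.pod_general_intake} inconsistent with "
                f"bmd10/allometric_factor = {scaled:.3f}")


def occupational_risk(d, m: RiskModel = RiskModel()):
    """Lifetime excess tumour risk for a working-day intake (mg/kg bw/working day)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise DomainError("dose must be non-negative")
    out = m.risk_at_pod * d / m.pod_occupational_intake
    return out if out.ndim else float(out)


def general_population_risk(d, m: RiskModel = RiskModel()):
    """Lifetime excess tumour risk for a continuous daily intake (mg/kg bw/d)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise DomainError("dose must be non-negative")
    out = m.risk_at_pod * d / m.pod_general_intake
    return out if out.ndim else float(out)


def derive_occupational_pod(bmd10: float = 42.2, allometric_factor: float = 4.0,
                            bw: float = 70.0, v_inh: float = 10.0,
                            duration_adjustment: float = DEFAULT_DURATION_ADJUSTMENT):
    """Derive the occupational airborne POD from the rat BMD10.

    Returns ``(rat_equivalent_air, human_pod_air)`` in mg/m3: the daily
    intake is converted to the air level inhaled over a working day,
    adjusted from continuous lifetime dosing to the occupational schedule,
    then scaled across species.
    """
    if min(bmd10, allometric_factor, bw, v_inh, duration_adjustment) <= 0:
        raise DomainError("all arguments must be positive")
    rat_equivalent_air = bmd10 * bw / v_inh * duration_adjustment
    return rat_equivalent_air, rat_equivalent_air / allometric_factor


def format_risk_per_million(risk: float, ndigits: int = 0) -> str:
    """Render a risk fraction as the customary ``N:10^6`` notation."""
    value = round_half_up(risk * 1e6, ndigits)
    if ndigits == 0:
        return f"{value:.0f}:10^6"
    return f"{value:.{ndigits}f}:10^6"


_RISK_LEVELS = [
    ("1:10", 0.1),
    ("1:1000", 1e-3),
    ("1:10,000", 1e-4),
    ("1:100,000", 1e-5),
    ("1:1,000,000", 1e-6),
]


def risk_table(m: RiskModel = RiskModel(),
               mb: MassBalanceParams = MassBalanceParams(),
               population: str = "worker",
               rounded: bool = True) -> pd.DataFrame:
    """Regenerate the published risk-level table for one population.

    Worker: tumour-risk level, air concentration (mg/m3 and ppm),
    working-day intake, steady-state urinary level.  General population:
    risk level, continuous intake, steady-state urinary level.  With
    ``rounded=True`` the table's printed rounding profile is applied
    (half-up at the printed precision; the worker urinary column is printed
    at 1 significant figure); ``rounded=False`` returns exact arithmetic.
    """
    if population not in ("worker", "general"):
        raise DomainError(f"unknown population {population!r}")
    rows = []
    for label, r in _RISK_LEVELS:
        frac = r / m.risk_at_pod
        if population == "worker":
            air = m.pod_occupational_air * frac
            ppm = 48.0 * frac  # printed ppm pairing of the 210 mg/m3 POD
            intake = m.pod_occupational_intake * frac
            urinary = spot_from_intake(intake, mb)
            if rounded:
                air, ppm = round_sig_half_up(air, 2), round_sig_half_up(ppm, 2)
                intake = round_sig_half_up(intake, 1)
                urinary = round_sig_half_up(urinary, 1)
            rows.append({"tumour_risk": label, "air_mg_per_m3": air, "air_ppm": ppm,
                         "intake_mg_per_kg_per_day": intake,
                         "urinary_steady_state_mg_per_L": urinary})
        else:
            intake = m.pod_general_intake * frac
            urinary = spot_from_intake(intake, mb)
            if rounded:
                intake = round_sig_half_up(intake, 3)
                urinary = round_sig_half_up(urinary, 3)
            rows.append({"tumour_risk": label,
                         "intake_mg_per_kg_per_day": intake,
                         "urinary_steady_state_mg_per_L": urinary})
    return pd.DataFrame(rows)
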