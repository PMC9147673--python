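"""Closed-form urinary mass-balance dosimetry for ortho-toluidine.

First-tier reverse dosimetry: urinary biomonitoring levels are assumed to
represent steady state, so external intake and urinary output are related by
a simple daily mass balance,

    Css = D * BW * FUE / V24        D = Css * V24 / (FUE * BW)

where ``D`` is the external dose (mg/kg bw/day), ``Css`` the steady-state
urinary concentration of total (free + conjugated, after hydrolysis)
o-toluidine (mg/L), ``V24`` the 24-h urine volume (L) and ``FUE`` the
fraction of the absorbed dose recovered in urine as the measured analyte
over 24 h.

All functions here work in canonical units (mg, kg, L, m3, day).  Thin
wrappers performing the field's customary unit conversions (ug/L spot
concentrations, ng/24 h excretion amounts) are provided for report tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import DomainError, ValidationError

__all__ = [
    "MassBalanceParams",
    "intake_from_spot",
    "spot_from_intake",
    "intake_from_24h_amount",
    "amount_24h_from_intake",
    "intake_from_air",
    "air_from_intake",
    "intake_ug_per_kg_from_24h_ng",
    "intake_ug_per_kg_from_spot_ug_per_L",
    "round_half_up",
    "round_sig_half_up",
]


@dataclass(frozen=True)
class MassBalanceParams:
    """Reference parameters of the urinary mass-balance model.

    Parameters
    ----------
    fue : float
        Fractional urinary excretion: mass of o-toluidine (including
        hydrolysed conjugates) excreted in urine over 24 h per mass
        absorbed.  Default 0.75, from 24-h urinary recovery in s.c. dosed
        rats.
    v24 : float
        Average 24-h urine volume in litres (default 1.5).
    bw : float
        Body weight in kg (default 70).
    v_inh_workday : float
        Air volume inhaled over an 8-h working day in m3 (default 10).
    """

    fue: float = 0.75
    v24: float = 1.5
    bw: float = 70.0
    v_inh_workday: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 < self.fue <= 1.0:
            raise ValidationError(f"fue must lie in (0, 1], got {self.fue}")
        for name in ("v24", "bw", "v_inh_workday"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive, got {getattr(self, name)}")


def _require_nonneg(value, name: str):
    value = np.asarray(value, dtype=float)
    if np.any(value < 0):
        raise DomainError(f"{name} must be non-negative")
    return value if value.ndim else float(value)


def intake_from_spot(css, p: MassBalanceParams = MassBalanceParams()):
    """External dose (mg/kg bw/d) from a steady-state urinary concentration.

    ``D = Css * V24 / (FUE * BW)`` with ``css`` in mg/L.
    """
    css = _require_nonneg(css, "css")
    return css * p.v24 / (p.fue * p.bw)


def spot_from_intake(d, p: MassBalanceParams = MassBalanceParams()):
    """Steady-state urinary concentration (mg/L) from an external dose.

    ``Css = D * BW * FUE / V24`` with ``d`` in mg/kg bw/d.  Exact inverse of
    :func:`intake_from_spot`.
    """
    d = _require_nonneg(d, "d")
    return d * p.bw * p.fue / p.v24


def intake_from_24h_amount(amount, p: MassBalanceParams = MassBalanceParams()):
    """External dose from a 24-h urinary excretion amount, same mass units per kg.

    The 24-h amount is already a daily excreted mass, so only FUE and body
    weight enter: ``D = amount / (FUE * BW)``.  Passing ng/24 h returns
    ng/kg bw/d.
    """
    amount = _require_nonneg(amount, "amount")
    return amount / (p.fue * p.bw)


def amount_24h_from_intake(d, p: MassBalanceParams = MassBalanceParams()):
    """24-h urinary excretion amount from an external dose (inverse of
    :func:`intake_from_24h_amount`)."""
    d = _require_nonneg(d, "d")
    return d * p.fue * p.bw


def intake_from_air(c_air, p: MassBalanceParams = MassBalanceParams(), absorbed_fraction: float = 1.0):
    """Daily occupational intake (mg/kg bw/working day) from an air level (mg/m3).

    Assumes the default working-day inhaled volume; inhaled and oral
    absorption are treated as equal, so ``absorbed_fraction`` defaults to 1.
    """
    c_air = _require_nonneg(c_air, "c_air")
    if not 0.0 < absorbed_fraction <= 1.0:
        raise DomainError(f"absorbed_fraction must lie in (0, 1], got {absorbed_fraction}")
    return c_air * p.v_inh_workday * absorbed_fraction / p.bw


def air_from_intake(d, p: MassBalanceParams = MassBalanceParams(), absorbed_fraction: float = 1.0):
    """Air concentration (mg/m3) whose working-day intake equals ``d`` (mg/kg bw/d)."""
    d = _require_nonneg(d, "d")
    return d * p.bw / (p.v_inh_workday * absorbed_fraction)


def intake_ug_per_kg_from_spot_ug_per_L(css_ug_per_L, p: MassBalanceParams = MassBalanceParams(),
                                        ndigits: int | None = None):
    """ug/kg bw/d intake from a ug/L spot concentration (report-table wrapper)."""
    d = intake_from_spot(np.asarray(css_ug_per_L, dtype=float) * 1e-3, p) * 1e3
    return round_half_up(d, ndigits) if ndigits is not None else d


def intake_ug_per_kg_from_24h_ng(amount_ng, p: MassBalanceParams = MassBalanceParams(),
                                 ndigits: int | None = 4):
    """ug/kg bw/d intake from an ng/24 h excretion amount, rounded for table use."""
    d = intake_from_24h_amount(amount_ng, p) * 1e-3  # ng/kg -> ug/kg
    return round_half_up(d, ndigits) if ndigits is not None else d


def round_half_up(x, ndigits: int):
    """Round half away from zero at ``ndigits`` decimals (report-table convention)."""
    if np.ndim(x) > 0:
        return np.array([round_half_up(float(v), ndigits) for v in np.asarray(x).ravel()]).reshape(np.shape(x))
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_sig_half_up(x, sig: int):
    """Round half-up to ``sig`` significant figures (used by table renderers)."""
    x = float(x)
    if x == 0:
        return 0.0
    exponent = int(np.floor(np.log10(abs(x))))
    return round_half_up(x, sig - 1 - exponent)
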