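"""Reproduction driver: regenerate the published result tables.

Four tables summarise the assessment: the occupational and
general-population linear risk scales (regenerated exactly, closed form),
and the per-study reverse-dosimetry tables giving external doses and risks
for each biomonitoring study by the urinary mass-balance method (exact,
closed form) and by PBPK/MCMC reconstruction (stochastic, reproduced
within a tolerance band because the original platform's physiology is not
published).  Mass-balance cells are checked against their published values
at printed precision and any mismatch is a hard error; PBPK cells report
their relative deviation from the published values instead.

The published risk column of the general-population reverse-dosimetry
table is not consistent with the linear slope of the published risk scale
(the printed risks are roughly tenfold low); risks here are computed from
the slope and the inconsistency is surfaced as a note rather than
silently matched.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from . import massbalance as mb
from .errors import ReproductionError
from .hbm import StudySummary, builtin_studies
from .massbalance import MassBalanceParams, round_half_up
from .reconstruct import (CachedForwardMap, ExposureReconstruction,
                          ReconstructionConfig)
from .risk import (RiskModel, format_risk_per_million, general_population_risk,
                   occupational_risk, risk_table)

__all__ = ["ReportBundle", "reproduce_tables",
           "WORKER_TABLE_LAYOUT", "GENERAL_TABLE_LAYOUT"]

#: (study_id, statistic, dose decimals, risk decimals) driving each
#: worker-table row, following the published row structure.
WORKER_TABLE_LAYOUT = [
    ("labat", "mean", 2, 0), ("labat", "p95", 2, 0),
    ("korinth", "mean", 2, 0), ("korinth", "p95", 2, 0),
    ("li", "median", 3, 2), ("li", "max", 2, 0),
    ("eitaki", "mean", 1, 0), ("eitaki", "max", 2, 0),
]

#: published mass-balance external doses (ug/kg bw/d) for the worker table
_PUBLISHED_MB_WORKER = {
    ("labat", "mean"): 14.94, ("labat", "p95"): 27.49,
    ("korinth", "mean"): 1.10, ("korinth", "p95"): 8.35,
    ("li", "median"): 0.013, ("li", "max"): 3.09,
    ("eitaki", "mean"): 1.6, ("eitaki", "max"): 3.69,
}

#: published PBPK reconstruction doses (ug/kg bw/d); approximate targets only
_PUBLISHED_PBPK_WORKER = {
    ("labat", "mean"): 9.96, ("labat", "p95"): 18.74,
    ("korinth", "mean"): 0.70, ("korinth", "p95"): 5.57,
    ("li", "median"): 0.012, ("li", "max"): 2.06,
    ("eitaki", "mean"): 1.1, ("eitaki", "max"): 2.5,
}

#: (study_id, statistic, dose decimals) for the general-population table
GENERAL_TABLE_LAYOUT = [
    ("seidel", "median", 4), ("seidel", "max", 3),
    ("riedel_nonsmoker", "mean", 4), ("riedel_nonsmoker", "sd", 3),
    ("riedel_smoker", "mean", 4), ("riedel_smoker", "sd", 3),
    ("lindner_nonsmoker", "mean", 4), ("lindner_nonsmoker", "sd", 4),
    ("lindner_smoker", "mean", 4), ("lindner_smoker", "sd", 4),
]

_PUBLISHED_MB_GENERAL = {
    ("seidel", "median"): 0.0012, ("seidel", "max"): 0.008,
    ("riedel_nonsmoker", "mean"): 0.0032, ("riedel_nonsmoker", "sd"): 0.004,
    ("riedel_smoker", "mean"): 0.0039, ("riedel_smoker", "sd"): 0.001,
    ("lindner_nonsmoker", "mean"): 0.0012, ("lindner_nonsmoker", "sd"): 0.0024,
    ("lindner_smoker", "mean"): 0.0034, ("lindner_smoker", "sd"): 0.0095,
}


@dataclass
class ReportBundle:
    """All regenerated tables plus provenance of the run."""

    table2: pd.DataFrame
    table3: pd.DataFrame
    table5: pd.DataFrame
    table6: pd.DataFrame
    comparison: pd.DataFrame
    notes: list[str]
    provenance: dict

    def mean_relative_difference_pct(self) -> float:
        """Mean (mass-balance - PBPK)/PBPK x 100 over the worker studies."""
        return float(self.comparison["relative_difference_pct"].mean())


def _study_map() -> dict[str, StudySummary]:
    return {s.study_id: s for s in builtin_studies()}


def _mass_balance_dose_ug_per_kg(study: StudySummary, statistic: str,
                                 params: MassBalanceParams) -> float:
    value = study.stat(statistic)
    if study.unit == "ug_per_L":
        return float(mb.intake_from_spot(value * 1e-3, params)) * 1e3
    return float(mb.intake_from_24h_amount(value, params)) * 1e-3


def reproduce_tables(seed: int = 0, skip_pbpk: bool = False,
                     n_iterations: int = 4000, burn_in: int = 1000,
                     n_chains: int = 2,
                     mb_params: MassBalanceParams | None = None,
                     risk_model: RiskModel | None = None,
                     pbpk_tolerance: float = 0.35) -> ReportBundle:
    """Regenerate the result tables; exact cells are verified, PBPK cells
    are recomputed by seeded MCMC reconstruction.

    Raises :class:`ReproductionError` if any closed-form cell deviates
    from its published value at printed precision.
    """
    mb_params = mb_params or MassBalanceParams()
    risk_model = risk_model or RiskModel()
    studies = _study_map()
    notes: list[str] = []
    failures: list[str] = []

    table2 = risk_table(risk_model, mb_params, "worker")
    table3 = risk_table(risk_model, mb_params, "general")
    for label, intake, urinary in (("1:10", 30, 1000), ("1:10,000", 0.03, 1)):
        row = table2[table2.tumour_risk == label].iloc[0]
        if row.intake_mg_per_kg_per_day != intake or \
                row.urinary_steady_state_mg_per_L != urinary:
            failures.append(f"occupational risk table {label}: expected "
                            f"({intake}, {urinary}), got ({row.intake_mg_per_kg_per_day}, "
                            f"{row.urinary_steady_state_mg_per_L})")
    for label, intake, urinary in (("1:10", 10.6, 371), ("1:10,000", 0.0106, 0.371)):
        row = table3[table3.tumour_risk == label].iloc[0]
        if row.intake_mg_per_kg_per_day != intake or \
                row.urinary_steady_state_mg_per_L != urinary:
            failures.append(f"general risk table {label}: expected "
                            f"({intake}, {urinary}), got ({row.intake_mg_per_kg_per_day}, "
                            f"{row.urinary_steady_state_mg_per_L})")

    # ---- worker reverse-dosimetry table --------------------------------------
    config = ReconstructionConfig(seed=seed, n_iterations=n_iterations,
                                  burn_in=burn_in, n_chains=n_chains)
    worker_map: CachedForwardMap | None = None
    rows5 = []
    comparison_rows = []
    central = {"labat": "mean", "korinth": "mean", "li": "median", "eitaki": "mean"}
    posteriors: dict[tuple[str, str], float] = {}
    if not skip_pbpk:
        seeds = np.random.SeedSequence(seed).generate_state(len(WORKER_TABLE_LAYOUT))
        for k, (sid, stat, _, _) in enumerate(WORKER_TABLE_LAYOUT):
            model = ExposureReconstruction.from_study(
                studies[sid], stat,
                config=ReconstructionConfig(seed=int(seeds[k] % (2 ** 31)),
                                            n_iterations=n_iterations,
                                            burn_in=burn_in, n_chains=n_chains),
                forward_map=worker_map)
            if worker_map is None:
                worker_map = model.forward_map()
            posteriors[(sid, stat)] = model.fit().median * 1e3  # ug/kg bw/d

    for sid, stat, dose_dec, risk_dec in WORKER_TABLE_LAYOUT:
        study = studies[sid]
        dose = _mass_balance_dose_ug_per_kg(study, stat, mb_params)
        dose_rounded = round_half_up(dose, dose_dec)
        expected = _PUBLISHED_MB_WORKER[(sid, stat)]
        if dose_rounded != expected:
            failures.append(f"worker table mass-balance dose {sid}/{stat}: "
                            f"expected {expected}, got {dose_rounded}")
        risk = occupational_risk(dose * 1e-3, risk_model)
        row = {
            "study_id": sid, "statistic": stat,
            "urinary_value_ug_per_L": study.stat(stat),
            "mass_balance_dose_ug_per_kg": dose_rounded,
            "mass_balance_risk": format_risk_per_million(risk, risk_dec),
        }
        if not skip_pbpk:
            pbpk_dose = posteriors[(sid, stat)]
            published = _PUBLISHED_PBPK_WORKER[(sid, stat)]
            deviation = pbpk_dose / published - 1.0
            row.update({
                "pbpk_dose_ug_per_kg": round_half_up(pbpk_dose, dose_dec),
                "pbpk_risk": format_risk_per_million(
                    occupational_risk(pbpk_dose * 1e-3, risk_model), risk_dec),
                "pbpk_published_dose_ug_per_kg": published,
                "pbpk_relative_deviation": round(deviation, 3),
            })
            if abs(deviation) > pbpk_tolerance:
                notes.append(f"PBPK dose for {sid}/{stat} deviates "
                             f"{deviation:+.0%} from the published value "
                             f"(tolerance {pbpk_tolerance:.0%}); approximate "
                             f"reproduction only")
            if stat == central[sid]:
                comparison_rows.append({
                    "study_id": sid, "statistic": stat,
                    "mass_balance_dose_ug_per_kg": dose,
                    "pbpk_dose_ug_per_kg": pbpk_dose,
                    "relative_difference_pct": (dose - pbpk_dose) / pbpk_dose * 100.0,
                })
        rows5.append(row)
    table5 = pd.DataFrame(rows5)

    # ---- general-population reverse-dosimetry table --------------------------
    rows6 = []
    for sid, stat, dose_dec in GENERAL_TABLE_LAYOUT:
        study = studies[sid]
        dose = _mass_balance_dose_ug_per_kg(study, stat, mb_params)
        dose_rounded = round_half_up(dose, dose_dec)
        expected = _PUBLISHED_MB_GENERAL[(sid, stat)]
        if dose_rounded != expected:
            failures.append(f"general table mass-balance dose {sid}/{stat}: "
                            f"expected {expected}, got {dose_rounded}")
        rows6.append({
            "study_id": sid, "statistic": stat,
            "urinary_value_ng_per_24h": study.stat(stat),
            "mass_balance_dose_ug_per_kg": dose_rounded,
            "mass_balance_risk": format_risk_per_million(
                general_population_risk(dose * 1e-3, risk_model), 4),
        })
    table6 = pd.DataFrame(rows6)
    notes.append(
        "general-population risks are computed from the linear risk-scale "
        "slope; the originally published risk column is about tenfold lower "
        "than that slope applied to its own dose column and is not matched")

    if failures:
        raise ReproductionError("exact reproduction failed:\n  " + "\n  ".join(failures))

    comparison = pd.DataFrame(comparison_rows) if comparison_rows else pd.DataFrame(
        columns=["study_id", "statistic", "mass_balance_dose_ug_per_kg",
                 "pbpk_dose_ug_per_kg", "relative_difference_pct"])
    config_payload = {
        "seed": seed, "skip_pbpk": skip_pbpk, "n_iterations": n_iterations,
        "burn_in": burn_in, "n_chains": n_chains, "pbpk_tolerance": pbpk_tolerance,
    }
    provenance = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(config_payload, sort_keys=True).encode()).hexdigest()[:16],
    }
    return ReportBundle(table2=table2, table3=table3, table5=table5, table6=table6,
                        comparison=comparison, notes=notes, provenance=provenance)
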