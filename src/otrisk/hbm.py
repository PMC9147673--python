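"""Registry of human-biomonitoring (HBM) study summaries for urinary o-toluidine.

Published biomonitoring of urinary o-toluidine reports only summary
statistics (mean, SD, median, P95, max) per study, never individual
measurements.  This module provides the typed container for one study
summary, a CSV reader/writer, and the built-in registry of the seven
published studies used by the risk-assessment pipeline: four occupational
cohorts with post-shift spot samples (ug/L) and three general-population
surveys with 24-h collections (ng/24 h).  Smoker and non-smoker strata of
the general-population surveys are stored as separate records sharing a
``study_id`` prefix, because the downstream tables treat strata as
independent rows.

"<LOD" lower range bounds are recorded via the ``lod_censored`` flag with
the minimum left absent; no substitution is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "StudySummary",
    "STAT_NAMES",
    "load_studies",
    "write_studies",
    "builtin_studies",
    "get_study",
]

STAT_NAMES = ("mean", "sd", "median", "p95", "max", "min")

_POPULATIONS = ("worker", "general")
_SAMPLE_TYPES = ("post_shift_spot", "urine_24h")
_SMOKER_STATUS = ("non_smoker", "smoker", "mixed", "unspecified")

#: the unit implied by each sample type (post-shift spot samples are reported
#: as concentrations, 24-h collections as excreted amounts)
UNIT_FOR_SAMPLE_TYPE = {"post_shift_spot": "ug_per_L", "urine_24h": "ng_per_24h"}


@dataclass(frozen=True)
class StudySummary:
    """Summary statistics of urinary o-toluidine from one biomonitoring study
    (or one smoking stratum of a study)."""

    study_id: str
    population: str
    country: str
    sample_type: str
    n: int
    stats: dict[str, float] = field(default_factory=dict)
    unit: str = ""
    smoker_status: str = "unspecified"
    lod_censored: bool = False

    def __post_init__(self) -> None:
        if self.population not in _POPULATIONS:
            raise ValidationError(f"{self.study_id}: unknown population {self.population!r}")
        if self.sample_type not in _SAMPLE_TYPES:
            raise ValidationError(f"{self.study_id}: unknown sample_type {self.sample_type!r}")
        if self.smoker_status not in _SMOKER_STATUS:
            raise ValidationError(f"{self.study_id}: unknown smoker_status {self.smoker_status!r}")
        if not isinstance(self.n, int) or self.n < 1:
            raise ValidationError(f"{self.study_id}: n must be a positive integer, got {self.n!r}")
        expected_unit = UNIT_FOR_SAMPLE_TYPE[self.sample_type]
        if self.unit != expected_unit:
            raise ValidationError(
                f"{self.study_id}: sample_type {self.sample_type!r} requires unit "
                f"{expected_unit!r}, got {self.unit!r}"
            )
        for name, value in self.stats.items():
            if name not in STAT_NAMES:
                raise ValidationError(f"{self.study_id}: unknown statistic {name!r}")
            if not math.isfinite(value) or value < 0:
                raise ValidationError(f"{self.study_id}: statistic {name}={value!r} must be >= 0")
        med = self.stats.get("median")
        if med is not None:
            for upper in ("p95", "max"):
                if upper in self.stats and self.stats[upper] < med:
                    raise ValidationError(
                        f"{self.study_id}: {upper}={self.stats[upper]} < median={med}"
                    )

    def stat(self, name: str) -> float:
        """Return a statistic, raising a KeyError naming the study if absent."""
        try:
            return self.stats[name]
        except KeyError:
            raise KeyError(f"study {self.study_id!r} does not report {name!r}") from None

    @property
    def study_key(self) -> str:
        """Study identifier with any stratum suffix removed."""
        return self.study_id.split("_")[0]

    def with_stats(self, **stats: float) -> "StudySummary":
        return replace(self, stats={**self.stats, **stats})


_MANDATORY_COLUMNS = ("study_id", "population", "country", "sample_type", "n", "unit")


def load_studies(path) -> list[StudySummary]:
    """Read study summaries from a CSV file (comma-separated, UTF-8, one header row).

    Unparseable or empty statistic cells are recorded as absent, never as
    zero.  Raises :class:`FormatError` for a missing mandatory column and
    :class:`ValidationError` (naming row and field) for invalid values.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _MANDATORY_COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    studies = []
    for idx, row in frame.iterrows():
        stats: dict[str, float] = {}
        for name in STAT_NAMES:
            raw = row.get(name, "")
            if raw is None or str(raw).strip() == "":
                continue
            try:
                value = float(raw)
            except ValueError:
                continue  # unparseable -> absent
            if value < 0:
                raise ValidationError(f"row {idx} ({row['study_id']}): {name} is negative")
            stats[name] = value
        try:
            n = int(float(row["n"]))
        except ValueError:
            raise FormatError(f"row {idx}: n={row['n']!r} is not an integer") from None
        studies.append(
            StudySummary(
                study_id=row["study_id"].strip(),
                population=row["population"].strip(),
                country=row["country"].strip(),
                sample_type=row["sample_type"].strip(),
                n=n,
                stats=stats,
                unit=row["unit"].strip(),
                smoker_status=(row.get("smoker_status", "") or "unspecified").strip(),
                lod_censored=str(row.get("lod_censored", "")).strip().lower()
                in ("true", "1", "yes"),
            )
        )
    return studies


def write_studies(studies: list[StudySummary], path) -> None:
    """Write studies to CSV so that :func:`load_studies` round-trips bit-exactly.

    Floats are written with ``repr``, which Python parses back to the
    identical double.
    """
    rows = []
    for s in studies:
        row = {
            "study_id": s.study_id,
            "population": s.population,
            "country": s.country,
            "sample_type": s.sample_type,
            "n": s.n,
            "smoker_status": s.smoker_status,
        }
        for name in STAT_NAMES:
            row[name] = repr(s.stats[name]) if name in s.stats else ""
        row["unit"] = s.unit
        row["lod_censored"] = s.lod_censored
        rows.append(row)
    columns = ["study_id", "population", "country", "sample_type", "n", "smoker_status",
               *STAT_NAMES, "unit", "lod_censored"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def _fixture_path() -> Path:
    return Path(str(resources.files("otrisk").joinpath("data", "table4_studies.csv")))


def builtin_studies() -> list[StudySummary]:
    """The packaged registry: 9 records spanning 7 published studies.

    Four occupational studies (post-shift spot, ug/L) and three
    general-population studies (24-h urine, ng/24 h), the latter split into
    smoking strata where the source reports them separately.
    """
    return load_studies(_fixture_path())


def get_study(study_id: str) -> StudySummary:
    """Look up a built-in study record by its ``study_id``."""
    for s in builtin_studies():
        if s.study_id == study_id:
            return s
    raise KeyError(f"no built-in study {study_id!r}")
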