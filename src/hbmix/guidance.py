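"""Human-biomonitoring health-based guidance values (HBM-HBGVs).

A guidance value is a urinary biomarker concentration below which no
health risk is expected.  The packaged database transcribes the values
used in the proof-of-concept toxicity weighting: HBM-GV values for the
general population, German HBM-I values, occupational biological
monitoring guidance values (BMGV) and biomonitoring equivalents (BE).
Sources are ranked by review rigour: HBM4EU-derived values first, then
European regulatory agencies, then other national agencies, and
finally biomonitoring equivalents (tier 1-4).

Matching rules implemented here:

* a query biomarker matches every entry whose component set contains
  it (sum-of-metabolite entries list several biomarkers);
* entries with an age band only match when the query age falls inside;
* general-population entries are preferred; occupational values are
  used only as a fallback and flagged as such;
* among remaining candidates, the best (lowest) source tier wins, then
  the lowest value.
"""

from __future__ import annotations

import dataclasses
import warnings
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "GuidanceValue",
    "MatchedGuidance",
    "load_database",
    "load_study_biomarkers",
    "load_molecular_weights",
    "match_guidance",
    "convert_units",
    "CREATININE_MW",
]

#: molar mass of creatinine, g/mol
CREATININE_MW = 113.12

UNITS = ("ug/L", "ug/g creatinine", "umol/mol creatinine")
VALUE_TYPES = ("HBM-GV", "HBM-I", "HBM-II", "BE", "BMGV")
POPULATIONS = ("general", "occupational")


@dataclasses.dataclass(frozen=True)
class GuidanceValue:
    """One guidance entry; ``biomarkers`` with more than one component
    denotes a sum-of-metabolites value."""

    substance: str
    label: str
    biomarkers: tuple[str, ...]
    value: float
    units: str
    age_min: float | None = None
    age_max: float | None = None
    population: str = "general"
    value_type: str = "HBM-GV"
    source_tier: int = 4

    @property
    def creatinine_standardized(self) -> bool:
        return "creatinine" in self.units

    @property
    def is_sum(self) -> bool:
        return len(self.biomarkers) > 1

    def matches_age(self, age: float | None) -> bool:
        if self.age_min is None and self.age_max is None:
            return True
        if age is None:
            return False
        lo = -float("inf") if self.age_min is None else self.age_min
        hi = float("inf") if self.age_max is None else self.age_max
        return lo <= age <= hi


@dataclasses.dataclass(frozen=True)
class MatchedGuidance:
    guidance: GuidanceValue
    occupational_fallback: bool


def _parse_row(row: pd.Series, rownum: int) -> GuidanceValue:
    try:
        value = float(row["value"])
    except (TypeError, ValueError):
        raise ValueError(f"row {rownum}: value {row['value']!r} is not numeric") from None
    if not value > 0:
        raise ValueError(f"row {rownum}: guidance value must be positive, got {value}")
    units = str(row["units"]).strip()
    if units not in UNITS:
        raise ValueError(f"row {rownum}: unknown units {units!r} (allowed: {UNITS})")
    population = str(row["population"]).strip()
    if population not in POPULATIONS:
        raise ValueError(f"row {rownum}: unknown population {population!r}")
    value_type = str(row["value_type"]).strip()
    if value_type not in VALUE_TYPES:
        raise ValueError(f"row {rownum}: unknown value type {value_type!r}")
    biomarkers = tuple(b.strip() for b in str(row["biomarkers"]).split(";") if b.strip())
    if not biomarkers:
        raise ValueError(f"row {rownum}: no component biomarkers listed")
    tier = int(row["source_tier"])
    if tier not in (1, 2, 3, 4):
        raise ValueError(f"row {rownum}: source tier must be 1-4, got {tier}")

    def _age(x):
        return None if pd.isna(x) else float(x)

    return GuidanceValue(
        substance=str(row["substance"]).strip(),
        label=str(row["label"]).strip(),
        biomarkers=biomarkers,
        value=value,
        units=units,
        age_min=_age(row.get("age_min")),
        age_max=_age(row.get("age_max")),
        population=population,
        value_type=value_type,
        source_tier=tier,
    )


def _packaged(name: str):
    return resources.files("hbmix") / "data" / name


def load_database(path: str | Path | None = None) -> list[GuidanceValue]:
    """Load and validate a guidance-value database (packaged default).

    Malformed rows (non-positive values, unknown units, ...) raise a
    ``ValueError`` naming the row; an empty file yields an empty
    database with a warning.
    """
    src = _packaged("guidance_values.csv") if path is None else Path(path)
    with (src.open("r") if hasattr(src, "open") else open(src)) as fh:
        df = pd.read_csv(fh)
    if df.empty:
        warnings.warn("guidance-value database is empty", stacklevel=2)
        return []
    return [_parse_row(row, i) for i, row in df.iterrows()]


def load_study_biomarkers(path: str | Path | None = None) -> pd.DataFrame:
    """The 51-biomarker study panel (biomarker, parent substance, family)."""
    src = _packaged("study_biomarkers.csv") if path is None else Path(path)
    with (src.open("r") if hasattr(src, "open") else open(src)) as fh:
        return pd.read_csv(fh).set_index("biomarker")


def load_molecular_weights(path: str | Path | None = None) -> dict[str, float]:
    src = _packaged("molecular_weights.csv") if path is None else Path(path)
    with (src.open("r") if hasattr(src, "open") else open(src)) as fh:
        df = pd.read_csv(fh)
    return dict(zip(df["biomarker"], df["mw_g_mol"].astype(float)))


def match_guidance(
    biomarkers: str | list[str] | tuple[str, ...],
    age: float | None = None,
    db: list[GuidanceValue] | None = None,
    population: str = "general",
) -> MatchedGuidance | None:
    """Select the guidance value for a biomarker (or sum set).

    A single-biomarker query matches entries containing that biomarker
    in their component set; a multi-biomarker query matches entries
    with exactly that component set.  Among age-compatible candidates,
    general-population entries are preferred (occupational ones only
    as a flagged fallback), then the best source tier, then the lowest
    value.  Returns None when nothing matches — a valid outcome, since
    guidance values exist for only a minority of biomarkers.
    """
    if db is None:
        db = load_database()
    if isinstance(biomarkers, str):
        query = (biomarkers,)
        single = True
    else:
        query = tuple(biomarkers)
        single = len(query) == 1

    def component_match(gv: GuidanceValue) -> bool:
        if single:
            return query[0] in gv.biomarkers
        return set(query) == set(gv.biomarkers)

    candidates = [gv for gv in db if component_match(gv) and gv.matches_age(age)]
    if not candidates:
        return None
    preferred = [gv for gv in candidates if gv.population == population]
    fallback = not preferred
    pool = preferred if preferred else candidates
    pool = sorted(pool, key=lambda gv: (gv.source_tier, gv.value, gv.label))
    chosen = pool[0]
    return MatchedGuidance(
        guidance=chosen,
        occupational_fallback=fallback and chosen.population == "occupational",
    )


def convert_units(
    value,
    from_units: str,
    to_units: str,
    creatinine: float | None = None,
    mw: float | None = None,
    biomarker: str = "",
):
    """Convert a urinary concentration between the supported units.

    ``ug/L -> ug/g creatinine`` divides by urinary creatinine (g/L);
    ``ug/g creatinine -> umol/mol creatinine`` multiplies by
    ``CREATININE_MW / mw`` (moles of analyte per mole of creatinine).
    All conversions are invertible; missing creatinine or molecular
    weight raises with the biomarker name.  ``value`` may be a scalar
    or array; ``creatinine`` may be per-sample.
    """
    for u in (from_units, to_units):
        if u not in UNITS:
            raise ValueError(f"unknown units {u!r}")
    if from_units == to_units:
        return value

    needs_creat = ("ug/L" in (from_units, to_units))
    if needs_creat and creatinine is None:
        raise ValueError(
            f"creatinine (g/L) required to convert {biomarker or 'concentration'} "
            f"between {from_units} and {to_units}"
        )
    needs_mw = "umol/mol creatinine" in (from_units, to_units)
    if needs_mw and mw is None:
        raise ValueError(
            f"molecular weight required for molar conversion of "
            f"{biomarker or 'this biomarker'}"
        )

    # route through ug/g creatinine
    if from_units == "ug/L":
        value = value / creatinine
    elif from_units == "umol/mol creatinine":
        value = value * (mw / CREATININE_MW)
    # value now in ug/g creatinine
    if to_units == "ug/L":
        value = value * creatinine
    elif to_units == "umol/mol creatinine":
        value = value * (CREATININE_MW / mw)
    return value
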