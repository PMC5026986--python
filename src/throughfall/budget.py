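"""Inorganic-nitrogen bookkeeping across incubation weeks and filter treatments.

Summarizes each (source, treatment) time series into endpoint deltas of
ammonium, nitrite and nitrate, the oxidized-N produced, the production in
excess of ammonium consumption (the signature of organic-N mineralization
feeding nitrification), and a three-way classification:

* ``nitrifying`` — nitrate accumulates (full two-step chain active);
* ``nitrite_accumulating`` — nitrite builds up without nitrate production,
  the pattern expected when filtration removes nitrite oxidizers but not
  ammonia oxidizers;
* ``inactive`` — no meaningful transformation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import MissingDataError, ValidationError

TREATMENTS = ("unfiltered", "f10um", "f2um", "f0_4um", "f0_2um")
WEEKS = (0, 1, 2, 3, 4)
N_SPECIES = ("nh4_uM", "no2_uM", "no3_uM")

CHEMISTRY_CSV_COLUMNS = ["sample_id", "source", "treatment", "week"] + list(N_SPECIES)

CLASS_NITRIFYING = "nitrifying"
CLASS_NITRITE_ACCUMULATING = "nitrite_accumulating"
CLASS_INACTIVE = "inactive"


@dataclass(frozen=True)
class ClassificationThresholds:
    """Cutoffs separating the qualitative incubation outcomes.

    ``nitrifying`` requires a nitrate increase of at least
    ``min_dno3_abs_uM`` that is also at least ``min_dno3_frac`` of the
    initial nitrate pool; ``nitrite_accumulating`` requires a nitrite
    increase of at least ``min_dno2_abs_uM`` without the nitrate criterion
    being met.
    """

    min_dno3_abs_uM: float = 20.0
    min_dno3_frac: float = 0.10
    min_dno2_abs_uM: float = 5.0


@dataclass
class NSpeciesProfile:
    """Inorganic-N concentrations (micromolar) for one sample; ``None``
    marks a not-determined value, which is preserved and never imputed."""

    sample_id: str
    source: str
    treatment: str
    week: int
    nh4_uM: float | None = None
    no2_uM: float | None = None
    no3_uM: float | None = None

    def __post_init__(self) -> None:
        if not self.source:
            raise ValueError("source label must be non-empty")
        if self.treatment not in TREATMENTS:
            raise ValueError(
                f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}"
            )
        if self.week not in WEEKS:
            raise ValueError(f"week must be one of {WEEKS}, got {self.week}")
        for name in N_SPECIES:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")


def mineral_nitrogen(profile: NSpeciesProfile) -> float:
    """Sum of ammonium, nitrite and nitrate (micromolar); nitrite counts."""
    values = [getattr(profile, n) for n in N_SPECIES]
    if any(v is None for v in values):
        missing = [n for n, v in zip(N_SPECIES, values) if v is None]
        raise MissingDataError(
            f"mineral N undefined for {profile.sample_id}: {missing} not determined"
        )
    return float(sum(values))


def load_profiles(table: str | Path | pd.DataFrame) -> list[NSpeciesProfile]:
    """Load and validate a tidy chemistry table.

    Not-determined cells (empty in the CSV) are kept as ``None``.  All row
    errors are collected and reported together.
    """
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    missing_cols = [c for c in CHEMISTRY_CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"chemistry table lacks required columns: {missing_cols}")
    profiles: list[NSpeciesProfile] = []
    problems: list[str] = []
    seen: dict[tuple, int] = {}
    for i, row in df.iterrows():
        key = (row["source"], row["treatment"], row["week"])
        if key in seen:
            problems.append(f"row {i}: duplicate (source, treatment, week) {key} "
                            f"(first seen at row {seen[key]})")
            continue
        seen[key] = i
        kwargs = {}
        for name in N_SPECIES:
            v = row[name]
            kwargs[name] = None if pd.isna(v) else float(v)
        try:
            profiles.append(
                NSpeciesProfile(
                    sample_id=str(row["sample_id"]),
                    source=str(row["source"]),
                    treatment=str(row["treatment"]),
                    week=int(row["week"]),
                    **kwargs,
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise ValidationError("invalid chemistry rows", problems)
    return profiles


@dataclass(frozen=True)
class BudgetSummary:
    """Endpoint N budget for one (source, treatment) incubation series.

    Deltas are final minus initial (micromolar); ``delta_nh4`` uses the
    latest week at which ammonium was determined, which can differ from the
    nitrate/nitrite endpoint week.  ``excess_over_nh4_consumption`` is
    ``oxidized_N_produced - max(0, -delta_nh4)`` and is only computed when
    both endpoint ammonium values exist.
    """

    source: str
    treatment: str
    week_initial: int
    week_final: int
    delta_nh4: float | None
    delta_no2: float | None
    delta_no3: float | None
    oxidized_n_produced: float | None
    excess_over_nh4_consumption: float | None
    classification: str


def _endpoint_delta(
    by_week: dict[int, NSpeciesProfile], species: str
) -> tuple[float | None, int | None]:
    """(final - initial, final week) for one species, or (None, None)."""
    weeks = sorted(w for w, p in by_week.items() if getattr(p, species) is not None)
    if not weeks or weeks[0] != 0 or len(weeks) < 2:
        return None, None
    w_final = weeks[-1]
    return (
        getattr(by_week[w_final], species) - getattr(by_week[0], species),
        w_final,
    )


def summarize_budget(
    profiles: Sequence[NSpeciesProfile] | Iterable[NSpeciesProfile],
    thresholds: ClassificationThresholds | None = None,
) -> BudgetSummary:
    """Summarize one (source, treatment) series into a :class:`BudgetSummary`.

    Requires a week-0 profile and at least one later week.  A missing
    ammonium determination at intermediate weeks never blocks the nitrate
    and nitrite deltas.
    """
    thresholds = thresholds or ClassificationThresholds()
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("no profiles supplied")
    keys = {(p.source, p.treatment) for p in profiles}
    if len(keys) != 1:
        raise ValidationError(f"profiles span multiple (source, treatment) groups: {keys}")
    source, treatment = keys.pop()
    by_week = {p.week: p for p in profiles}
    if 0 not in by_week:
        raise ValidationError(f"{source}/{treatment}: no week-0 (pre-incubation) profile")
    later = [w for w in by_week if w > 0]
    if not later:
        raise ValidationError(f"{source}/{treatment}: no post-incubation data")
    week_final = max(later)

    d_nh4, _ = _endpoint_delta(by_week, "nh4_uM")
    d_no2, _ = _endpoint_delta(by_week, "no2_uM")
    d_no3, _ = _endpoint_delta(by_week, "no3_uM")

    oxidized = d_no3 + d_no2 if d_no3 is not None and d_no2 is not None else None
    excess = (
        oxidized - max(0.0, -d_nh4)
        if oxidized is not None and d_nh4 is not None
        else None
    )

    no3_initial = by_week[0].no3_uM
    classification = CLASS_INACTIVE
    if d_no3 is not None:
        frac_ok = (
            no3_initial is None
            or no3_initial <= 0
            or d_no3 >= thresholds.min_dno3_frac * no3_initial
        )
        if d_no3 >= thresholds.min_dno3_abs_uM and frac_ok:
            classification = CLASS_NITRIFYING
    if classification != CLASS_NITRIFYING:
        if d_no2 is not None and d_no2 >= thresholds.min_dno2_abs_uM:
            classification = CLASS_NITRITE_ACCUMULATING

    return BudgetSummary(
        source=source,
        treatment=treatment,
        week_initial=0,
        week_final=week_final,
        delta_nh4=d_nh4,
        delta_no2=d_no2,
        delta_no3=d_no3,
        oxidized_n_produced=oxidized,
        excess_over_nh4_consumption=excess,
        classification=classification,
    )


def summarize_all(
    profiles: Iterable[NSpeciesProfile],
    thresholds: ClassificationThresholds | None = None,
) -> pd.DataFrame:
    """Budget summaries for every (source, treatment) group, as a tidy frame.

    Groups lacking post-incubation data are reported with classification
    ``not_evaluable`` rather than raised, so one bad group does not abort a
    whole run.
    """
    groups: dict[tuple[str, str], list[NSpeciesProfile]] = {}
    for p in profiles:
        groups.setdefault((p.source, p.treatment), []).append(p)
    rows = []
    for (source, treatment), group in sorted(groups.items()):
        try:
            s = summarize_budget(group, thresholds)
            rows.append(vars(s) if not hasattr(s, "__dataclass_fields__") else {
                k: getattr(s, k) for k in s.__dataclass_fields__
            })
        except ValidationError:
            rows.append(
                {
                    "source": source,
                    "treatment": treatment,
                    "week_initial": 0,
                    "week_final": math.nan,
                    "delta_nh4": math.nan,
                    "delta_no2": math.nan,
                    "delta_no3": math.nan,
                    "oxidized_n_produced": math.nan,
                    "excess_over_nh4_consumption": math.nan,
                    "classification": "not_evaluable",
                }
            )
    return pd.DataFrame(rows)
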