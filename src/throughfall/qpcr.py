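"""qPCR copy-number normalization with limit-of-quantification censoring,
and assembly of gene presence/absence matrices across filter fractions.

Copy counts measured per reaction are scaled to per-filter totals (given
the fraction of the DNA extract loaded per reaction) and then to copies per
mL of filtered water.  Counts below the limit of quantification (LOQ) are
censored: such records carry only an upper bound, never a point value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError

TARGET_ARCHAEAL = "archaeal_amoA"
TARGET_BETAPROTEOBACTERIAL = "betaproteobacterial_amoA"
TARGETS = (TARGET_ARCHAEAL, TARGET_BETAPROTEOBACTERIAL)

#: Smallest quantifiable archaeal amoA copy number per reaction; the
#: boundary is inclusive (a mean exactly at the LOQ is quantifiable).
DEFAULT_LOQ_COPIES = 44.0

OUTCOME_DETECTED = "detected"
OUTCOME_NOT_DETECTED = "not_detected"
OUTCOME_NOT_TESTED = "not_tested"
OUTCOMES = (OUTCOME_DETECTED, OUTCOME_NOT_DETECTED, OUTCOME_NOT_TESTED)

QPCR_CSV_COLUMNS = [
    "source",
    "fraction",
    "target",
    "copies_per_reaction_mean",
    "copies_per_reaction_sd",
    "n_replicates",
    "volume_filtered_mL",
    "loq",
]


def per_filter_abundance(
    copies_per_reaction_mean: float, reaction_fraction_of_extract: float = 1.0
) -> float:
    """Scale a per-reaction copy count to the whole filter.

    ``reaction_fraction_of_extract`` is the share of the filter's DNA
    extract loaded into one reaction; the default of 1.0 means reported
    values are already per-filter totals.
    """
    if copies_per_reaction_mean < 0:
        raise ValueError(f"copy count must be nonnegative, got {copies_per_reaction_mean}")
    if not 0.0 < reaction_fraction_of_extract <= 1.0:
        raise ValueError(
            f"reaction fraction must lie in (0, 1], got {reaction_fraction_of_extract}"
        )
    return copies_per_reaction_mean / reaction_fraction_of_extract


def per_ml_abundance(copies_per_filter: float, volume_mL: float) -> float:
    """Copies per mL of water passed through the filter."""
    if volume_mL <= 0:
        raise ValueError(f"filtered volume must be positive, got {volume_mL}")
    return copies_per_filter / volume_mL


def apply_loq(mean_copies: float, loq: float = DEFAULT_LOQ_COPIES) -> bool:
    """True iff the per-reaction mean is censored (strictly below the LOQ)."""
    if loq <= 0:
        raise ValueError(f"LOQ must be positive, got {loq}")
    return mean_copies < loq


@dataclass(frozen=True)
class QpcrAbundance:
    """Normalized abundance of one gene target on one filter fraction.

    For censored records (mean below LOQ) the point values
    ``copies_per_filter`` / ``copies_per_mL`` are ``None`` and only the
    LOQ-equivalent upper bounds are populated.  SDs propagate by pure
    rescaling (no replicate-level model).
    """

    target: str
    source: str
    filter_fraction: str
    copies_per_reaction_mean: float
    copies_per_reaction_sd: float
    n_replicates: int
    volume_filtered_mL: float
    loq_copies_per_reaction: float = DEFAULT_LOQ_COPIES
    reaction_fraction_of_extract: float = 1.0
    censored: bool = field(init=False)
    copies_per_filter: float | None = field(init=False)
    copies_per_filter_sd: float | None = field(init=False)
    copies_per_mL: float | None = field(init=False)
    copies_per_mL_sd: float | None = field(init=False)
    per_filter_upper_bound: float = field(init=False)
    per_mL_upper_bound: float = field(init=False)

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"unknown target {self.target!r}; expected one of {TARGETS}")
        if self.copies_per_reaction_sd < 0:
            raise ValueError("copies_per_reaction_sd must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive integer")
        censored = apply_loq(self.copies_per_reaction_mean, self.loq_copies_per_reaction)
        scale = 1.0 / self.reaction_fraction_of_extract
        bound_filter = per_filter_abundance(
            self.loq_copies_per_reaction, self.reaction_fraction_of_extract
        )
        object.__setattr__(self, "censored", censored)
        object.__setattr__(self, "per_filter_upper_bound", bound_filter)
        object.__setattr__(
            self, "per_mL_upper_bound", per_ml_abundance(bound_filter, self.volume_filtered_mL)
        )
        if censored:
            for name in ("copies_per_filter", "copies_per_filter_sd",
                         "copies_per_mL", "copies_per_mL_sd"):
                object.__setattr__(self, name, None)
        else:
            cpf = per_filter_abundance(
                self.copies_per_reaction_mean, self.reaction_fraction_of_extract
            )
            object.__setattr__(self, "copies_per_filter", cpf)
            object.__setattr__(self, "copies_per_filter_sd", self.copies_per_reaction_sd * scale)
            object.__setattr__(
                self, "copies_per_mL", per_ml_abundance(cpf, self.volume_filtered_mL)
            )
            object.__setattr__(
                self,
                "copies_per_mL_sd",
                self.copies_per_reaction_sd * scale / self.volume_filtered_mL,
            )


def quantify_table(table: pd.DataFrame) -> list[QpcrAbundance]:
    """Build :class:`QpcrAbundance` records from a tidy qPCR table."""
    missing = [c for c in QPCR_CSV_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"qPCR table lacks required columns: {missing}")
    out = []
    for _, row in table.iterrows():
        out.append(
            QpcrAbundance(
                target=str(row["target"]),
                source=str(row["source"]),
                filter_fraction=str(row["fraction"]),
                copies_per_reaction_mean=float(row["copies_per_reaction_mean"]),
                copies_per_reaction_sd=float(row["copies_per_reaction_sd"]),
                n_replicates=int(row["n_replicates"]),
                volume_filtered_mL=float(row["volume_filtered_mL"]),
                loq_copies_per_reaction=float(row["loq"]),
            )
        )
    return out


def abundance_frame(records: Iterable[QpcrAbundance]) -> pd.DataFrame:
    """Tidy output frame; censored rows show only '< bound' columns."""
    rows = []
    for r in records:
        rows.append(
            {
                "source": r.source,
                "fraction": r.filter_fraction,
                "target": r.target,
                "copies_per_reaction_mean": r.copies_per_reaction_mean,
                "censored": r.censored,
                "copies_per_filter": r.copies_per_filter,
                "copies_per_mL": r.copies_per_mL,
                "per_filter_upper_bound": r.per_filter_upper_bound,
                "per_mL_upper_bound": r.per_mL_upper_bound,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DetectionMatrix:
    """Presence/absence of gene targets per (source, fraction-or-leaf) row;
    every cell is exactly one of detected / not_detected / not_tested."""

    frame: pd.DataFrame

    def outcome(self, source: str, fraction: str, target: str) -> str:
        return str(self.frame.loc[(source, fraction), target])


def build_detection_matrix(
    records: Sequence[tuple[str, str, str, str]]
) -> DetectionMatrix:
    """Assemble PCR outcomes into a matrix.

    ``records`` are (source, fraction, target, outcome) tuples.  Cells not
    reported are filled ``not_tested``; conflicting duplicates are an error.
    """
    cells: dict[tuple[str, str], dict[str, str]] = {}
    problems: list[str] = []
    for source, fraction, target, outcome in records:
        if outcome not in OUTCOMES:
            problems.append(
                f"({source}, {fraction}, {target}): invalid outcome {outcome!r}"
            )
            continue
        row = cells.setdefault((source, fraction), {})
        if target in row and row[target] != outcome:
            problems.append(
                f"({source}, {fraction}, {target}): conflicting outcomes "
                f"{row[target]!r} vs {outcome!r}"
            )
            continue
        row[target] = outcome
    if problems:
        raise ValidationError("invalid detection records", problems)
    if not cells:
        return DetectionMatrix(
            pd.DataFrame(
                columns=list(TARGETS),
                index=pd.MultiIndex.from_tuples([], names=["source", "fraction"]),
            )
        )
    index = pd.MultiIndex.from_tuples(sorted(cells), names=["source", "fraction"])
    frame = pd.DataFrame(
        [[cells[key].get(t, OUTCOME_NOT_TESTED) for t in TARGETS] for key in sorted(cells)],
        index=index,
        columns=list(TARGETS),
    )
    return DetectionMatrix(frame)
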