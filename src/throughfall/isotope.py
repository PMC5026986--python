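"""Delta-notation arithmetic, calibration, and the analytical-noise model.

Stable isotope ratios are expressed in delta notation: the relative
difference, in parts per thousand (per mil), between the isotope ratio R of
a sample and that of an international reference — VSMOW for 18O/16O and
atmospheric N2 for 15N/14N.  All downstream mixing arithmetic in this
package is linear in delta space; the absolute reference ratios are kept as
configuration constants only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

ELEMENT_O18 = "O18"
ELEMENT_N15 = "N15"
ELEMENTS = (ELEMENT_O18, ELEMENT_N15)

#: One-sigma analytical precision of the nitrate isotope measurement, per mil.
DEFAULT_PRECISION_PERMIL = {ELEMENT_O18: 0.59, ELEMENT_N15: 0.19}

#: Reference scale conventionally used for each element.
DEFAULT_REFERENCE = {ELEMENT_O18: "VSMOW", ELEMENT_N15: "AIR_N2"}

#: Absolute isotope ratios of the reference materials.  Configuration
#: constants; the pipeline itself works entirely in delta space.
REFERENCE_RATIOS = {"VSMOW": 2005.20e-6, "AIR_N2": 3676.5e-6}

ISOTOPE_CSV_COLUMNS = [
    "sample_id",
    "source",
    "treatment",
    "week",
    "element",
    "delta_permil",
    "sd_permil",
]


def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """Convert an absolute isotope ratio to delta notation (per mil).

    delta = (R_sample / R_standard - 1) * 1000
    """
    if r_sample <= 0 or r_standard <= 0:
        raise ValueError(
            f"isotope ratios must be positive, got sample={r_sample}, "
            f"standard={r_standard}"
        )
    return (r_sample / r_standard - 1.0) * 1000.0


def ratio_from_delta(delta: float, r_standard: float) -> float:
    """Inverse of :func:`delta_from_ratio`; round-trips to machine precision."""
    if delta <= -1000.0:
        raise ValueError(f"delta must exceed -1000 per mil, got {delta}")
    if r_standard <= 0:
        raise ValueError(f"standard ratio must be positive, got {r_standard}")
    return r_standard * (1.0 + delta / 1000.0)


@dataclass
class IsotopeMeasurement:
    """One delta value for one analyte in one sample.

    ``sd_permil`` defaults to the analytical precision for the element
    (0.59 per mil for delta-18O, 0.19 per mil for delta-15N) when unset.
    """

    element: str
    delta_permil: float
    analyte: str = "nitrate"
    reference: str | None = None
    sd_permil: float | None = None

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise ValueError(f"unknown element {self.element!r}; expected one of {ELEMENTS}")
        if not self.delta_permil > -1000.0:
            raise ValueError(
                f"delta_permil must exceed -1000 (ratios are positive), got {self.delta_permil}"
            )
        if self.reference is None:
            self.reference = DEFAULT_REFERENCE[self.element]
        if self.sd_permil is None:
            self.sd_permil = DEFAULT_PRECISION_PERMIL[self.element]
        if self.sd_permil < 0:
            raise ValueError(f"sd_permil must be nonnegative, got {self.sd_permil}")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear correction mapping measured deltas onto the assigned scale.

    Fitted as an ordinary-least-squares line of assigned-on-measured delta
    through at least two reference materials (e.g. IAEA-N3, USGS32, USGS34,
    USGS35).  With unbiased standards the fit reduces to the identity.
    """

    slope: float
    intercept: float
    element: str
    standards_used: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"calibration slope must be positive, got {self.slope}")

    @classmethod
    def fit(
        cls, standards: Sequence[tuple[str, float, float]], element: str
    ) -> "CalibrationCurve":
        """Fit from (name, assigned_delta, measured_delta) triples."""
        if len(standards) < 2:
            raise ValueError("calibration requires at least two standards")
        measured = np.asarray([s[2] for s in standards], dtype=float)
        assigned = np.asarray([s[1] for s in standards], dtype=float)
        if np.ptp(measured) == 0:
            raise ValueError("standards have identical measured values; line is undefined")
        slope, intercept = np.polyfit(measured, assigned, 1)
        return cls(
            slope=float(slope),
            intercept=float(intercept),
            element=element,
            standards_used=tuple(standards),
        )

    @classmethod
    def identity(cls, element: str) -> "CalibrationCurve":
        return cls(slope=1.0, intercept=0.0, element=element)

    def apply(self, delta_measured: float) -> float:
        return self.slope * delta_measured + self.intercept


def calibrate(
    measured: Iterable[IsotopeMeasurement], curve: CalibrationCurve
) -> list[IsotopeMeasurement]:
    """Apply ``delta_corrected = slope * delta_measured + intercept``.

    Preserves ordering and count; every measurement must share the curve's
    element.
    """
    out: list[IsotopeMeasurement] = []
    for m in measured:
        if m.element != curve.element:
            raise ValueError(
                f"element mismatch: measurement is {m.element}, curve is {curve.element}"
            )
        out.append(
            IsotopeMeasurement(
                element=m.element,
                delta_permil=curve.apply(m.delta_permil),
                analyte=m.analyte,
                reference=m.reference,
                sd_permil=m.sd_permil,
            )
        )
    return out


def read_isotope_csv(path: str | Path) -> pd.DataFrame:
    """Read a tidy isotope table; missing ``sd_permil`` cells get the default
    analytical precision for their element."""
    df = pd.read_csv(path)
    missing = [c for c in ISOTOPE_CSV_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValidationError(f"isotope table {path} lacks required columns: {missing}")
    if "sd_permil" not in df.columns:
        df["sd_permil"] = np.nan
    bad = ~df["element"].isin(ELEMENTS)
    if bad.any():
        raise ValidationError(
            "unknown element values in isotope table",
            [f"row {i}: element={e!r}" for i, e in df.loc[bad, "element"].items()],
        )
    fill = df["element"].map(DEFAULT_PRECISION_PERMIL)
    df["sd_permil"] = df["sd_permil"].fillna(fill)
    if (df["delta_permil"] <= -1000).any():
        raise ValidationError("delta_permil values at or below -1000 per mil are impossible")
    return df
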