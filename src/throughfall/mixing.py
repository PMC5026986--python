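"""Two-end-member isotope mass balance for nitrate source attribution.

Freshly nitrified nitrate carries a predictable delta-18O: during microbial
nitrification about two-thirds of the nitrate oxygen comes from ambient
water and one-third from dissolved O2, so

    delta18O_new = w * delta18O_water + (1 - w) * delta18O_O2,   w = 2/3.

Because atmospherically deposited nitrate is strongly 18O-enriched (delta-18O
well above +60 per mil) while the nitrification end member sits near 0 per
mil, mixing new nitrate into the standing pool pulls the pool's delta-18O
down, and the observed decrease quantifies how much was produced:

    f = (delta_initial - delta_final) / (delta_initial - delta_new)

is the fraction of the FINAL pool that is newly produced, and
100 * f / (1 - f) expresses production as a percentage of the ORIGINAL
amount, directly comparable to the measured concentration increase.
Both denominators are exposed under explicit names to prevent confusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import OutOfEnvelopeError, UndefinedMixtureError
from .isotope import DEFAULT_PRECISION_PERMIL, ELEMENT_O18

WATER_FRACTION_DEFAULT = 2.0 / 3.0
#: Default delta-18O of ambient water (per mil, VSMOW), typical terrestrial range.
WATER_DELTA18O_DEFAULT = (-10.0, -5.0)
#: delta-18O of atmospheric (hence dissolved) O2, per mil VSMOW.
O2_DELTA18O_DEFAULT = 23.5
#: Bound deviations within this many analytical SDs are clamped, not rejected.
CLAMP_SDS_DEFAULT = 2.0


@dataclass(frozen=True)
class EndmemberSpec:
    """delta-18O of freshly nitrified nitrate, as an interval with provenance.

    The interval arises from the range assumed for ambient water; its width
    equals ``water_fraction`` times the water-range width.
    """

    endmember_low: float
    endmember_high: float
    water_delta18O_low: float | None = None
    water_delta18O_high: float | None = None
    o2_delta18O: float | None = None
    water_fraction: float = WATER_FRACTION_DEFAULT

    def __post_init__(self) -> None:
        if self.endmember_low > self.endmember_high:
            raise ValueError(
                f"end-member interval inverted: [{self.endmember_low}, {self.endmember_high}]"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.endmember_low + self.endmember_high)

    @property
    def width(self) -> float:
        return self.endmember_high - self.endmember_low


def nitrification_endmember(
    water_low: float = WATER_DELTA18O_DEFAULT[0],
    water_high: float = WATER_DELTA18O_DEFAULT[1],
    o2: float = O2_DELTA18O_DEFAULT,
    water_fraction: float = WATER_FRACTION_DEFAULT,
) -> EndmemberSpec:
    """Predict the delta-18O interval of nitrified nitrate from the
    water/O2 oxygen-sourcing rule, evaluated at both water bounds."""
    if water_low > water_high:
        raise ValueError(f"inverted water range [{water_low}, {water_high}]")
    if not 0.0 <= water_fraction <= 1.0:
        raise ValueError(f"water_fraction must lie in [0, 1], got {water_fraction}")
    bounds = sorted(
        water_fraction * w + (1.0 - water_fraction) * o2 for w in (water_low, water_high)
    )
    return EndmemberSpec(
        endmember_low=bounds[0],
        endmember_high=bounds[1],
        water_delta18O_low=water_low,
        water_delta18O_high=water_high,
        o2_delta18O=o2,
        water_fraction=water_fraction,
    )


def mixing_fraction(
    delta_initial: float,
    delta_final: float,
    delta_new: float,
    sd_permil: float = DEFAULT_PRECISION_PERMIL[ELEMENT_O18],
    clamp_sds: float = CLAMP_SDS_DEFAULT,
) -> float:
    """Fraction of the final nitrate pool that is newly produced.

    ``delta_final`` must lie between ``delta_new`` and ``delta_initial``.
    Analytical noise can push an observation slightly past a bound: values
    within ``clamp_sds`` measurement SDs of a bound are clamped to it (with
    a warning); farther violations raise :class:`OutOfEnvelopeError`.
    """
    if delta_new == delta_initial:
        raise UndefinedMixtureError(
            f"end member equals the initial pool ({delta_initial} per mil); "
            "the mixture is undefined"
        )
    lo, hi = sorted((delta_new, delta_initial))
    df = delta_final
    if not lo <= df <= hi:
        bound = lo if df < lo else hi
        excess = abs(df - bound)
        f_raw = (delta_initial - bound) / (delta_initial - delta_new)
        if excess <= clamp_sds * sd_permil:
            warnings.warn(
                f"delta_final={df} per mil lies {excess:.2f} per mil outside the "
                f"mixing envelope [{lo}, {hi}]; within {clamp_sds} SD of the bound, "
                "clamping",
                stacklevel=2,
            )
            df = bound
        else:
            raise OutOfEnvelopeError(
                f"delta_final={df} per mil lies {excess:.2f} per mil outside the "
                f"mixing envelope [{lo}, {hi}], beyond {clamp_sds} analytical SDs "
                f"({clamp_sds * sd_permil:.2f} per mil)",
                raw_delta_final=df,
                raw_fraction=f_raw,
            )
    return (delta_initial - df) / (delta_initial - delta_new)


def new_to_original_pct(frac_new_of_final: float) -> float:
    """Re-express the fraction of the final pool as a percentage of the
    original amount: 100 * f / (1 - f)."""
    f = frac_new_of_final
    if f == 1.0:
        raise UndefinedMixtureError(
            "the pool is fully replaced (f = 1); the new:original ratio is infinite"
        )
    if not 0.0 <= f < 1.0:
        raise ValueError(f"fraction must lie in [0, 1), got {f}")
    return 100.0 * f / (1.0 - f)


def concentration_increase_pct(c_initial: float, c_final: float) -> float:
    """Concentration-based counterpart: 100 * (c_final - c_initial) / c_initial."""
    if c_initial <= 0:
        raise ValueError(f"initial concentration must be positive, got {c_initial}")
    return 100.0 * (c_final - c_initial) / c_initial


def implied_new_delta15N(
    delta_initial_15N: float, delta_final_15N: float, frac_new_of_final: float
) -> float:
    """Invert the mixing mass balance on delta-15N.

    Given the fraction f of the final pool that is new, the delta-15N the
    produced nitrate must have carried is
    (delta_final - (1 - f) * delta_initial) / f.  Nitrification of
    isotopically light ammonium (generally below 0 per mil) should make
    this implied value lower than the initial pool's — a qualitative sign
    check, since no first-principles 15N end member is predicted.
    """
    f = frac_new_of_final
    if not 0.0 < f <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {f}")
    return (delta_final_15N - (1.0 - f) * delta_initial_15N) / f


@dataclass(frozen=True)
class MixingResult:
    """Outcome of the two-end-member attribution for one incubation."""

    delta_initial: float
    delta_final: float
    endmember: EndmemberSpec
    frac_new_of_final_low: float
    frac_new_of_final_high: float
    new_to_original_pct_low: float
    new_to_original_pct_high: float
    conc_based_pct: float | None = None
    consistent: bool | None = None


def attribute_nitrification(
    delta_initial: float,
    delta_final: float,
    endmember: EndmemberSpec,
    c_initial: float | None = None,
    c_final: float | None = None,
    tolerance_pp: float = 2.0,
    sd_permil: float = DEFAULT_PRECISION_PERMIL[ELEMENT_O18],
) -> MixingResult:
    """Full attribution: interval mixing fractions at both end-member bounds,
    their new:original percentages, and (when concentrations are supplied)
    the concentration-based cross-check.

    ``consistent`` is True iff the concentration-based percentage lies within
    [pct_low - tolerance_pp, pct_high + tolerance_pp]; None when no
    concentrations were given.
    """
    fracs = sorted(
        mixing_fraction(delta_initial, delta_final, e, sd_permil=sd_permil)
        for e in (endmember.endmember_low, endmember.endmember_high)
    )
    pcts = [new_to_original_pct(f) for f in fracs]
    conc_pct: float | None = None
    consistent: bool | None = None
    if c_initial is not None and c_final is not None:
        conc_pct = concentration_increase_pct(c_initial, c_final)
        consistent = pcts[0] - tolerance_pp <= conc_pct <= pcts[1] + tolerance_pp
    return MixingResult(
        delta_initial=delta_initial,
        delta_final=delta_final,
        endmember=endmember,
        frac_new_of_final_low=fracs[0],
        frac_new_of_final_high=fracs[1],
        new_to_original_pct_low=pcts[0],
        new_to_original_pct_high=pcts[1],
        conc_based_pct=conc_pct,
        consistent=consistent,
    )
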