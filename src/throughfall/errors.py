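"""Exception hierarchy shared across the package."""


class ThroughfallError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ThroughfallError, ValueError):
    """Malformed or inconsistent input data.

    Carries a list of row-level messages in ``details`` when raised while
    loading a table, so callers can report every offending row at once.
    """

    def __init__(self, message: str, details: list[str] | None = None):
        self.details = list(details or [])
        if self.details:
            message = message + "\n  " + "\n  ".join(self.details)
        super().__init__(message)


class MissingDataError(ThroughfallError, ValueError):
    """A computation requires a value that is flagged not-determined."""


class UndefinedMixtureError(ThroughfallError, ValueError):
    """Two-end-member mixing is undefined (end members coincide, or the
    mixing fraction leaves its domain, e.g. a fully replaced pool in a
    ratio that would be infinite)."""


class OutOfEnvelopeError(ThroughfallError, ValueError):
    """The observed final isotope value lies outside the interval spanned
    by the initial pool and the production end member by more than can be
    attributed to analytical noise.

    Attributes
    ----------
    raw_delta_final : the offending observed value (per mil)
    raw_fraction : the mixing fraction implied by clamping the value to the
        nearer envelope bound (reported for diagnostics, never used).
    """

    def __init__(self, message: str, raw_delta_final: float, raw_fraction: float):
        super().__init__(message)
        self.raw_delta_final = raw_delta_final
        self.raw_fraction = raw_fraction
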