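"""Typed error hierarchy.

Fitting and matching operations raise subclasses of :class:`PTRError` so that
a Monte Carlo driver can record a method failure for one replicate and carry
on, while genuine configuration mistakes surface as ordinary exceptions.
"""

from __future__ import annotations


class PTRError(Exception):
    """Base class for recoverable analysis errors."""


class SchemaError(PTRError):
    """A declared column, role or rule term does not match the data."""


class CodingError(PTRError):
    """The treatment-arm column cannot be recoded to effect coding."""


class DataError(PTRError):
    """Invalid values in the data (missing outcome/arm, bad indicators...)."""


class InsufficientDataError(PTRError):
    """Fewer observations than parameters for a requested fit."""


class SingularFitError(PTRError):
    """Rank-deficient design matrix.

    ``columns`` names the offending (linearly dependent) design columns.
    """

    def __init__(self, message: str, columns: tuple[str, ...] = ()):
        super().__init__(message)
        self.columns = tuple(columns)


class NoPairsError(PTRError):
    """No treated/control pairs could be formed (empty arm or caliper too tight)."""


class DegenerateScoreError(PTRError):
    """The prognostic score has zero variance; caliper matching is undefined."""


class DegenerateCompositeError(PTRError):
    """The composite moderator Z* is constant; no rule can be fitted on it.

    ``diagnostics`` carries the moderator weights and matching counts that led
    to the degenerate composite, for reporting.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = dict(diagnostics or {})
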