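"""Exception hierarchy shared across the package.

CLI exit codes: :class:`PanelValidationError` family maps to exit code 2,
:class:`DegeneratePanelError` to exit code 3.
"""


class AnchorCutError(Exception):
    """Base class for all package errors."""


class PanelValidationError(AnchorCutError, ValueError):
    """Input data violate the panel contract (range, schema, duplicates)."""


class InsufficientPanelError(PanelValidationError):
    """Fewer ratings than the operation requires (SEs need >= 2 judges)."""


class DegeneratePanelError(AnchorCutError):
    """SE_L + SE_H = 0 with distinct anchor means: the Z equation has no
    finite solution."""


class NoAnalyticOracleError(AnchorCutError):
    """The population-level closed form does not apply (skew, contamination,
    or material truncation present)."""
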