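"""Exception hierarchy for the package."""


class AkiImpactError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AkiImpactError):
    """A configuration object or file is invalid (bad probability, unknown field, ...)."""


class DataError(AkiImpactError):
    """Input data violate a precondition (non-positive creatinine, too few measurements, ...)."""


class ValidationError(AkiImpactError):
    """Schema validation of user-supplied input files failed.

    ``problems`` holds one human-readable message per offending row/column.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            f"{len(self.problems)} validation problem(s):\n" + "\n".join(self.problems)
        )


class FitFailureError(AkiImpactError):
    """A regression fit did not converge or was degenerate; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)
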