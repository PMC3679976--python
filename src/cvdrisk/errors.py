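"""Exception hierarchy shared across the package."""


class CvdRiskError(Exception):
    """Base class for all package errors."""


class ChartValidationError(CvdRiskError):
    """A chart file failed structural validation.

    Carries the full list of problems so a user can fix every offending
    row in one pass; ``str()`` renders them all.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        msg = "chart validation failed with %d problem(s):\n  " % len(self.problems)
        super().__init__(msg + "\n  ".join(self.problems))


class InputError(CvdRiskError):
    """A measurement value is invalid (e.g. non-positive blood pressure)."""


class MissingInputError(CvdRiskError):
    """A required input is missing; the record should be excluded, not imputed."""


class OutOfScopeError(CvdRiskError):
    """The input falls outside the instrument's domain (e.g. age below 40)."""


class VariantMismatchError(CvdRiskError):
    """Profile and chart disagree on cholesterol availability."""


class ConfigError(CvdRiskError):
    """Invalid generator or analysis configuration."""
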