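"""Exception types shared across the package."""


class ParScoreError(Exception):
    """Base class for all package errors."""


class DomainError(ParScoreError, ValueError):
    """An argument is outside its documented domain."""


class MissingLandmarkError(ParScoreError):
    """A required landmark is absent from the arch."""


class DegenerateFrameError(ParScoreError):
    """The occlusal-plane anchors do not determine a plane (fewer than
    3 points, or collinear)."""


class InsufficientDataError(ParScoreError):
    """Too few observations for the requested statistic."""


class SchemaError(ParScoreError, ValueError):
    """A file does not conform to the expected schema.

    ``violations`` lists every problem found, not just the first.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))
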