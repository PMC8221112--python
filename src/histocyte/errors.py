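"""Exception types shared across the pipeline.

Every stage failure maps onto one of these so the CLI can translate them
into stable exit codes (2 = configuration, 3 = data, 4 = stage failure).
"""


class ConfigurationError(ValueError):
    """Invalid or inconsistent configuration (unknown channel, bad panel...)."""


class SceneValidationError(ConfigurationError):
    """A scene config violates its invariants (e.g. composition != 1)."""


class PlacementError(RuntimeError):
    """Scene geometry could not be realized (field too small for follicles)."""


class DataError(ValueError):
    """Invalid input data (non-finite pixels, frame mismatch...)."""


class EstimationError(RuntimeError):
    """A statistical estimate could not be formed (too few foreground pixels)."""


class ConditioningError(RuntimeError):
    """A linear system is singular or too ill-conditioned to invert."""
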