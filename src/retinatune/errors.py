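"""Exception hierarchy for the retinatune pipeline."""


class RetinatuneError(Exception):
    """Base class for all retinatune errors."""


class ParameterError(RetinatuneError, ValueError):
    """A parameter is outside its admissible range."""


class DataError(RetinatuneError, ValueError):
    """Input data violate a structural precondition."""


class FitError(RetinatuneError, RuntimeError):
    """A model fit failed to converge or hit a bound."""


class SaturationError(RetinatuneError, ValueError):
    """A response amplitude reached or exceeded the fitted maximum."""


class EmptyOpponentError(RetinatuneError, ValueError):
    """No hyperpolarizing responses found; cell not opponent or adaptation insufficient."""


class InvalidStateError(RetinatuneError, ValueError):
    """A forbidden opsin co-expression combination was requested."""


class NoCallError(RetinatuneError, ValueError):
    """No label channel exceeded its threshold."""


class CoverageError(RetinatuneError, ValueError):
    """The wavelength grid does not cover the required range."""


class ConfigurationError(RetinatuneError, ValueError):
    """A configuration value is missing or inconsistent."""
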