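"""Exception hierarchy."""


class NeuroscreenError(Exception):
    """Base class for all package-specific errors."""


class GenerationError(NeuroscreenError):
    """Synthetic scene could not be generated under the given constraints."""


class PatternNameError(NeuroscreenError, ValueError):
    """Substrate identifier does not match the DxxxLyyy / flat grammar."""


class AngleEstimationError(NeuroscreenError):
    """No dominant direction found in a reference image."""


class DegenerateInputError(NeuroscreenError, ValueError):
    """Input carries no usable signal (constant image, constant sample...)."""


class ConsistencyError(NeuroscreenError):
    """Cross-referenced records are inconsistent (dangling ids, shape mismatch)."""


class ConfigError(NeuroscreenError):
    """Run configuration is incomplete or out of domain."""
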