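"""Exception hierarchy."""


class PentailError(Exception):
    """Base class for all package-specific errors."""


class ManifestFormatError(PentailError):
    """A manifest file is structurally unreadable (missing columns, bad types)."""


class IntegrityError(PentailError):
    """Data violate an invariant (duplicate frames, label/category mismatch)."""


class ConfigurationError(PentailError):
    """A configuration object is internally inconsistent or infeasible."""


class BalanceError(PentailError):
    """Class balancing is impossible (no positive sequences)."""


class EvaluationError(PentailError):
    """An evaluation cannot be computed (e.g. single-class test labels)."""


class LeakageError(PentailError):
    """A pen appears on both sides of a train/validation/test split."""
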