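"""Exception hierarchy for barriereis."""


class BarrierEisError(Exception):
    """Base class for all barriereis errors."""


class DomainError(BarrierEisError, ValueError):
    """An argument is outside the physically meaningful domain."""


class IdentifiabilityError(BarrierEisError):
    """A spectrum is too short or too narrow-band to constrain the circuit."""


class NoDeflectionError(BarrierEisError):
    """A clamped-voltage trace shows no usable current deflection."""


class EquilibriumError(BarrierEisError):
    """A current trace has not reached baseline equilibrium."""


class PairingError(BarrierEisError):
    """A paired test was requested on arms that cannot be paired."""


class NormalizationError(BarrierEisError):
    """A baseline value is unusable as a normalization divisor."""


class CalibrationError(BarrierEisError):
    """Nuisance-parameter calibration could not bracket a root."""


class FileFormatError(BarrierEisError):
    """A delimited input file does not match its expected dialect."""
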