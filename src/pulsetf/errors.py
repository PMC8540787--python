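"""Exception hierarchy for pulsetf.

Every error raised by the package derives from :class:`PulseTFError`, so
callers can catch one type at an application boundary.  The finer-grained
subclasses mirror the distinct failure modes of the pipeline: malformed
signals, unit mismatches, contract violations between the periodic and
finite-experiment solvers, degenerate fits, and I/O parse failures.
"""


class PulseTFError(Exception):
    """Base class for all pulsetf errors."""


class InvalidSignalError(PulseTFError, ValueError):
    """A sampled signal violates its invariants (dt, length, period grid)."""


class UnitError(PulseTFError, ValueError):
    """A signal carries a unit incompatible with the requested operation."""


class ContractError(PulseTFError, ValueError):
    """An operation was called outside its contract (e.g. wrong periodicity)."""


class ParameterError(PulseTFError, ValueError):
    """Viscoelastic or scale parameters violate their positivity invariants."""


class InvalidRecordError(PulseTFError, ValueError):
    """A compression record violates its invariants (time order, endpoints)."""


class SingularFitError(PulseTFError, ValueError):
    """A regression problem is degenerate (e.g. constant strain)."""


class FitFailureError(PulseTFError, RuntimeError):
    """A parameter search produced no usable optimum (all-NaN surface)."""


class DegenerateNormalizationError(PulseTFError, ValueError):
    """Min-max normalization requested for a constant waveform."""


class NoPeakError(PulseTFError, ValueError):
    """No systolic peak could be located in a pulse waveform."""


class ParseError(PulseTFError, ValueError):
    """A CSV/JSON input file is malformed; the message names the line."""


class ConfigError(PulseTFError, ValueError):
    """A run configuration is invalid (unknown keys, missing paths)."""
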