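"""Exception hierarchy for pepflux."""


class PepfluxError(Exception):
    """Base class for all pepflux errors."""


class InvalidInputError(PepfluxError, ValueError):
    """A physical quantity is outside its valid domain (e.g. a non-positive
    concentration, a pH outside [0, 14], an efficiency outside (0, 1])."""


class ProtocolError(PepfluxError, ValueError):
    """An assay protocol is malformed (unknown event kind, event outside the
    run, non-positive sampling interval)."""


class TraceError(PepfluxError, ValueError):
    """A fluorescence or ratio trace violates its invariants (empty trace,
    non-positive reference channel, mismatched vector lengths)."""


class WindowError(PepfluxError, ValueError):
    """A readout window does not fit inside the trace it is applied to."""


class InconsistentCallsError(PepfluxError, ValueError):
    """Flux-direction calls violate the monotone direction-vs-voltage law
    (an acidification observed at a voltage above an alkalinization)."""
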