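"""Exception hierarchy.

Validation problems (bad judgments, broken reciprocity, schema violations)
derive from :class:`SwotAhpError` so callers can catch everything the package
raises with one handler; the CLI maps subclasses onto its exit codes.
"""


class SwotAhpError(Exception):
    """Base class for all errors raised by swotahp."""


class JudgmentError(SwotAhpError, ValueError):
    """A pairwise judgment is unparseable or outside the admissible domain."""


class MatrixValidationError(SwotAhpError, ValueError):
    """A comparison matrix violates shape, positivity, or reciprocity."""


class UnsupportedOrderError(SwotAhpError, ValueError):
    """Matrix order exceeds the random-index table and no extension was given."""


class ConfigError(SwotAhpError, ValueError):
    """A configuration file violates the schema; message carries a field path."""


class ConsistencyGateError(SwotAhpError, RuntimeError):
    """A group's consistency ratio exceeded the acceptability threshold."""


class DegenerateAnalysisError(SwotAhpError, RuntimeError):
    """The analysis is degenerate (e.g. all intensities zero, rho undefined)."""
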