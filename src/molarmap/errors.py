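"""Exception hierarchy.

``InputError`` covers everything a user can fix (bad files, bad
annotations, inconsistent tables); ``ComputationError`` covers failures
of the numerics on valid-looking input (degenerate geometry, singular
matrices).  The CLI maps them to exit codes 1 and 2 respectively.
"""


class MolarMapError(Exception):
    """Base class for all package errors."""


class InputError(MolarMapError):
    """User-correctable problem with an input file, annotation or table."""


class ComputationError(MolarMapError):
    """A computation failed on structurally valid input."""
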