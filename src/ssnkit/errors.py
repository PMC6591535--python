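"""Exception hierarchy.

``InputFormatError`` covers anything wrong with user-supplied files or
streams (bad characters, wrong column counts, duplicate ids) and maps to
CLI exit code 2.  ``InvariantError`` covers violated structural contracts
(asymmetric distance matrix, dangling graph edges) and maps to exit code 3.
"""


class SSNKitError(Exception):
    """Base class for all package-specific errors."""


class InputFormatError(SSNKitError):
    """A file or stream could not be parsed under the declared format."""


class InvariantError(SSNKitError):
    """A structural invariant of a domain object was violated."""
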