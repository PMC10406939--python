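"""Exception hierarchy shared across the toolkit.

The CLI maps :class:`HepasegError` subclasses to exit code 2; everything
else is a genuine bug and propagates.
"""


class HepasegError(Exception):
    """Base class for all user-facing errors raised by hepaseg."""


class ConfigurationError(HepasegError):
    """A parameter object violates one of its invariants."""


class InputError(HepasegError):
    """Input data (image, mask, file) is malformed or incompatible."""
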