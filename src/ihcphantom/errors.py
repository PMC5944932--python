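"""Exception hierarchy for the phantom toolkit."""


class PhantomError(Exception):
    """Base class for all errors raised by this package."""


class LibraryLoadError(PhantomError):
    """An on-disk object library is missing files or violates an invariant."""


class GenerationError(PhantomError):
    """Phantom synthesis cannot satisfy its contract (counts, locations)."""


class RatioError(PhantomError):
    """A requested ratio is undefined (e.g. zero total nuclei)."""


class FitError(PhantomError):
    """The mapping fit is underdetermined or rank deficient."""


class ProtocolError(PhantomError):
    """The held-out evaluation protocol cannot be applied to the given data."""


class AgreementError(PhantomError):
    """Agreement statistics are undefined for the given inputs."""
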