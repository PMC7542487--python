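"""Exception types shared across the package."""


class InputError(ValueError):
    """Invalid user-supplied data or parameters."""


class DegenerateKernelError(ValueError):
    """A Gram matrix is unusable (e.g. zero self-similarity on the diagonal)."""


class NumericalError(RuntimeError):
    """A linear solve or factorization failed beyond recoverable jitter."""


class UnknownStyleError(KeyError):
    """A prediction was requested for a style group the model never saw.

    Raised by Rule-2 prediction; the caller should fall back to Rule 3,
    which handles unseen styles by direct extrapolation.
    """
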