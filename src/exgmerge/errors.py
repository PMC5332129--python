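"""Exception types shared across the package."""


class ExgmergeError(Exception):
    """Base class for package-specific failures."""


class EmptyDatasetError(ExgmergeError, ValueError):
    """Raised when an input source yields zero usable observations."""


class DegenerateGroupError(ExgmergeError, ValueError):
    """Raised when a reflection group cannot support a distribution fit
    (too few observations or zero variance)."""


class InsufficientMultiplicityError(DegenerateGroupError):
    """Raised when a group has too few observations for the ex-Gaussian fit."""
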