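"""Exception hierarchy.

Support-boundary violations raise loudly (never silent zeros or NaN): a rate
law evaluated outside its temperature support would otherwise corrupt fits.
"""


class KineticsError(Exception):
    """Base class for all ratekit errors."""


class DomainError(KineticsError, ValueError):
    """Input outside a formula's support (deformed base <= 0, T <= T0, ...)."""


class SingularTransitivityError(KineticsError, ZeroDivisionError):
    """Apparent activation energy is zero: gamma = 1/Ea undefined."""


class DivergenceError(KineticsError):
    """Evaluation refused near a genuine pole of a tunneling formula."""


class InputError(KineticsError, ValueError):
    """Malformed user input (file contents, inconsistent system definition)."""
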