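"""Exception hierarchy for network validation and numerical failures."""


class WordageError(Exception):
    """Base class for all package-specific errors."""


class NegativeRateError(WordageError):
    """A transmission rate is negative (or above one)."""


class RowSumError(WordageError):
    """A population's transmission rates do not sum to one."""


class UnreachableError(WordageError):
    """Some peripheral population can never receive a word from the centre."""


class RateRangeError(WordageError):
    """A builder parameter is outside the range that keeps all rates valid."""


class CutoffError(WordageError):
    """The age cut-off grew past the hard limit without meeting the tail tolerance."""


class SingularityError(WordageError):
    """The (E - A) system is singular; the network cannot reach equilibrium."""


class NegativeVarianceError(WordageError):
    """The moment solve produced a variance below the numerical noise floor."""


class MissingInitError(WordageError):
    """Pre-emergence age mass was requested but no initial distribution was given."""


class BarrierIsCenterError(WordageError):
    """The barrier node coincides with the central population."""


class CoordinateRangeError(WordageError):
    """A latitude or longitude is outside its valid range."""


class ZeroRowError(WordageError):
    """An interaction-density row is entirely zero and cannot be normalized."""
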