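"""Typed errors.

Degenerate statistics surface as exceptions, never as silent NaN: a fully
fixed population has H_S = 0 (and He = 0 at every locus), and neither the
Shannon heterozygosity statistic nor F_IS is defined there.
"""


class ShannonHetError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ShannonHetError, ValueError):
    """Malformed or empty input (empty profile, bad counts, unknown label)."""


class UndefinedStatisticError(ShannonHetError, ArithmeticError):
    """A statistic has no defined value, e.g. F_IS or ¹H_IS under total fixation."""


class UndefinedEvennessError(UndefinedStatisticError):
    """Evenness H_S/ln V is undefined because V < 2 (ln 1 = 0)."""


class ParseError(InvalidInputError):
    """A file could not be parsed; carries file and line context in the message."""
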