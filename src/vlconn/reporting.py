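"""Rounding conventions for reported statistics, centralized.

Connectivity fractions are printed as whole percentages, classifier
training fractions to two decimals, standard deviations to two decimals,
and census totals in millions (one decimal) or thousands.  Keeping the
conventions in one place makes reported numbers reproducible verbatim.
"""

from __future__ import annotations


def fraction_percent(count: int, total: int, decimals: int = 0) -> float:
    """Percentage of ``count`` out of ``total``, rounded for reporting."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals) if decimals else round(100.0 * count / total)


def round_sd(value: float, decimals: int = 2) -> float:
    """Standard deviations are reported to two decimals by default."""
    return round(value, decimals)


def in_millions(value: float, decimals: int = 1) -> float:
    """A cell count expressed in millions, one decimal by default."""
    return round(value / 1e6, decimals)


def in_thousands(value: float, decimals: int = 0) -> float:
    """A cell count expressed in thousands."""
    return round(value / 1e3, decimals) if decimals else round(value / 1e3)
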