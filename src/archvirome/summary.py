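"""Small reporting helpers shared by the CLI and analysis scripts."""

from __future__ import annotations


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage of a count over a total, rounded for reporting.

    Uses round-half-away-from-zero, the convention of printed tables,
    rather than banker's rounding.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty total is undefined")
    value = 100.0 * numerator / denominator
    shift = 10**ndigits
    import math

    return math.floor(abs(value) * shift + 0.5) / shift * (1 if value >= 0 else -1)
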