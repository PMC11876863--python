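"""Small summary-reporting helpers shared across modules."""

from __future__ import annotations

__all__ = ["percent"]


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Fraction expressed as a percentage, rounded half-away-from-zero.

    ``percent(93, 102)`` is ``91.2``.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0 or numerator > denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    value = 100.0 * numerator / denominator
    scale = 10**ndigits
    import math

    return math.floor(value * scale + 0.5) / scale
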