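"""Small metric helpers shared by evaluation and reporting."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (table-reporting convention).

    Python's builtin ``round`` is banker's rounding; printed clinical
    tables conventionally round 0.005 up, so 0.805 -> 0.81.
    """
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(x))
    if d < 0:
        return float(-(-d).quantize(q, rounding=ROUND_HALF_UP))
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def f1_from(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision: 2rp / (r + p)."""
    if recall + precision == 0:
        raise ValueError("recall + precision must be positive")
    return 2.0 * recall * precision / (recall + precision)
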