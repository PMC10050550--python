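"""Display-rounding helpers shared by summaries and reports."""

from __future__ import annotations


def percent(numerator: float, denominator: float, decimals: int = 0) -> float:
    """``numerator / denominator`` as a percentage, rounded for display.

    With ``decimals=0`` an integer is returned (e.g. ``percent(3462, 8793)``
    is ``39``); otherwise a float rounded to that many decimals
    (``percent(8606, 8793, 1)`` is ``97.9``).
    """
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    value = 100.0 * numerator / denominator
    if decimals == 0:
        return int(round(value))
    return round(value, decimals)
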