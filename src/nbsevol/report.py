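"""Display arithmetic shared by the census tables and the pipeline report.

All percentages and means in the summary tables are shown at 2 decimals with
half-up rounding (so 52.6011... % of genes in multi-gene families prints as
"52.60%" and 273 members over 64 families prints as "4.27").
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (display convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Percentage at display rounding; 0 when the denominator is 0."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, ndigits)


def mean_per_group(total: float, groups: float, ndigits: int = 2) -> float:
    """Members-per-family style mean at display rounding; 0 for no groups."""
    if groups == 0:
        return 0.0
    return round_half_up(total / groups, ndigits)


def format_percentage(numerator: float, denominator: float) -> str:
    return f"{percentage(numerator, denominator):.2f}%"


def format_mean(total: float, groups: float) -> str:
    return f"{mean_per_group(total, groups):.2f}"
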