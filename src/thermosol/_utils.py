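"""Small shared helpers."""

from decimal import ROUND_HALF_UP, Decimal

GAS_CONSTANT = 8.314  # J·mol⁻¹·K⁻¹, fixed by convention throughout the package


def round_half_up(value: float, decimals: int) -> float:
    """Round with ties going away from zero, as printed tables usually do.

    Python's built-in ``round`` uses banker's rounding, which disagrees with
    the round-half-up convention of published solubility tables at exact
    .5 ties; golden-cell comparisons use this helper instead.
    """
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
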