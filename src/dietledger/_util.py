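"""Shared helpers: name normalization and display rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def normalize_name(name: str) -> str:
    """Canonical form of a dish or ingredient name.

    Trims, case-folds, and collapses internal whitespace. Matching
    elsewhere in the package is exact after this normalization; there is
    deliberately no fuzzy matching.
    """
    return " ".join(str(name).strip().casefold().split())


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero at `ndigits` decimals.

    Python's builtin `round` is banker's rounding; report tables here use
    conventional half-up rounding (13.875 -> 13.88).
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, ndigits: int = 1) -> float:
    """Share of `count` in `total` as a percentage, rounded half-up."""
    if total <= 0:
        raise ValueError("percentage denominator must be positive")
    return round_half_up(count / total * 100.0, ndigits)
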