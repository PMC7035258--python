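"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["format_percent", "child_seed"]


def format_percent(count: int | float, total: int | float) -> str:
    """``100*count/total`` rounded half-up to two decimals, as a string.

    The rounding convention used throughout the report tables
    (e.g. 353/420 -> "84.05", 1/3 -> "33.33").
    """
    if total == 0:
        raise ValueError("total must be positive")
    value = Decimal(str(100 * count)) / Decimal(str(total))
    return str(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derivation from one master seed (< 2**31)."""
    h = 2166136261
    for ch in f"{seed}:{stage}".encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h % (2**31)
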