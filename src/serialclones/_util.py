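"""Small shared numeric helpers."""

from __future__ import annotations

import math


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Python's built-in ``round`` uses banker's rounding; copy-number and
    fold-change displays in this package follow the half-away-from-zero
    convention instead (5.28 -> 5, 2.83 -> 3, 4.5 -> 5, -2.5 -> -3).
    """
    if x >= 0:
        return int(math.floor(x + 0.5))
    return int(math.ceil(x - 0.5))


def normalize_chrom(chrom: str) -> str:
    """Canonical chromosome key: strip a leading 'chr' prefix, keep case of names."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c
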