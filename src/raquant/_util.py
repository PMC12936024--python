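"""Small shared helpers: presentation rounding and sequence alphabet handling."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

VALID_BASES = frozenset("ACGTUN")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (printed-table convention).

    Python's builtin round() is banker's rounding; printed percentage tables in
    clinical work use half-up, so 45.3125 -> 45.31 but 33.335 -> 33.34.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, ndigits: int = 2) -> float:
    """Percentage ``100*count/total`` rounded half-up; ``total`` must be > 0."""
    if total <= 0:
        raise ValueError(f"percentage denominator must be positive, got {total}")
    return round_half_up(100.0 * count / total, ndigits)


def normalize_sequence(sequence: str) -> str:
    """Uppercase a nucleotide sequence and map RNA U to DNA T.

    Rejects characters outside {A,C,G,T,U,N} with the offending position.
    """
    seq = sequence.upper()
    for i, base in enumerate(seq):
        if base not in VALID_BASES:
            raise ValueError(f"invalid base {base!r} at position {i}")
    return seq.replace("U", "T")
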