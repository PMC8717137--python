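"""Shared helpers: deterministic seeding and presentation rounding."""

from __future__ import annotations

import hashlib
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, as tables are conventionally printed.

    Python's built-in ``round`` is banker's rounding; printed shares like
    36.25 -> 36.3 need half-up.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from a master seed by stable hashing.

    Adding or removing a stage never perturbs the randomness of the others,
    and the result is independent of Python's hash randomization.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
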