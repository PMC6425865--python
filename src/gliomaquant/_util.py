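"""Small shared helpers: rounding conventions and seeding."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

#: Seed used by every generator when the caller does not supply one.
DEFAULT_SEED = 20190313


def round_half_up(x: float, decimals: int) -> float:
    """Round ``x`` to ``decimals`` places with ties going away from zero.

    Plain :func:`round` uses banker's rounding; published tables almost
    universally round half up, so p-value matching goes through this.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def truncate(x: float, decimals: int) -> float:
    """Truncate ``x`` toward zero at ``decimals`` places."""
    f = 10.0**decimals
    return math.trunc(x * f) / f
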