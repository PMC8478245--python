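"""Small shared helpers: report-time rounding and normal quantiles."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

from scipy.stats import norm


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, the convention used in printed tables.

    Python's built-in ``round`` is banker's rounding; cost tables round 0.5 up.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def normal_quantile(p: float) -> float:
    """Exact standard-normal quantile (e.g. 1.959964 at p=0.975, not 1.96)."""
    return float(norm.ppf(p))
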