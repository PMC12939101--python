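from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero at the given decimal place.

    Display rounding for contributions, DRVs and margins: plain ``round``
    uses banker's rounding and would turn e.g. 26.985 into 26.98; the
    tables round halves up. The float is routed through its shortest
    decimal repr so 9.835 (stored as 9.8349999...) still rounds to 9.84.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
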