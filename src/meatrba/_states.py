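"""Distinguished non-numeric states used throughout the assessment.

Three states are deliberately kept distinct from each other, from ``None``
and from every number:

``NOT_REPORTED``
    No retrieved occurrence study quantified the component in that product.
    A data-availability state — not zero, not absence of risk.
``NA``
    Not applicable: the quantity is undefined for this cell (e.g. a margin
    of exposure for a hazard judged against a regulatory limit, or a DRV
    contribution for an "as low as possible" nutrient). Arises from
    computation, never from data.
``AS_LOW_AS_POSSIBLE``
    The guidance class for nutrients with no safe-intake reference value
    (trans and saturated fatty acids); carries no number.
"""

from __future__ import annotations


class Sentinel:
    """A named singleton; equality is identity, so it never equals a number."""

    __slots__ = ("_name",)
    _registry: dict[str, "Sentinel"] = {}

    def __new__(cls, name: str) -> "Sentinel":
        if name in cls._registry:
            return cls._registry[name]
        obj = super().__new__(cls)
        obj._name = name
        cls._registry[name] = obj
        return obj

    @property
    def name(self) -> str:
        return self._name

    def __repr__(self) -> str:
        return self._name

    def __reduce__(self):
        return (Sentinel, (self._name,))

    def __deepcopy__(self, memo):
        return self

    def __copy__(self):
        return self


NOT_REPORTED = Sentinel("NOT_REPORTED")
NA = Sentinel("NA")
AS_LOW_AS_POSSIBLE = Sentinel("AS_LOW_AS_POSSIBLE")


def is_number(x: object) -> bool:
    """True for real numbers, False for sentinels, None, strings, bools."""
    return isinstance(x, (int, float)) and not isinstance(x, bool)
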