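"""Scalar value-with-uncertainty arithmetic.

``UFloat`` carries a nominal value and a one-standard-deviation uncertainty
and propagates the latter to first order through ``+ - * /`` under the
assumption that the operands are statistically independent. That assumption
holds for the way rates are assembled here: every uncertain factor (counts,
substrate pool, dry mass, carbon content, spike activity) is measured
independently. Correlated inputs are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class UFloat:
    """A value ± one standard deviation."""

    value: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"standard deviation must be >= 0, got {self.sd}")

    # -- arithmetic (first-order, independent operands) ------------------

    def __add__(self, other: "UFloat | float") -> "UFloat":
        o = as_ufloat(other)
        return UFloat(self.value + o.value, math.hypot(self.sd, o.sd))

    __radd__ = __add__

    def __sub__(self, other: "UFloat | float") -> "UFloat":
        o = as_ufloat(other)
        return UFloat(self.value - o.value, math.hypot(self.sd, o.sd))

    def __rsub__(self, other: "UFloat | float") -> "UFloat":
        return as_ufloat(other) - self

    def __mul__(self, other: "UFloat | float") -> "UFloat":
        o = as_ufloat(other)
        sd = math.hypot(self.value * o.sd, o.value * self.sd)
        return UFloat(self.value * o.value, sd)

    __rmul__ = __mul__

    def __truediv__(self, other: "UFloat | float") -> "UFloat":
        o = as_ufloat(other)
        if o.value == 0:
            raise ZeroDivisionError("division by a zero-valued UFloat")
        v = self.value / o.value
        sd = abs(v) * _rel_hypot(self, o) if self.value != 0 else self.sd / abs(o.value)
        return UFloat(v, sd)

    def __rtruediv__(self, other: "UFloat | float") -> "UFloat":
        return as_ufloat(other) / self

    def __neg__(self) -> "UFloat":
        return UFloat(-self.value, self.sd)

    def __abs__(self) -> "UFloat":
        return UFloat(abs(self.value), self.sd)

    def __float__(self) -> float:
        return float(self.value)

    @property
    def relative_sd(self) -> float:
        return self.sd / abs(self.value)


def as_ufloat(x: "UFloat | float | int | tuple[float, float]") -> UFloat:
    """Coerce a float, ``(value, sd)`` pair or UFloat to UFloat."""
    if isinstance(x, UFloat):
        return x
    if isinstance(x, tuple):
        return UFloat(*x)
    return UFloat(float(x))


def _rel_hypot(a: UFloat, b: UFloat) -> float:
    return math.hypot(a.sd / a.value, b.sd / b.value)
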