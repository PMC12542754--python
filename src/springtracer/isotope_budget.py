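"""Derived isotope and elemental quantities of mat biomass.

Two small derivations accompany the water chemistry: the apparent carbon
isotope fractionation between mat biomass and dissolved inorganic carbon,
Delta13C = d13C_mat - d13C_DIC (the plain delta difference, not the exact
epsilon = 1000(alpha - 1), because that is how the field tables are built),
and the molar C:N ratio of the mat from its weight-percent carbon and
nitrogen. Errors are combined in quadrature. d15N is carried through
unchanged — no derived quantity uses it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import ComputationError, UsageError
from .uncertainty import UFloat, as_ufloat

MOLAR_MASS_C = 12.011
MOLAR_MASS_N = 14.007


@dataclass(frozen=True)
class IsotopeTable:
    """Isotopic and elemental measurements for one site/year."""

    d13C_mat: Optional[UFloat] = None   # ‰ vs VPDB
    d13C_DIC: Optional[UFloat] = None   # ‰ vs VPDB
    d13C_DOC: Optional[UFloat] = None   # ‰ vs VPDB
    wt_pct_C: Optional[UFloat] = None   # % of dry mass
    wt_pct_N: Optional[UFloat] = None   # % of dry mass
    d15N_mat: Optional[UFloat] = None   # ‰ vs air; carried, never transformed


def capital_delta_13C(d13C_mat: UFloat | float | tuple,
                      d13C_DIC: UFloat | float | tuple) -> UFloat:
    """Delta13C = d13C_mat - d13C_DIC, errors in quadrature (‰)."""
    if d13C_mat is None or d13C_DIC is None:
        raise UsageError("both d13C_mat and d13C_DIC are required")
    return as_ufloat(d13C_mat) - as_ufloat(d13C_DIC)


def cn_molar_ratio(wt_pct_C: UFloat | float | tuple,
                   wt_pct_N: UFloat | float | tuple) -> UFloat:
    """Molar C:N from weight-percent C and N, relative errors in quadrature."""
    c = as_ufloat(wt_pct_C)
    n = as_ufloat(wt_pct_N)
    if n.value == 0:
        raise ComputationError("wt% N must be non-zero for a C:N ratio")
    return (c / MOLAR_MASS_C) / (n / MOLAR_MASS_N)


def derive(table: IsotopeTable) -> dict[str, UFloat]:
    """All derivable quantities present in the table."""
    out: dict[str, UFloat] = {}
    if table.d13C_mat is not None and table.d13C_DIC is not None:
        out["Delta13C_permil"] = capital_delta_13C(table.d13C_mat, table.d13C_DIC)
    if table.wt_pct_C is not None and table.wt_pct_N is not None:
        out["CN_molar"] = cn_molar_ratio(table.wt_pct_C, table.wt_pct_N)
    if table.d15N_mat is not None:
        out["d15N_mat_permil"] = table.d15N_mat
    return out


def format_with_error(u: UFloat, decimals: int = 1) -> str:
    """Table-style presentation: error to its leading significant figure,
    value to the matching decimal place (at least ``decimals``).

    Rounding happens only here, at presentation; stored values are never
    rounded.
    """
    if u.sd == 0:
        return f"{u.value:.{decimals}f}"
    err_decimals = max(-math.floor(math.log10(u.sd)), decimals, 0)
    return f"{u.value:.{err_decimals}f} ± {u.sd:.{err_decimals}f}"
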