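"""Redfield-stoichiometry coupling of methane formation to carbon fixation.

Methylphosphonate demethylation by the C-P lyase liberates methane and
phosphate 1:1, so a measured net methane-formation rate doubles as a
maximum phosphate-liberation rate.  Dividing measured carbon fixation by
the Redfield C:P ratio (106) gives the phosphate demand of primary
production; the ratio of supply to demand expresses how much of that
demand phosphonate catabolism could sustain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "REDFIELD_C_TO_P",
    "CouplingResult",
    "redfield_pi_demand",
    "percent_support",
    "support_distribution",
]

#: Canonical Redfield carbon : phosphorus ratio of marine plankton.
REDFIELD_C_TO_P = 106.0


class UndefinedSupportError(ZeroDivisionError):
    """Percent support is undefined for zero phosphate demand."""


@dataclass(frozen=True)
class CouplingResult:
    """Phosphate demand vs phosphonate-derived supply, both nmol P L-1 d-1.

    ``percent_support`` is unclamped and may exceed 100 when methane
    formation liberates more phosphate than primary production consumes.
    """

    pi_demand: float
    pi_supply: float
    percent_support: float
    redfield_c_to_p: float = REDFIELD_C_TO_P


def redfield_pi_demand(cfix_rate: float,
                       c_to_p: float = REDFIELD_C_TO_P) -> float:
    """Phosphate demand of a carbon-fixation rate, nmol P L-1 d-1.

    demand = cfix_rate / c_to_p, with cfix_rate in nmol C L-1 d-1.
    """
    if c_to_p <= 0:
        raise ValueError("C:P ratio must be positive")
    if cfix_rate < 0:
        raise ValueError("carbon-fixation rate must be >= 0")
    return cfix_rate / c_to_p


def percent_support(ch4_rate: float, pi_demand: float) -> float:
    """Percent of the phosphate demand met at 1:1 CH4:Pi stoichiometry."""
    if pi_demand <= 0:
        raise UndefinedSupportError("phosphate demand must be positive")
    return 100.0 * ch4_rate / pi_demand


def couple(ch4_rate: float, cfix_rate: float,
           c_to_p: float = REDFIELD_C_TO_P) -> CouplingResult:
    demand = redfield_pi_demand(cfix_rate, c_to_p)
    return CouplingResult(pi_demand=demand, pi_supply=ch4_rate,
                          percent_support=percent_support(ch4_rate, demand),
                          redfield_c_to_p=c_to_p)


def support_distribution(ch4_rates: Sequence[float], cfix_rate: float,
                         c_to_p: float = REDFIELD_C_TO_P) -> dict:
    """Order statistics of percent support over a set of methane rates.

    Returns min, Q1, median, Q3 and max of the elementwise percent support
    (quartiles by linear interpolation, i.e. numpy's default type-7;
    median by the midpoint-of-middle-two convention, which type-7 implies).
    """
    rates = np.asarray(ch4_rates, float)
    if rates.size == 0:
        raise ValueError("need at least one methane rate")
    demand = redfield_pi_demand(cfix_rate, c_to_p)
    pct = 100.0 * rates / demand
    return {
        "min": float(pct.min()),
        "q1": float(np.percentile(pct, 25)),
        "median": float(np.median(pct)),
        "q3": float(np.percentile(pct, 75)),
        "max": float(pct.max()),
        "n": int(pct.size),
    }


__all__.append("couple")
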