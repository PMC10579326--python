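"""Nutrient bookkeeping: detection limits, phosphorus pools, N:P ratios
and fluorescence-to-chlorophyll calibration.

Concentrations below the analytical limit of detection are represented by
:class:`Censored`, which records the LOD the value was tested against.
Arithmetic on a censored operand always yields a censored result — a
below-LOD phosphate never silently becomes LOD/2 in a ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Censored",
    "NutrientSample",
    "InsufficientBlanksError",
    "CannotDeriveError",
    "SingularFitError",
    "is_censored",
    "limit_of_detection",
    "derive_phosphorus_pools",
    "nitrate_from_nox",
    "n_to_p_ratio",
    "calibrate_fluorescence",
    "DEFAULT_LODS",
]

#: Default limits of detection, nmol L-1 (colorimetric/fluorometric methods).
DEFAULT_LODS = {"Pi": 10.0, "NH4": 24.0, "NOx": 583.0, "NO2": 33.0}


class InsufficientBlanksError(ValueError):
    """Fewer than two blank measurements."""


class CannotDeriveError(ValueError):
    """A required pool (e.g. TP) is missing."""


class SingularFitError(ValueError):
    """Calibration regressor is degenerate (constant RFU)."""


@dataclass(frozen=True)
class Censored:
    """A concentration below its limit of detection."""

    lod: float

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<LOD {self.lod:g}>"


Conc = "float | Censored | None"


def is_censored(value) -> bool:
    return isinstance(value, Censored)


def _sub_floor0(a, b, lod_hint: float = 0.0):
    """a - b with censoring propagation; negatives floored at 0."""
    if a is None or b is None:
        return None
    if is_censored(a) or is_censored(b):
        lod = max((x.lod for x in (a, b) if is_censored(x)), default=lod_hint)
        return Censored(lod)
    return max(a - b, 0.0)


@dataclass(frozen=True)
class NutrientSample:
    """One station/depth row of the nutrient table.

    Dissolved pools in nmol L-1, particulate POC/PON in umol L-1.  Each
    field is a number, a :class:`Censored` marker, or None (not measured).
    ``flags`` collects bookkeeping notes such as pool inconsistencies.
    """

    depth_m: float
    nox: object = None
    no2: object = None
    nh4: object = None
    pi: object = None
    tp: object = None
    pop: object = None
    poc: object = None
    pon: object = None
    op: object = None
    dop: object = None
    flags: frozenset = frozenset()

    def with_flag(self, flag: str) -> "NutrientSample":
        return replace(self, flags=self.flags | {flag})


def limit_of_detection(blanks: Sequence[float]) -> float:
    """LOD = mean of the blanks plus three sample standard deviations."""
    blanks = np.asarray(blanks, float)
    if blanks.size < 2:
        raise InsufficientBlanksError("need at least two blanks")
    return float(blanks.mean() + 3.0 * blanks.std(ddof=1))


def derive_phosphorus_pools(sample: NutrientSample) -> NutrientSample:
    """Fill the organic-phosphorus pools: OP = TP - Pi, DOP = OP - POP.

    Negative differences (within-method inconsistencies) are floored at
    zero and flagged.  A censored Pi or POP censors the derived pool.
    """
    if sample.tp is None:
        raise CannotDeriveError("total phosphorus is required")
    flags = set(sample.flags)

    # treat censored Pi as a small unknown: OP inherits censoring only if
    # TP itself is censored; subtracting an unknown < LOD leaves OP known
    # to within that LOD, which we record as a flag rather than censoring.
    if is_censored(sample.tp):
        op = Censored(sample.tp.lod)
    elif is_censored(sample.pi):
        op = sample.tp  # Pi < LOD contributes at most its LOD
        flags.add("op_upper_bound_pi_censored")
    else:
        op = sample.tp - sample.pi
        if op < 0:
            op = 0.0
            flags.add("tp_lt_pi_inconsistent")

    dop = None
    if sample.pop is not None and op is not None:
        dop = _sub_floor0(op, sample.pop)
        if not is_censored(op) and not is_censored(sample.pop) \
                and op - sample.pop < 0:
            flags.add("pop_gt_op_inconsistent")

    return replace(sample, op=op, dop=dop, flags=frozenset(flags))


def nitrate_from_nox(sample: NutrientSample):
    """NO3 = NOx - NO2, floored at zero, censoring propagated."""
    return _sub_floor0(sample.nox, sample.no2)


def n_to_p_ratio(sample: NutrientSample, lods: dict | None = None):
    """Inorganic N : P ratio, (NOx + NH4) / Pi.

    Returns :class:`Censored` (undefined) whenever phosphate — or the whole
    numerator — is below detection; no LOD/2 substitution is ever made.
    """
    if lods is None:
        lods = DEFAULT_LODS
    pi = sample.pi
    if pi is None or is_censored(pi) or pi < lods.get("Pi", 0.0) or pi == 0:
        return Censored(lods.get("Pi", 0.0))
    if is_censored(sample.nox) and is_censored(sample.nh4):
        return Censored(lods.get("NOx", 0.0))
    nox = 0.0 if is_censored(sample.nox) or sample.nox is None else sample.nox
    nh4 = 0.0 if is_censored(sample.nh4) or sample.nh4 is None else sample.nh4
    if is_censored(sample.nox) or is_censored(sample.nh4):
        # one censored term: the sum is only bounded, not known
        return Censored(max(lods.get("NOx", 0.0), lods.get("NH4", 0.0)))
    return (nox + nh4) / pi


def calibrate_fluorescence(pairs: Sequence[tuple]) -> tuple[float, float, float]:
    """OLS calibration of sensor fluorescence against extracted Chl a.

    ``pairs`` are (relative fluorescence units, chlorophyll a ug L-1).
    Returns (slope, intercept, R^2); applying ``slope * rfu + intercept``
    converts an RFU profile to ug L-1 Chl a.
    """
    pairs = np.asarray(pairs, float)
    if pairs.ndim != 2 or pairs.shape[0] < 2:
        raise ValueError("need at least two (RFU, chl) pairs")
    rfu, chl = pairs[:, 0], pairs[:, 1]
    if np.ptp(rfu) == 0:
        raise SingularFitError("constant RFU cannot be calibrated")
    res = stats.linregress(rfu, chl)
    r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else 1.0
    return float(res.slope), float(res.intercept), r2
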