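"""Methane-formation and carbon-fixation rate estimation.

Methane formation is quantified as the ordinary-least-squares slope of the
excess 13C-CH4 series over the first four time points (0-24 h).  A rate is
accepted only if a one-sided t-test on the slope (H1: slope > 0, df = n-2)
gives p <= 0.05 *and* the fit has R^2 > 0.81; accepted slopes are divided by
the labelling fraction of the tracer pool (1.0 for methylphosphonate
amendments, ~0.1 for DIC amendments).  Series that are not significant but
show formation only at the last fitted time point are classed as
late-onset ("exponential") and their net rate is set to zero, as are plainly
insignificant ones.

Carbon fixation follows the standard 13C-DIC uptake formulation: the atom-%
enrichment of particulate organic carbon over the incubation, relative to
the labelling of the DIC pool, scaled by the POC standing stock.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .tracer import ExcessSeries

__all__ = [
    "RateResult",
    "CarbonFixationInput",
    "InsufficientDataError",
    "InvalidLabellingError",
    "fit_linear_rate",
    "classify_and_finalize",
    "carbon_fixation_rate",
]

HOURS_PER_DAY = 24.0


class InsufficientDataError(ValueError):
    """Too few time points for the requested fit."""


class InvalidLabellingError(ValueError):
    """DIC labelling does not exceed the initial biomass enrichment."""


@dataclass(frozen=True)
class RateResult:
    """OLS slope with its significance test and kinetic classification.

    ``slope`` and ``net_rate`` are in nmol CH4 L-1 d-1.  ``net_rate`` is the
    labelling-corrected slope for linear_significant incubations and zero
    otherwise.
    """

    slope: float
    slope_se: float
    t_statistic: float
    p_one_sided: float
    r_squared: float
    df: int
    kinetic_class: str = "unclassified"
    net_rate: float = 0.0
    labelling_corrected: bool = False


@dataclass(frozen=True)
class CarbonFixationInput:
    """End-point 13C-POC enrichment data for one carbon-fixation bottle."""

    poc_concentration: float     # umol C L-1 at the end point
    atom_pct_poc_t0: float       # at% 13C of POC at t0
    atom_pct_poc_tf: float       # at% 13C of POC at the end point
    atom_pct_dic: float          # at% 13C of the labelled DIC pool
    duration_d: float

    def __post_init__(self) -> None:
        if self.duration_d <= 0:
            raise ValueError("duration must be positive")
        if self.atom_pct_dic <= self.atom_pct_poc_t0:
            raise InvalidLabellingError(
                "DIC labelling must exceed the initial POC enrichment")


def fit_linear_rate(series: ExcessSeries, n_fit_points: int = 4) -> RateResult:
    """OLS fit of excess 13C-CH4 vs time over the first ``n_fit_points``.

    Returns the slope in nmol L-1 d-1 with its standard error, the one-sided
    t-test p-value for H1: slope > 0 at df = n_fit_points - 2, and R^2.
    The kinetic class is left ``"unclassified"``; see
    :func:`classify_and_finalize`.
    """
    if len(series.times_h) < n_fit_points:
        raise InsufficientDataError(
            f"need {n_fit_points} points, have {len(series.times_h)}")
    t = series.times_h[:n_fit_points]
    y = series.excess_nmol_per_l[:n_fit_points]
    df = n_fit_points - 2

    res = stats.linregress(t, y)
    slope_h, se_h = res.slope, res.stderr
    if se_h > 0:
        t_stat = slope_h / se_h
        p_one = float(stats.t.sf(t_stat, df))
    else:
        # degenerate: exactly collinear (p -> 0 if rising) or constant
        t_stat = np.inf if slope_h > 0 else (-np.inf if slope_h < 0 else 0.0)
        p_one = 0.0 if slope_h > 0 else 1.0
    r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else 0.0

    return RateResult(
        slope=slope_h * HOURS_PER_DAY,
        slope_se=se_h * HOURS_PER_DAY,
        t_statistic=float(t_stat),
        p_one_sided=p_one,
        r_squared=r2,
        df=df,
    )


def classify_and_finalize(raw: RateResult, series: ExcessSeries,
                          labelling_fraction: float | None = None,
                          p_max: float = 0.05, r2_min: float = 0.81,
                          exp_ratio: float = 3.0,
                          detection_sd: float = 0.0,
                          n_fit_points: int = 4) -> RateResult:
    """Apply the significance filter, the late-onset rule and corrections.

    linear_significant  iff p <= p_max and R^2 > r2_min (strict); then
        net_rate = slope / labelling_fraction.
    exponential  iff not significant, the last fitted point is positive, and
        it exceeds ``exp_ratio`` times the larger of ``detection_sd`` and the
        intermediate points (formation essentially only at the last point);
        net_rate = 0.
    insignificant  otherwise; net_rate = 0.

    Negative slopes can never be significant under the one-sided test, so
    consumption is never reported.
    """
    if labelling_fraction is None:
        labelling_fraction = series.labelling_fraction
    y = series.excess_nmol_per_l[:n_fit_points]

    if raw.p_one_sided <= p_max and raw.r_squared > r2_min and raw.slope > 0:
        return replace(raw, kinetic_class="linear_significant",
                       net_rate=raw.slope / labelling_fraction,
                       labelling_corrected=True)

    last = y[-1]
    floor = max(detection_sd, float(np.max(y[1:-1], initial=0.0)))
    if last > 0 and last > exp_ratio * floor:
        return replace(raw, kinetic_class="exponential", net_rate=0.0,
                       labelling_corrected=True)
    return replace(raw, kinetic_class="insignificant", net_rate=0.0,
                   labelling_corrected=True)


def carbon_fixation_rate(inp: CarbonFixationInput) -> float:
    """Carbon fixation from 13C-DIC uptake into biomass, umol C L-1 d-1.

    rate = (A_POC(t) - A_POC(0)) / (A_DIC - A_POC(0)) * [POC] / dt.

    A negative result (isotopic depletion, within measurement error of zero
    uptake) is returned as-is with a warning.
    """
    uptake = (inp.atom_pct_poc_tf - inp.atom_pct_poc_t0) \
        / (inp.atom_pct_dic - inp.atom_pct_poc_t0)
    rate = uptake * inp.poc_concentration / inp.duration_d
    if rate < 0:
        warnings.warn("negative carbon-fixation rate; treating as noise "
                      "around zero uptake", stacklevel=2)
    return rate
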