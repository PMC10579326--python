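"""Closed-vessel tracer mass balance for serially subsampled incubations.

A seawater incubation bottle is filled headspace-free, a headspace of
synthetic air is set, and a ``13C``-labelled substrate is added.  At each
sampling time a fixed aliquot of the headspace is withdrawn (and replaced
with tracer-free synthetic air), so every sampling event removes a known
fraction of the methane present in the vessel.  This module converts the raw
headspace measurements (CH4 amount and 13C atom fraction) into the excess
13C-CH4 inventory of the whole vessel, per litre of incubated water,
corrected for those serial-subsampling losses.

The vessel is treated as fully equilibrated at each sampling instant:
a dimensionless partition coefficient ``K_H`` (dissolved / gas-phase
concentration at equilibrium) fixes the fraction of total methane residing
in the headspace,

    f_g = V_g / (V_g + K_H * V_l).

Each subsampling event therefore removes the fraction
``phi = (v_s / V_g) * f_g`` of the vessel's methane inventory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "R_VPDB",
    "NATURAL_ATOM_FRACTION_13C",
    "VesselGeometry",
    "IsotopeMeasurement",
    "IncubationRecord",
    "ExcessSeries",
    "InvalidGeometryError",
    "MalformedSeriesError",
    "MissingBaselineError",
    "delta13c_to_atom_fraction",
    "atom_fraction_to_delta13c",
    "headspace_fraction",
    "dilution_correction_factors",
    "excess_13c_series",
    "ppm_to_nmol",
]

#: 13C/12C isotope ratio of the VPDB standard.
R_VPDB = 0.0111802

#: Natural-abundance 13C atom fraction, R_VPDB / (1 + R_VPDB).
NATURAL_ATOM_FRACTION_13C = R_VPDB / (1.0 + R_VPDB)

#: Ideal gas constant, J mol-1 K-1.
_R_GAS = 8.31446261815324

#: Standard atmosphere, Pa.
_P_ATM = 101325.0


class InvalidGeometryError(ValueError):
    """Vessel geometry violates a physical constraint."""


class MalformedSeriesError(ValueError):
    """Measurement times are not strictly increasing."""


class MissingBaselineError(ValueError):
    """The series lacks a t = 0 baseline measurement."""


def delta13c_to_atom_fraction(delta_permil: float) -> float:
    """Convert a d13C value (permil vs VPDB) to a 13C atom fraction.

    x13 = R / (1 + R) with R = (delta/1000 + 1) * R_VPDB.
    """
    r = (delta_permil / 1000.0 + 1.0) * R_VPDB
    return r / (1.0 + r)


def atom_fraction_to_delta13c(atom_fraction: float) -> float:
    """Inverse of :func:`delta13c_to_atom_fraction`."""
    if not 0.0 <= atom_fraction < 1.0:
        raise ValueError("atom fraction must lie in [0, 1)")
    r = atom_fraction / (1.0 - atom_fraction)
    return (r / R_VPDB - 1.0) * 1000.0


def ppm_to_nmol(ppm: float, gas_volume_l: float, temperature_c: float,
                pressure_pa: float = _P_ATM) -> float:
    """Convert a mole fraction (ppm) in a gas volume to nmol, ideal gas."""
    mol = ppm * 1e-6 * pressure_pa * (gas_volume_l * 1e-3) / (
        _R_GAS * (temperature_c + 273.15))
    return mol * 1e9


@dataclass(frozen=True)
class VesselGeometry:
    """Geometry and partitioning constants of one incubation vessel.

    Parameters
    ----------
    liquid_volume : float
        Incubated water volume, L.
    headspace_volume : float
        Headspace volume, L.
    subsample_volume : float
        Gas volume withdrawn (and replaced) at each sampling event, L.
    temperature : float
        Incubation temperature, deg C.
    salinity : float
        Salinity, PSU (bookkeeping only).
    partition_coefficient : float
        Dimensionless K_H = dissolved / gas-phase concentration at
        equilibrium.  0 is the insoluble-gas limit.  Default 0.032
        (~25 deg C seawater).
    """

    liquid_volume: float
    headspace_volume: float
    subsample_volume: float
    temperature: float = 25.0
    salinity: float = 35.0
    partition_coefficient: float = 0.032

    def __post_init__(self) -> None:
        if self.liquid_volume <= 0 or self.headspace_volume <= 0 \
                or self.subsample_volume <= 0:
            raise InvalidGeometryError("all volumes must be positive")
        if self.subsample_volume >= self.headspace_volume:
            raise InvalidGeometryError(
                "subsample volume must be smaller than the headspace")
        if self.partition_coefficient < 0:
            raise InvalidGeometryError("partition coefficient must be >= 0")


@dataclass(frozen=True)
class IsotopeMeasurement:
    """One headspace measurement: time, CH4 amount, 13C atom fraction."""

    time_h: float
    ch4_headspace_nmol: float
    atom_fraction_13c: float

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError("time must be >= 0")
        if not 0.0 <= self.atom_fraction_13c <= 1.0:
            raise ValueError("atom fraction must lie in [0, 1]")
        if self.ch4_headspace_nmol < 0:
            raise ValueError("CH4 amount must be >= 0")


@dataclass(frozen=True)
class IncubationRecord:
    """One vessel's metadata, geometry, tracer and measurement series."""

    station: str
    depth_category: str
    treatment: str
    replicate: str
    geometry: VesselGeometry
    labelling_fraction: float
    measurements: tuple[IsotopeMeasurement, ...]

    def __post_init__(self) -> None:
        if not 0.0 < self.labelling_fraction <= 1.0:
            raise ValueError("labelling fraction must lie in (0, 1]")
        object.__setattr__(self, "measurements", tuple(self.measurements))
        times = [m.time_h for m in self.measurements]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise MalformedSeriesError("times must be strictly increasing")
        if times and times[0] != 0.0:
            raise MissingBaselineError("first measurement must be at t = 0")

    @property
    def times_h(self) -> np.ndarray:
        return np.array([m.time_h for m in self.measurements])


@dataclass(frozen=True)
class ExcessSeries:
    """Dilution-corrected excess 13C-CH4 per litre of incubated water."""

    times_h: np.ndarray
    excess_nmol_per_l: np.ndarray
    correction_factors: np.ndarray
    station: str = ""
    depth_category: str = ""
    treatment: str = ""
    replicate: str = ""
    labelling_fraction: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_h", np.asarray(self.times_h, float))
        object.__setattr__(self, "excess_nmol_per_l",
                           np.asarray(self.excess_nmol_per_l, float))
        object.__setattr__(self, "correction_factors",
                           np.asarray(self.correction_factors, float))
        n = len(self.times_h)
        if len(self.excess_nmol_per_l) != n or len(self.correction_factors) != n:
            raise ValueError("series arrays must share one length")


def headspace_fraction(geometry: VesselGeometry) -> float:
    """Fraction of the vessel's methane in the headspace at equilibrium.

    f_g = V_g / (V_g + K_H * V_l); f_g = 1 for an insoluble gas.
    """
    vg = geometry.headspace_volume
    return vg / (vg + geometry.partition_coefficient * geometry.liquid_volume)


def _event_loss_fraction(geometry: VesselGeometry) -> float:
    """Fraction of the vessel's methane removed by one subsampling event."""
    return (geometry.subsample_volume / geometry.headspace_volume) \
        * headspace_fraction(geometry)


def dilution_correction_factors(geometry: VesselGeometry,
                                n_timepoints: int) -> np.ndarray:
    """Multiplicative dilution-correction factors for serial subsampling.

    Each sampling event removes the fraction ``phi = (v_s/V_g) * f_g`` of a
    conserved methane pool; the measurement at (0-based) time point ``k``
    has experienced ``k`` prior events, so

        D_k = (1 - phi)^(-k),

    the multiplier that restores the amount present had no gas been
    withdrawn.  D_0 = 1 and the factors are non-decreasing.
    """
    if n_timepoints < 1:
        raise ValueError("need at least one time point")
    phi = _event_loss_fraction(geometry)
    return (1.0 - phi) ** -np.arange(n_timepoints, dtype=float)


def excess_13c_series(record: IncubationRecord,
                      method: str = "mass_balance") -> ExcessSeries:
    """Compute the dilution-corrected excess 13C-CH4 series of one vessel.

    The headspace excess at time point k is
    ``ch4_headspace_nmol * (x13(t_k) - x13(0))``; dividing by the headspace
    fraction ``f_g`` gives the whole-vessel excess M_k actually present.
    Subsampling losses are then restored by one of two corrections:

    ``"mass_balance"`` (default)
        Exact bookkeeping: the aliquot taken at event j removed
        ``phi * M_j``, so cumulative production is
        ``M_k + phi * sum_{j<k} M_j``.  Exact for any production history.

    ``"factor"``
        The conventional multiplier ``M_k * D_k`` with
        ``D_k = (1 - phi)^(-k)``.  Exact only for a pool entirely present
        before the first sampling; it over-corrects methane produced after
        earlier sampling events.

    Excess at t = 0 is identically zero (the bottle's own t0 atom fraction
    is the baseline).  Negative values are retained, not clamped, so that
    regression noise stays unbiased.  The result is expressed per litre of
    incubated water.
    """
    if len(record.measurements) < 2:
        raise MalformedSeriesError("need at least two measurements")
    if method not in ("mass_balance", "factor"):
        raise ValueError(f"unknown correction method: {method!r}")

    geometry = record.geometry
    f_g = headspace_fraction(geometry)
    phi = _event_loss_fraction(geometry)
    x0 = record.measurements[0].atom_fraction_13c

    # whole-vessel excess 13C-CH4 at each sampling instant, nmol
    vessel = np.array([
        m.ch4_headspace_nmol * (m.atom_fraction_13c - x0) / f_g
        for m in record.measurements
    ])
    factors = dilution_correction_factors(geometry, len(vessel))
    if method == "factor":
        corrected = vessel * factors
    else:
        removed = phi * np.concatenate([[0.0], np.cumsum(vessel)[:-1]])
        corrected = vessel + removed
    corrected[0] = 0.0

    return ExcessSeries(
        times_h=record.times_h,
        excess_nmol_per_l=corrected / geometry.liquid_volume,
        correction_factors=factors,
        station=record.station,
        depth_category=record.depth_category,
        treatment=record.treatment,
        replicate=record.replicate,
        labelling_fraction=record.labelling_fraction,
    )
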