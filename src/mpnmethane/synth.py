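"""Seeded forward simulators for every input the pipeline consumes.

Three generators with known ground truth:

* :func:`simulate_incubation` — a single closed-vessel tracer incubation,
  simulated event-by-event: excess 13C-CH4 accumulates between sampling
  instants (linearly, with a late onset, or not at all), partitions into
  the headspace by the equilibrium fraction f_g, and each sampling event
  removes the subsample's share of the vessel inventory before replacement
  with tracer-free air.  Measurement noise is applied in the excess domain.
* :func:`simulate_station_profiles` — a whole campaign: stations x depths x
  replicates of net rates drawn lognormally around depth medians (with a
  configurable share of incubations failing the significance filter and
  reported as zero), plus nutrient profiles whose phosphorus pool
  identities hold by construction and whose phosphate is censored above
  the deep chlorophyll maximum.
* :func:`simulate_count_table` — marker-gene read counts drawn
  multinomially from specified per-gene length-normalized rates, so the
  exact TPM and phnJ% answers are known in expectation.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tracer import (NATURAL_ATOM_FRACTION_13C, IncubationRecord,
                     IsotopeMeasurement, VesselGeometry, headspace_fraction)

__all__ = [
    "DEFAULT_GEOMETRY",
    "DEFAULT_SCHEDULE",
    "DEPTH_MEDIANS",
    "TREATMENT_MULTIPLIERS",
    "SimulationConfig",
    "SimulatedIncubation",
    "simulate_incubation",
    "simulate_station_profiles",
    "simulate_count_table",
]

#: 250 mL serum bottle filled headspace-free, then a 50 mL headspace set
#: and 5 mL exchanged at each sampling.
DEFAULT_GEOMETRY = VesselGeometry(
    liquid_volume=0.200, headspace_volume=0.050, subsample_volume=0.005,
    temperature=27.0, salinity=35.0, partition_coefficient=0.032)

#: Sampling times, hours since tracer addition.
DEFAULT_SCHEDULE = (0.0, 6.0, 12.0, 24.0, 48.0)

#: Median net methane-formation rate per depth, nmol CH4 L-1 d-1.
DEPTH_MEDIANS = {"surface": 0.40, "intermediate": 0.30,
                 "DCM": 0.07, "below_DCM": 0.06}

#: Treatment effect on the depth median: phosphate addition represses
#: methylphosphonate use, nitrate addition leaves it unchanged.
TREATMENT_MULTIPLIERS = {"MPn": 1.0, "MPn_Pi": 0.5, "MPn_NO3": 1.0}

#: Share of incubations failing the significance filter (reported as zero)
#: per depth: the deep quartile-1 rates of zero require >= 25% zeros there,
#: while the quantifiable surface quartile 1 caps the surface share.
DEPTH_ZERO_FRACTIONS = {"surface": 0.10, "intermediate": 0.10,
                        "DCM": 0.30, "below_DCM": 0.30}

DEPTH_METRES = {"surface": 10.0, "intermediate": 45.0,
                "DCM": 110.0, "below_DCM": 160.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the forward simulators; defaults emulate the study design."""

    seed: int = 0
    true_rate: float = 0.40            # nmol CH4 L-1 d-1 (excess-13C basis)
    noise_sd_excess: float = 0.05      # nmol L-1, per measured time point
    scenario: str = "linear"           # linear | exponential | null
    oxidation_k: float = 0.0           # d-1 first-order loss inside the vessel
    geometry: VesselGeometry = DEFAULT_GEOMETRY
    schedule: tuple = DEFAULT_SCHEDULE
    depth_medians: dict = field(default_factory=lambda: dict(DEPTH_MEDIANS))
    lognormal_sigma: float = 1.36      # log-scale spread of campaign rates
    #: scalar override for the per-depth zero-rate shares; None uses
    #: :data:`DEPTH_ZERO_FRACTIONS`
    zero_rate_fraction: float | None = None
    labelling_fraction: float = 1.0    # 1.0 for MPn, ~0.1 for DIC amendments
    tracer_atom_fraction: float = 0.99
    background_ch4_nmol: float = 5.0   # ambient CH4 in the vessel at t0
    exp_onset_h: float = 24.0          # late-onset scenario: first formation
    exp_growth: float = 4.0            # fold increase per day after onset
    n_stations: int = 12
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if self.noise_sd_excess < 0 or self.oxidation_k < 0:
            raise ValueError("noise and oxidation must be >= 0")
        if self.schedule[0] != 0:
            raise ValueError("schedule must start at t = 0")
        if self.scenario not in ("linear", "exponential", "null"):
            raise ValueError(f"unknown scenario {self.scenario!r}")


@dataclass(frozen=True)
class SimulatedIncubation:
    """A simulated vessel plus its ground truth for round-trip tests."""

    record: IncubationRecord
    #: excess 13C-CH4 inventory per litre had no gas been subsampled
    true_excess_nmol_per_l: np.ndarray
    #: excess 13C-CH4 withdrawn at each sampling event, nmol (vessel)
    removed_excess_nmol: np.ndarray
    #: vessel excess inventory at each measurement instant, nmol
    vessel_excess_nmol: np.ndarray
    true_rate: float


def _true_increment(config: SimulationConfig, t0: float, t1: float,
                    rate_vessel: float) -> float:
    """Excess-13C production (nmol, vessel) in the interval (t0, t1]."""
    if config.scenario == "null":
        return 0.0
    if config.scenario == "linear":
        return rate_vessel * (t1 - t0) / 24.0

    def level(t: float) -> float:
        if t < config.exp_onset_h:
            return 0.0
        return rate_vessel * config.exp_growth ** (
            (t - config.exp_onset_h) / 24.0)
    return level(t1) - level(t0)


def simulate_incubation(config: SimulationConfig,
                        station: str = "S1", depth_category: str = "surface",
                        treatment: str = "MPn", replicate: str = "a",
                        rng: np.random.Generator | None = None,
                        ) -> SimulatedIncubation:
    """Forward-simulate one incubation through the sampling protocol.

    The vessel state is advanced interval by interval; at each scheduled
    time the headspace is measured (CH4 amount and 13C atom fraction),
    then the subsample aliquot removes the fraction
    ``(v_s/V_g) * f_g`` of the vessel's methane, which is replaced with
    methane-free synthetic air.  Gaussian noise of ``noise_sd_excess``
    (nmol L-1) enters the measured atom fraction so that the reconstructed
    excess — not the raw signal — carries the specified error; the t0
    baseline is the reference point and stays noise-free.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g = config.geometry
    f_g = headspace_fraction(g)
    phi = (g.subsample_volume / g.headspace_volume) * f_g
    x0 = NATURAL_ATOM_FRACTION_13C
    xp = config.tracer_atom_fraction
    rate_vessel = config.true_rate * g.liquid_volume  # nmol per vessel per day

    decay = math.exp(-config.oxidation_k / 24.0)  # per hour factor base

    excess = 0.0          # vessel excess 13C-CH4, nmol
    excess_nosub = 0.0    # same, had no gas been subsampled
    total = config.background_ch4_nmol  # vessel total CH4, nmol
    removed = []
    vessel_at_meas = []
    true_per_l = []
    measurements = []
    t_prev = 0.0
    for k, t in enumerate(config.schedule):
        dt = t - t_prev
        d = decay ** dt
        gain = _true_increment(config, t_prev, t, rate_vessel)
        excess = excess * d + gain
        excess_nosub = excess_nosub * d + gain
        total = total * d + (gain / (xp - x0) if gain else 0.0)
        t_prev = t

        noise = rng.normal(0.0, config.noise_sd_excess) if (
            config.noise_sd_excess > 0 and k > 0) else 0.0
        atom_frac = x0 + (excess + noise * g.liquid_volume) / total
        atom_frac = min(max(atom_frac, 0.0), 1.0)
        measurements.append(IsotopeMeasurement(
            time_h=t, ch4_headspace_nmol=f_g * total,
            atom_fraction_13c=atom_frac))
        vessel_at_meas.append(excess)
        true_per_l.append(excess_nosub / g.liquid_volume)

        removed.append(phi * excess)
        excess *= (1.0 - phi)
        total *= (1.0 - phi)

    record = IncubationRecord(
        station=station, depth_category=depth_category, treatment=treatment,
        replicate=replicate, geometry=g,
        labelling_fraction=config.labelling_fraction,
        measurements=tuple(measurements))
    return SimulatedIncubation(
        record=record,
        true_excess_nmol_per_l=np.array(true_per_l),
        removed_excess_nmol=np.array(removed),
        vessel_excess_nmol=np.array(vessel_at_meas),
        true_rate=config.true_rate)


def _campaign_rate(rng: np.random.Generator, median: float,
                   sigma: float, zero_fraction: float) -> float:
    if zero_fraction > 0 and rng.uniform() < zero_fraction:
        return 0.0
    if sigma == 0:
        return median
    return float(rng.lognormal(mean=math.log(median), sigma=sigma))


def simulate_station_profiles(config: SimulationConfig
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a campaign's rate table and nutrient profiles.

    Returns ``(rates, nutrients)``.  ``rates`` has one row per
    station x depth x replicate x treatment (n_stations * 4 depths *
    n_replicates rows per treatment) with net rates drawn lognormally
    around the depth median (scaled per treatment), zero with probability
    ``zero_rate_fraction``.  ``nutrients`` has one row per station x depth
    with phosphorus pool identities (TP = Pi + POP + DOP) holding exactly;
    phosphate and inorganic nitrogen are below detection above and within
    the DCM (censored columns flag them), and quantifiable below it.
    """
    rng = np.random.default_rng(config.seed)
    depths = list(config.depth_medians)
    stations = [f"S{i + 1}" for i in range(config.n_stations)]
    reps = [chr(ord("a") + i) for i in range(config.n_replicates)]

    rate_rows = []
    for treatment, mult in TREATMENT_MULTIPLIERS.items():
        for station in stations:
            for depth in depths:
                median = config.depth_medians[depth] * mult
                zero_frac = (config.zero_rate_fraction
                             if config.zero_rate_fraction is not None
                             else DEPTH_ZERO_FRACTIONS.get(depth, 0.15))
                for rep in reps:
                    rate_rows.append((station, depth, treatment, rep,
                                      _campaign_rate(rng, median,
                                                     config.lognormal_sigma,
                                                     zero_frac)))
    rates = pd.DataFrame(rate_rows, columns=[
        "station", "depth_category", "treatment", "replicate", "net_rate"])

    nut_rows = []
    for station in stations:
        for depth in depths:
            below_dcm = depth == "below_DCM"
            pi_true = (rng.uniform(100.0, 400.0) if below_dcm
                       else rng.uniform(0.2, 8.0))
            pop = rng.uniform(5.0, 30.0)
            dop = rng.uniform(20.0, 153.0)
            op = pop + dop
            tp = op + pi_true
            nox_true = (20.0 * pi_true if below_dcm
                        else rng.uniform(10.0, 400.0))
            nh4_true = rng.uniform(1.0, 20.0)
            nut_rows.append({
                "station": station, "depth_category": depth,
                "depth_m": DEPTH_METRES.get(depth, np.nan),
                "Pi": pi_true, "Pi_censored": pi_true < 10.0,
                "TP": tp, "POP": pop, "DOP": dop, "OP": op,
                "NOx": nox_true, "NOx_censored": nox_true < 583.0,
                "NH4": nh4_true, "NH4_censored": nh4_true < 24.0,
                "POC": rng.uniform(2.0, 8.0), "PON": rng.uniform(0.3, 1.2),
            })
    nutrients = pd.DataFrame(nut_rows)
    return rates, nutrients


def simulate_count_table(config: SimulationConfig,
                         total_reads: int = 100_000,
                         gene_specs: pd.DataFrame | None = None,
                         phnj_percent: float = 14.71) -> pd.DataFrame:
    """Draw a marker-gene count table with a known normalization answer.

    ``gene_specs`` needs columns gene_id, orf_length, taxon, gene_family and
    rel_rate (length-normalized read rate).  By default a small community is
    built in which the summed phnJ rate is ``phnj_percent`` % of the recA
    rate, so the recA-normalized phnJ abundance converges to that value as
    sequencing depth grows.  Counts are multinomial with per-gene
    probability proportional to rel_rate * orf_length.
    """
    rng = np.random.default_rng(config.seed)
    if gene_specs is None:
        w = phnj_percent / 100.0
        gene_specs = pd.DataFrame([
            ("recA_c1", 1060, "Bacteria", "recA", 1.0),
            ("phnJ_tricho", 750, "Trichodesmium", "phnJ", 0.6 * w),
            ("phnJ_pelagibacter", 740, "Pelagibacterales", "phnJ", 0.3 * w),
            ("phnJ_sar116", 760, "SAR116", "phnJ", 0.1 * w),
            ("psbA_c1", 1080, "Cyanobacteria", "other", 0.8),
            ("amoA_c1", 820, "Thaumarchaeota", "other", 0.2),
        ], columns=["gene_id", "orf_length", "taxon", "gene_family",
                    "rel_rate"])
    weights = gene_specs["rel_rate"] * gene_specs["orf_length"]
    probs = weights / weights.sum()
    counts = rng.multinomial(total_reads, probs)
    out = gene_specs[["gene_id", "orf_length", "taxon", "gene_family"]].copy()
    out["read_count"] = counts
    return out[["gene_id", "orf_length", "read_count", "taxon", "gene_family"]]
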