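"""Volumetric conversion rates and gas-phase balances from raw time series.

Rates are computed per sampling interval on the constant-working-volume
(overflow) assumption Q_out = Q_feed + Q_base.  For species i the net
volumetric conversion rate in mCmol/L/d is

    r_i = (Cbar_i * Q_out - C_feed,i * Q_feed) / V  +  (C_i(t) - C_i(t_prev)) / dt

with Cbar_i the interval-mean (trapezoidal) broth concentration, flows
averaged over the interval, and the accumulation term from finite
differences.  Positive rates are production.  Each record is attached to the
interval's right endpoint.

CO2 is tracked in three streams: dosed gas in, off-gas out (headspace mole
fraction times measured outflow) and dissolved inorganic carbon leaving with
the effluent, computed from headspace pCO2 by Henry's law with optional
bicarbonate speciation.  Their difference is the CO2 utilization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compounds import CompoundRegistry, NormalConditions, default_registry
from .timeseries import FeedDefinition, ReactorTimeSeries, Sample

__all__ = [
    "CO2Equilibrium",
    "RatesRecord",
    "hydraulic_retention_time",
    "liquid_conversion_rates",
    "co2_utilization",
    "dissolved_co2_effluent",
    "h2_output",
    "compute_rates",
    "rates_frame",
]

MIN_PER_DAY = 1440.0


@dataclass(frozen=True)
class CO2Equilibrium:
    """Gas-liquid CO2 equilibrium constants (defaults for 35 degC).

    kh: Henry's constant, mol/L/atm.  pka1: first dissociation constant of
    carbonic acid (apparent).  speciation=False restricts dissolved carbon to
    free CO2(aq); True adds bicarbonate 1 + Ka1/[H+].
    """

    kh: float = 0.026
    pka1: float = 6.31
    total_pressure_atm: float = 1.0
    speciation: bool = True


@dataclass
class RatesRecord:
    """Per-interval volumetric rates; co2_utilization is in - out by identity."""

    t_prev: float
    t: float
    phase: str | None
    rates: dict[str, float]  # compound -> mCmol/L/d, positive = production
    h2_out: float  # mmol/L/d
    co2_in: float  # mCmol/L/d
    co2_out_gas: float  # mCmol/L/d
    co2_out_dissolved: float  # mCmol/L/d
    hrt: float  # h

    @property
    def co2_utilization(self) -> float:
        return self.co2_in - self.co2_out_gas - self.co2_out_dissolved


def hydraulic_retention_time(
    volume_l: float, feed_flow_ml_d: float, base_flow_ml_d: float = 0.0
) -> float:
    """HRT in hours for a constant-volume overflow reactor.

    HRT = V / (Q_feed + Q_base); base dosing shortens the HRT, which is why
    pH control load feeds back on residence time in these systems.
    """
    total = feed_flow_ml_d + base_flow_ml_d
    if total <= 0:
        raise ValueError("total liquid flow is zero; HRT undefined (batch mode)")
    return 24.0 * 1000.0 * volume_l / total


def liquid_conversion_rates(
    sample_prev: Sample,
    sample: Sample,
    feed: FeedDefinition,
    volume_l: float,
    include_accumulation: bool = True,
) -> dict[str, float]:
    """Net volumetric conversion rates (mCmol/L/d) over one interval.

    The base stream contributes flow but zero carbon.  Compounds present in
    either the broth or the feed are reported; unmeasured ones count as zero
    concentration.  ``include_accumulation=False`` gives the pure
    flow-through (pseudo-steady-state) estimate.
    """
    dt = sample.time - sample_prev.time
    if dt <= 0:
        raise ValueError(f"non-positive interval: {sample_prev.time} -> {sample.time}")
    q_feed = 0.5 * (sample_prev.feed_flow + sample.feed_flow) / 1000.0  # L/d
    q_base = 0.5 * (sample_prev.base_flow + sample.base_flow) / 1000.0
    q_out = q_feed + q_base
    names = set(sample.broth) | set(sample_prev.broth) | set(feed.composition)
    out: dict[str, float] = {}
    for name in names:
        c_prev = sample_prev.broth.get(name, 0.0)
        c_now = sample.broth.get(name, 0.0)
        c_feed = feed.composition.get(name, 0.0)
        c_bar = 0.5 * (c_prev + c_now)
        r = (c_bar * q_out - c_feed * q_feed) / volume_l
        if include_accumulation:
            r += (c_now - c_prev) / dt
        out[name] = r
    return out


def co2_utilization(
    co2_in: float, co2_out_gas: float, co2_out_dissolved: float
) -> float:
    """Dosed minus outgoing CO2 (all mCmol/L/d); positive = net consumption."""
    return co2_in - co2_out_gas - co2_out_dissolved


def dissolved_co2_effluent(
    pH: float,
    temperature: float,
    headspace_co2_fraction: float,
    effluent_flow_ml_d: float,
    volume_l: float,
    equilibrium: CO2Equilibrium | None = None,
) -> float:
    """Dissolved inorganic carbon leaving with the effluent, mCmol/L/d.

    DIC = KH * pCO2 * (1 + Ka1/[H+]) mol/L at gas-liquid equilibrium with the
    measured headspace, times the dilution rate Q_out/V.  The bicarbonate
    term is dropped when ``equilibrium.speciation`` is False.  ``temperature``
    is carried for interface completeness; the constants themselves are
    supplied (defaults documented for 35 degC).
    """
    eq = equilibrium or CO2Equilibrium()
    if not 0.0 <= headspace_co2_fraction <= 1.0:
        raise ValueError(f"headspace CO2 fraction {headspace_co2_fraction} outside [0, 1]")
    if not math.isnan(pH) and not 3.0 <= pH <= 9.0:
        warnings.warn(f"pH {pH} outside [3, 9]; carbonate model validity doubtful")
    p_co2 = headspace_co2_fraction * eq.total_pressure_atm
    dic_mol_l = eq.kh * p_co2
    if eq.speciation and not math.isnan(pH):
        dic_mol_l *= 1.0 + 10.0 ** (pH - eq.pka1)
    dilution = effluent_flow_ml_d / 1000.0 / volume_l  # 1/d
    return dic_mol_l * 1000.0 * dilution  # mCmol/L/d


def h2_output(
    gas_out_flow_nml_min: float,
    headspace_h2_fraction: float,
    volume_l: float,
    conditions: NormalConditions | None = None,
) -> float:
    """Volumetric H2 export in mmol/L/d from off-gas flow and composition."""
    if gas_out_flow_nml_min < 0 or headspace_h2_fraction < 0:
        raise ValueError("gas flow and headspace fraction must be >= 0")
    vm = (conditions or NormalConditions()).molar_volume
    return gas_out_flow_nml_min * headspace_h2_fraction * MIN_PER_DAY / vm / volume_l


def _gas_species_out(
    s: Sample, species: str, volume_l: float, vm: float
) -> float:
    """mmol/L/d of one species leaving in the off-gas at sample s."""
    frac = s.headspace.get(species, 0.0)
    return s.gas_out_flow * frac * MIN_PER_DAY / vm / volume_l


def compute_rates(
    ts: ReactorTimeSeries,
    feed: FeedDefinition,
    registry: CompoundRegistry | None = None,
    equilibrium: CO2Equilibrium | None = None,
    conditions: NormalConditions | None = None,
    include_accumulation: bool = True,
) -> list[RatesRecord]:
    """One :class:`RatesRecord` per sampling interval of the series."""
    registry = registry or default_registry()
    eq = equilibrium or CO2Equilibrium()
    vm = (conditions or NormalConditions()).molar_volume
    records: list[RatesRecord] = []
    for prev, cur in zip(ts.samples, ts.samples[1:]):
        rates = liquid_conversion_rates(
            prev, cur, feed, ts.volume, include_accumulation=include_accumulation
        )
        q_feed = 0.5 * (prev.feed_flow + cur.feed_flow)
        q_base = 0.5 * (prev.base_flow + cur.base_flow)
        q_out = q_feed + q_base
        hrt = hydraulic_retention_time(ts.volume, q_feed, q_base)
        # interval means of endpoint gas terms (same trapezoid as the broth)
        co2_in = 0.5 * sum(
            s.gas_in.get("CO2", 0.0) * MIN_PER_DAY / vm for s in (prev, cur)
        )
        co2_out_gas = 0.5 * sum(
            _gas_species_out(s, "CO2", ts.volume, vm) for s in (prev, cur)
        )
        co2_diss = 0.5 * sum(
            dissolved_co2_effluent(
                s.pH,
                s.temperature,
                s.headspace.get("CO2", 0.0),
                q_out,
                ts.volume,
                eq,
            )
            for s in (prev, cur)
        )
        h2 = 0.5 * sum(_gas_species_out(s, "H2", ts.volume, vm) for s in (prev, cur))
        records.append(
            RatesRecord(
                t_prev=prev.time,
                t=cur.time,
                phase=cur.phase,
                rates=rates,
                h2_out=h2,
                co2_in=co2_in,
                co2_out_gas=co2_out_gas,
                co2_out_dissolved=co2_diss,
                hrt=hrt,
            )
        )
    return records


def rates_frame(records: list[RatesRecord]) -> pd.DataFrame:
    """Wide DataFrame, one row per interval; rate columns in mCmol/L/d."""
    rows = []
    for r in records:
        row = {
            "t_prev_d": r.t_prev,
            "t_d": r.t,
            "phase": r.phase,
            "hrt_h": r.hrt,
            "h2_out_mmol_L_d": r.h2_out,
            "co2_in_mCmol_L_d": r.co2_in,
            "co2_out_gas_mCmol_L_d": r.co2_out_gas,
            "co2_out_dissolved_mCmol_L_d": r.co2_out_dissolved,
            "co2_utilization_mCmol_L_d": r.co2_utilization,
        }
        for name, val in r.rates.items():
            row[f"r_{name}_mCmol_L_d"] = val
        rows.append(row)
    frame = pd.DataFrame(rows)
    rate_cols = sorted(c for c in frame.columns if c.startswith("r_"))
    other = [c for c in frame.columns if not c.startswith("r_")]
    return frame[other + rate_cols]
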