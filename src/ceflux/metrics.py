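"""Derived stoichiometric metrics: Cmol% selectivity, carbon and electron
balance closure, excessive ethanol oxidation (EEO), phase averages.

EEO background
--------------
In ethanol-based chain elongation by reverse beta-oxidation the elongating
organisms oxidize roughly one ethanol to acetate (releasing 2 H2) per five
2-carbon elongation steps, to generate ATP.  Ethanol consumed beyond the sum
of (i) ethanol condensed into elongation steps, (ii) ethanol spent reducing
carboxylates to their alcohols (carboxyl-hydroxyl exchange, 1 per mol alcohol
formed), and (iii) that expected 1-per-5 oxidation, is "excessive ethanol
oxidation" -- ethanol burned to acetate by non-elongating flanking organisms:

    EEO% = 100 * (E_cons - S - E_red - S/5) / E_cons        (mol ethanol basis)

with S the number of elongation steps inferred from the net product spectrum.
Negative values are legitimate and reported: they indicate the community
oxidized less ethanol than the 1-per-5 assumption predicts (or that the
underlying balance is slightly off).

Step counting is a strategy because the net rates do not uniquely identify
the acceptor of each elongation.  The default ("acceptor_routing") routes
net-consumed lower acids to the next chain length up at 1 step/mol before
attributing the remainder to acetate (2 steps for C6, etc.); the alternative
("from_acetate") charges every product its full from-acetate step count.
Alcohols count as their precursor acid for step accounting and additionally
book 1 ethanol each under reduction.  Branched acids count as isomerization
(0 steps) by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compounds import CompoundRegistry, default_registry
from .rates import RatesRecord
from .timeseries import FeedDefinition, ReactorTimeSeries

__all__ = [
    "EthanolAllocation",
    "product_selectivity",
    "carbon_balance",
    "electron_balance",
    "excessive_ethanol_oxidation",
    "compute_metrics",
    "phase_average",
]

#: Alcohols formed by carboxylate reduction, with their precursor acids.
ALCOHOL_PRECURSOR = {
    "n-propanol": "propionate",
    "n-butanol": "n-butyrate",
    "n-pentanol": "n-valerate",
    "n-hexanol": "n-caproate",
}

_EVEN_CHAIN = {4: "n-butyrate", 6: "n-caproate", 8: "n-caprylate"}
_ODD_CHAIN = {3: "propionate", 5: "n-valerate", 7: "n-heptanoate"}

#: The electron donor is never counted as a product.
DEFAULT_NON_PRODUCTS = ("ethanol",)

EXPECTED_OXIDATION_PER_STEP = 1.0 / 5.0


def product_selectivity(
    rates: dict[str, float],
    registry: CompoundRegistry | None = None,
    non_products: tuple[str, ...] = DEFAULT_NON_PRODUCTS,
) -> dict[str, float]:
    """Cmol% of each formed product among all formed products.

    ``rates`` are net volumetric rates in mCmol/L/d; only positive-rate
    liquid carbon compounds count as products, and net-consumed substrates
    (negative rates) as well as the donor are excluded.  Returns an empty
    dict with a warning when nothing is formed.
    """
    registry = registry or default_registry()
    products = {}
    for name, r in rates.items():
        if r <= 0 or name in non_products:
            continue
        c = registry[name]
        if c.carbon_number < 1 or c.phase_hint == "gas":
            continue
        products[name] = r
    total = sum(products.values())
    if total <= 0:
        warnings.warn("no net product formation; selectivity undefined")
        return {}
    return {name: 100.0 * r / total for name, r in products.items()}


def _mol_rates(
    rates: dict[str, float], registry: CompoundRegistry
) -> dict[str, float]:
    """mCmol/L/d -> mmol/L/d for carbon compounds."""
    out = {}
    for name, r in rates.items():
        c = registry[name]
        if c.carbon_number >= 1:
            out[name] = r / c.carbon_number
    return out


def _chain_steps(eff: dict[int, float], base: int) -> float:
    """Elongation steps for one homologous chain from net mol rates.

    ``eff`` maps chain length -> net rate (alcohols already folded into their
    precursor acid).  Net-consumed members act as acceptors for the next
    lengths up (1 step per 2 carbons gained); residual production is
    elongated all the way from the chain's base (acetate or propionate).
    """
    levels = sorted(eff)
    consumed = {n: max(0.0, -eff[n]) for n in levels}
    steps = 0.0
    for n in reversed(levels):
        p = max(0.0, eff[n])
        for m in [l for l in levels if l < n][::-1]:
            take = min(p, consumed[m])
            steps += take * (n - m) / 2.0
            consumed[m] -= take
            p -= take
        steps += p * (n - base) / 2.0
    return steps


def count_elongation_steps(
    mol_rates: dict[str, float], strategy: str = "acceptor_routing"
) -> float:
    """Elongation steps per litre per day inferred from net product rates."""
    if strategy not in ("acceptor_routing", "from_acetate"):
        raise ValueError(f"unknown step-counting strategy {strategy!r}")
    folded = dict(mol_rates)
    for alcohol, acid in ALCOHOL_PRECURSOR.items():
        folded[acid] = folded.get(acid, 0.0) + folded.get(alcohol, 0.0)
    steps = 0.0
    for chain, base in ((_EVEN_CHAIN, 2), (_ODD_CHAIN, 3)):
        eff = {n: folded.get(name, 0.0) for n, name in chain.items()}
        if strategy == "from_acetate":
            steps += sum(max(0.0, r) * (n - base) / 2.0 for n, r in eff.items())
        else:
            steps += _chain_steps(eff, base)
    return steps


@dataclass
class EthanolAllocation:
    """Where consumed ethanol went, mmol/L/d; components sum to total."""

    elongation: float
    expected_oxidation: float
    reduction_exchange: float
    excess: float

    @property
    def total(self) -> float:
        return (
            self.elongation
            + self.expected_oxidation
            + self.reduction_exchange
            + self.excess
        )

    @property
    def eeo_pct(self) -> float:
        return 100.0 * self.excess / self.total

    def as_cmol(self) -> dict[str, float]:
        """Allocation in mCmol/L/d (2 carbons per ethanol)."""
        return {
            "elongation": 2.0 * self.elongation,
            "expected_oxidation": 2.0 * self.expected_oxidation,
            "reduction_exchange": 2.0 * self.reduction_exchange,
            "excess": 2.0 * self.excess,
        }


def excessive_ethanol_oxidation(
    rates: dict[str, float],
    registry: CompoundRegistry | None = None,
    strategy: str = "acceptor_routing",
) -> EthanolAllocation | None:
    """EEO and the full ethanol allocation from net rates (mCmol/L/d).

    Returns None (with a warning) when ethanol is not net consumed; the
    statistic is undefined then.  ``allocation.eeo_pct`` is identical on a
    mol or Cmol basis since every term is ethanol.
    """
    registry = registry or default_registry()
    mol = _mol_rates(rates, registry)
    e_cons = -mol.get("ethanol", 0.0)
    if e_cons <= 0:
        warnings.warn("ethanol not net consumed; EEO undefined")
        return None
    steps = count_elongation_steps(mol, strategy=strategy)
    e_red = sum(max(0.0, mol.get(a, 0.0)) for a in ALCOHOL_PRECURSOR)
    e_exp = steps * EXPECTED_OXIDATION_PER_STEP
    excess = e_cons - steps - e_red - e_exp
    return EthanolAllocation(
        elongation=steps,
        expected_oxidation=e_exp,
        reduction_exchange=e_red,
        excess=excess,
    )


def _flow_terms(ts: ReactorTimeSeries, record: RatesRecord):
    by_time = {s.time: s for s in ts.samples}
    prev, cur = by_time[record.t_prev], by_time[record.t]
    q_feed = 0.5 * (prev.feed_flow + cur.feed_flow) / 1000.0  # L/d
    q_base = 0.5 * (prev.base_flow + cur.base_flow) / 1000.0
    return prev, cur, q_feed, q_feed + q_base


def carbon_balance(
    ts: ReactorTimeSeries,
    record: RatesRecord,
    feed: FeedDefinition,
    registry: CompoundRegistry | None = None,
    ch4_out: float = 0.0,
) -> float:
    """Carbon out / carbon in over one interval, in percent.

    In: feed organics + dosed CO2.  Out: effluent organics (interval-mean
    concentrations), off-gas + dissolved CO2, CH4, and the accumulation term
    d(broth carbon)/dt.  Yeast extract carbon is untracked by convention.
    """
    registry = registry or default_registry()
    prev, cur, q_feed, q_out = _flow_terms(ts, record)
    dt = record.t - record.t_prev
    c_in = record.co2_in + sum(
        v * q_feed / ts.volume for v in feed.composition.values()
    )
    if c_in <= 0:
        raise ValueError("no carbon enters the reactor; balance undefined")
    names = set(prev.broth) | set(cur.broth)
    effluent = accum = 0.0
    for name in names:
        if registry[name].carbon_number < 1:
            continue
        c_bar = 0.5 * (prev.broth.get(name, 0.0) + cur.broth.get(name, 0.0))
        effluent += c_bar * q_out / ts.volume
        accum += (cur.broth.get(name, 0.0) - prev.broth.get(name, 0.0)) / dt
    c_out = (
        effluent + record.co2_out_gas + record.co2_out_dissolved + ch4_out + accum
    )
    return 100.0 * c_out / c_in


def electron_balance(
    ts: ReactorTimeSeries,
    record: RatesRecord,
    feed: FeedDefinition,
    registry: CompoundRegistry | None = None,
    ch4_out: float = 0.0,
) -> float:
    """Electron-equivalent closure over one interval, in percent.

    Electron equivalents are gamma per Cmol for carbon compounds and 2 per
    mol H2; dosed CO2 carries none, so H2 and CH4 export show up directly as
    electron sinks.
    """
    registry = registry or default_registry()
    prev, cur, q_feed, q_out = _flow_terms(ts, record)
    dt = record.t - record.t_prev
    e_in = sum(
        v * registry[name].gamma * q_feed / ts.volume
        for name, v in feed.composition.items()
    )
    if e_in <= 0:
        raise ValueError("no electrons enter the reactor; balance undefined")
    names = set(prev.broth) | set(cur.broth)
    effluent = accum = 0.0
    for name in names:
        gamma = registry[name].gamma
        if gamma == 0.0:
            continue
        c_bar = 0.5 * (prev.broth.get(name, 0.0) + cur.broth.get(name, 0.0))
        effluent += c_bar * gamma * q_out / ts.volume
        accum += gamma * (cur.broth.get(name, 0.0) - prev.broth.get(name, 0.0)) / dt
    h2_electrons = record.h2_out * registry["H2"].electrons_per_mol
    ch4_electrons = ch4_out * registry["CH4"].gamma
    e_out = effluent + h2_electrons + ch4_electrons + accum
    return 100.0 * e_out / e_in


def compute_metrics(
    ts: ReactorTimeSeries,
    records: list[RatesRecord],
    feed: FeedDefinition,
    registry: CompoundRegistry | None = None,
    eeo_strategy: str = "acceptor_routing",
) -> pd.DataFrame:
    """Per-interval metrics table: selectivities, balances, EEO, allocation.

    Selectivity columns are ``sel_<compound>_cmolpct`` (NaN where a compound
    was not a product on that interval); allocation columns are mmol/L/d.
    """
    registry = registry or default_registry()
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "t_prev_d": rec.t_prev,
            "t_d": rec.t,
            "phase": rec.phase,
            "hrt_h": rec.hrt,
            "co2_utilization_mCmol_L_d": rec.co2_utilization,
            "h2_out_mmol_L_d": rec.h2_out,
            "carbon_balance_pct": carbon_balance(ts, rec, feed, registry),
            "electron_balance_pct": electron_balance(ts, rec, feed, registry),
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = product_selectivity(rec.rates, registry)
            alloc = excessive_ethanol_oxidation(
                rec.rates, registry, strategy=eeo_strategy
            )
        for name, pct in sel.items():
            row[f"sel_{name}_cmolpct"] = pct
        if alloc is None:
            row["eeo_pct"] = np.nan
        else:
            row["eeo_pct"] = alloc.eeo_pct
            row["ethanol_elongation_mmol_L_d"] = alloc.elongation
            row["ethanol_expected_oxidation_mmol_L_d"] = alloc.expected_oxidation
            row["ethanol_reduction_exchange_mmol_L_d"] = alloc.reduction_exchange
            row["ethanol_excess_mmol_L_d"] = alloc.excess
        rows.append(row)
    frame = pd.DataFrame(rows)
    sel_cols = sorted(c for c in frame.columns if c.startswith("sel_"))
    other = [c for c in frame.columns if not c.startswith("sel_")]
    return frame[other + sel_cols]


def phase_average(
    metrics: pd.DataFrame, phase: str, n_last: int = 5
) -> pd.Series:
    """Mean of the last ``n_last`` interval records of a phase.

    End-of-phase averaging describes the settled activity a phase converged
    to, rather than the transient after the set-point change.  With fewer
    than ``n_last`` records available, all records of the phase are used and
    a warning is issued.
    """
    sub = metrics[metrics["phase"] == phase].sort_values("t_d")
    if sub.empty:
        raise ValueError(f"no metrics records for phase {phase!r}")
    if len(sub) < n_last:
        warnings.warn(
            f"phase {phase!r} has only {len(sub)} records; averaging all of them"
        )
    tail = sub.tail(n_last)
    numeric = tail.select_dtypes(include=[np.number]).mean()
    numeric["phase"] = phase
    numeric["n_records"] = float(len(tail))
    return numeric
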