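"""Reactor time-series data model, tidy-CSV readers/writers, phase schedules.

The canonical concentration unit is mCmol/L (mMC): millimoles of carbon per
litre.  ``mg/L``, ``g/L``, ``mmol/L`` and ``mol/L`` are accepted on input and
converted through the compound registry; conversion is idempotent because the
canonical unit is written back out.

The on-disk layout is a tidy long CSV with columns

    reactor_id, time_d, section, species, value, unit

where ``section`` is one of ``broth`` (mCmol/L), ``gas_in`` (NmL/L/min),
``headspace`` (mole fraction), ``scalar`` (per-sample operating variables:
gas_out_flow NmL/min, feed_flow and base_flow mL/d, base_molarity mol/L, pH,
temperature degC) and ``constant`` (series-level values, currently the
working volume in L at time_d 0).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compounds import CompoundRegistry, default_registry

__all__ = [
    "Sample",
    "ReactorTimeSeries",
    "FeedDefinition",
    "PhaseDefinition",
    "read_timeseries",
    "write_timeseries",
    "assign_phases",
]

#: Maximum allowed sum of headspace mole fractions (measurement tolerance).
HEADSPACE_SUM_TOL = 1.02

_SCALAR_UNITS = {
    "gas_out_flow": "NmL/min",
    "feed_flow": "mL/d",
    "base_flow": "mL/d",
    "base_molarity": "mol/L",
    "pH": "-",
    "temperature": "degC",
}


@dataclass
class Sample:
    """One reactor check-up: broth, gas and operating measurements."""

    time: float  # days
    broth: dict[str, float] = field(default_factory=dict)  # compound -> mCmol/L
    gas_in: dict[str, float] = field(default_factory=dict)  # species -> NmL/L/min
    gas_out_flow: float = 0.0  # NmL/min
    headspace: dict[str, float] = field(default_factory=dict)  # mole fraction
    feed_flow: float = 0.0  # mL/d
    base_flow: float = 0.0  # mL/d
    base_molarity: float = float("nan")  # mol/L
    pH: float = float("nan")
    temperature: float = float("nan")  # degC
    phase: str | None = None


@dataclass
class ReactorTimeSeries:
    """Ordered samples for one reactor plus its working volume (L)."""

    reactor_id: str
    volume: float  # L, working volume including carrier
    samples: list[Sample] = field(default_factory=list)

    def validate(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"{self.reactor_id}: working volume must be > 0")
        times = [s.time for s in self.samples]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"{self.reactor_id}: sample times not strictly increasing")
        for s in self.samples:
            bad = [c for c, v in s.broth.items() if v < 0]
            if bad:
                raise ValueError(
                    f"{self.reactor_id} day {s.time}: negative concentration for "
                    + ", ".join(sorted(bad))
                )
            if s.headspace:
                if any(v < 0 for v in s.headspace.values()):
                    raise ValueError(
                        f"{self.reactor_id} day {s.time}: negative headspace fraction"
                    )
                total = sum(s.headspace.values())
                if total > HEADSPACE_SUM_TOL:
                    raise ValueError(
                        f"{self.reactor_id} day {s.time}: headspace fractions sum "
                        f"to {total:.3f} > {HEADSPACE_SUM_TOL}"
                    )

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.samples])

    def broth_frame(self) -> pd.DataFrame:
        """Wide DataFrame of broth concentrations (mCmol/L), index time_d."""
        rows = {s.time: s.broth for s in self.samples}
        return pd.DataFrame.from_dict(rows, orient="index").sort_index().fillna(0.0)

    def copy(self) -> "ReactorTimeSeries":
        return ReactorTimeSeries(
            reactor_id=self.reactor_id,
            volume=self.volume,
            samples=[
                replace(
                    s,
                    broth=dict(s.broth),
                    gas_in=dict(s.gas_in),
                    headspace=dict(s.headspace),
                )
                for s in self.samples
            ],
        )


@dataclass
class FeedDefinition:
    """Feed medium: carbon sources in mCmol/L plus untracked yeast extract."""

    composition: dict[str, float]  # compound -> mCmol/L
    yeast_extract_g_l: float = 0.0  # carbon-untracked by default

    def validate(self) -> None:
        bad = [c for c, v in self.composition.items() if v < 0]
        if bad:
            raise ValueError("negative feed concentration for " + ", ".join(bad))
        if self.yeast_extract_g_l < 0:
            raise ValueError("negative yeast extract")


@dataclass
class PhaseDefinition:
    """A named operating phase with gas-dosing set-points, [start, end) days."""

    name: str
    start_day: float
    end_day: float
    co2_load: float = 0.0  # NmL per L reactor per min
    n2_load: float = 0.0  # NmL per L reactor per min

    def __post_init__(self) -> None:
        if self.end_day <= self.start_day:
            raise ValueError(f"phase {self.name}: end_day must exceed start_day")
        if self.co2_load < 0 or self.n2_load < 0:
            raise ValueError(f"phase {self.name}: gas loads must be >= 0")

    def contains(self, t: float) -> bool:
        return self.start_day <= t < self.end_day


def validate_phases(phases: Sequence[PhaseDefinition]) -> None:
    if not phases:
        raise ValueError("empty phase list")
    for p1, p2 in zip(phases, phases[1:]):
        if p2.start_day < p1.end_day:
            raise ValueError(f"phases {p1.name} and {p2.name} overlap or are unordered")


def assign_phases(
    ts: ReactorTimeSeries, phases: Sequence[PhaseDefinition]
) -> ReactorTimeSeries:
    """Label every sample with its phase (half-open [start, end) intervals).

    A sample exactly on a boundary belongs to the later phase.  Raises if any
    sample time is not covered.
    """
    validate_phases(phases)
    out = ts.copy()
    for s in out.samples:
        hits = [p for p in phases if p.contains(s.time)]
        if not hits:
            raise ValueError(
                f"sample at day {s.time} not covered by any phase "
                f"(phases span [{phases[0].start_day}, {phases[-1].end_day}))"
            )
        s.phase = hits[0].name
    return out


def _convert_concentration(
    value: float, unit: str, compound: str, registry: CompoundRegistry
) -> float:
    """Convert a broth concentration to mCmol/L via the registry."""
    c = registry[compound]
    if unit in ("mCmol/L", "mCM", "mMC"):
        return value
    if c.carbon_number < 1:
        raise ValueError(f"cannot express carbon-free {compound!r} in mCmol/L")
    if unit == "mg/L":
        return value * c.carbon_number / c.molar_mass
    if unit == "g/L":
        return value * 1000.0 * c.carbon_number / c.molar_mass
    if unit in ("mmol/L", "mM"):
        return value * c.carbon_number
    if unit in ("mol/L", "M"):
        return value * 1000.0 * c.carbon_number
    raise ValueError(f"unparseable unit {unit!r} for {compound!r}")


def read_timeseries(
    path: str | Path | io.TextIOBase,
    registry: CompoundRegistry | None = None,
    aliases: Mapping[str, str] | None = None,
    default_base_molarity: float | None = None,
) -> ReactorTimeSeries:
    """Read a tidy long CSV into a validated, unit-normalized series.

    ``aliases`` maps nonstandard species labels to registry names, allowing a
    foreign column vocabulary to be adapted in configuration rather than code.
    ``default_base_molarity`` fills samples that omit base_molarity.
    """
    registry = registry or default_registry()
    aliases = {k.lower(): v for k, v in (aliases or {}).items()}
    table = pd.read_csv(path, float_precision="round_trip")
    required = {"reactor_id", "time_d", "section", "species", "value", "unit"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    reactors = table["reactor_id"].unique()
    if len(reactors) != 1:
        raise ValueError(f"expected exactly one reactor_id, found {list(reactors)}")

    def canon(species: str) -> str:
        key = species.strip().lower()
        if key in aliases:
            return aliases[key]
        return registry.resolve(species)

    const = table[table["section"] == "constant"]
    vol_rows = const[const["species"] == "working_volume"]
    if len(vol_rows) != 1:
        raise ValueError("expected exactly one constant/working_volume row")
    volume = float(vol_rows["value"].iloc[0])

    samples: dict[float, Sample] = {}
    for i, row in enumerate(
        table[table["section"] != "constant"].itertuples(index=False), start=2
    ):
        t = float(row.time_d)
        s = samples.setdefault(t, Sample(time=t))
        section, species = row.section, str(row.species)
        value = float(row.value)
        try:
            if section == "broth":
                s.broth[canon(species)] = _convert_concentration(
                    value, str(row.unit), canon(species), registry
                )
            elif section == "gas_in":
                s.gas_in[canon(species)] = value
            elif section == "headspace":
                frac = value / 100.0 if str(row.unit) == "%" else value
                s.headspace[canon(species)] = frac
            elif section == "scalar":
                if species not in _SCALAR_UNITS:
                    raise ValueError(f"unknown scalar {species!r}")
                setattr(s, species, value)
            else:
                raise ValueError(f"unknown section {section!r}")
        except (KeyError, ValueError) as err:
            raise ValueError(f"row {i} (day {t}, {section}/{species}): {err}") from err

    if default_base_molarity is not None:
        for s in samples.values():
            if np.isnan(s.base_molarity):
                s.base_molarity = default_base_molarity

    ts = ReactorTimeSeries(
        reactor_id=str(reactors[0]),
        volume=volume,
        samples=[samples[t] for t in sorted(samples)],
    )
    ts.validate()
    return ts


def write_timeseries(ts: ReactorTimeSeries, path: str | Path) -> None:
    """Write the tidy long CSV.  Full float precision; deterministic order."""
    rows: list[tuple] = [(ts.reactor_id, 0.0, "constant", "working_volume", ts.volume, "L")]
    for s in ts.samples:
        for name in sorted(s.broth):
            rows.append((ts.reactor_id, s.time, "broth", name, s.broth[name], "mCmol/L"))
        for name in sorted(s.gas_in):
            rows.append((ts.reactor_id, s.time, "gas_in", name, s.gas_in[name], "NmL/L/min"))
        for name in sorted(s.headspace):
            rows.append((ts.reactor_id, s.time, "headspace", name, s.headspace[name], "frac"))
        for name, unit in _SCALAR_UNITS.items():
            value = getattr(s, name)
            if not np.isnan(value):
                rows.append((ts.reactor_id, s.time, "scalar", name, value, unit))
    frame = pd.DataFrame(
        rows, columns=["reactor_id", "time_d", "section", "species", "value", "unit"]
    )
    # default str() formatting emits the shortest exact repr, so the
    # write/read round trip is lossless at full float precision
    frame.to_csv(path, index=False)
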