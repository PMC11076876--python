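"""Compound registry: elemental composition, degree of reduction, unit conversions.

All stoichiometric bookkeeping in this package runs through one registry of
species (C2-C8 carboxylic acids, C2-C6 primary alcohols, the fermentation
gases, water and an optional generic biomass).  Acids are carried in their
undissociated (protonated) form so that carbon and electron balances stay
charge-free; pH chemistry enters only through base-dosing flow bookkeeping
elsewhere.

Electron accounting convention
------------------------------
The registry exposes exactly one electron unit: *electron equivalents per
mol*, defined as gamma * n_C for carbon compounds, where gamma is the
generalized degree of reduction per carbon-mole,

    gamma = (4 n_C + n_H - 2 n_O - 3 n_N) / n_C .

H2 carries 2 electron equivalents per mol on the same scale (its combustion
electron content); CO2, H2O, N2 carry 0.  Under this convention the ethanol
oxidation EtOH + H2O -> acetate + 2 H2 is exactly electron neutral
(12 = 8 + 2*2), which anchors every electron balance downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import pandas as pd

__all__ = [
    "ATOMIC_MASS",
    "Compound",
    "CompoundRegistry",
    "NormalConditions",
    "degree_of_reduction",
    "cmol_rate_to_mass_rate",
    "mass_rate_to_cmol_rate",
    "gas_volume_to_moles",
    "default_registry",
]

# Standard atomic masses (IUPAC 2021 abridged), g/mol.
ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}

#: Electron equivalents per mol for carbon-free species on the gamma*n_C scale.
_CARBON_FREE_ELECTRONS = {"H2": 2.0, "N2": 0.0, "O2": 0.0, "H2O": 0.0}


def degree_of_reduction(n_C: float, n_H: float, n_O: float, n_N: float = 0.0) -> float:
    """Generalized degree of reduction per Cmol.

    gamma = (4 n_C + n_H - 2 n_O - 3 n_N) / n_C, with CO2, H2O and NH3 as the
    zero-electron references.  Undefined for carbon-free species; those carry
    dedicated constants in the registry (H2 = 2 electron equivalents / mol).

    Parameters
    ----------
    n_C, n_H, n_O, n_N:
        Atom counts of the (neutral, undissociated) molecule.

    Raises
    ------
    ValueError
        If ``n_C < 1``.
    """
    if n_C < 1:
        raise ValueError(
            "degree of reduction is per carbon-mole and needs n_C >= 1; "
            "carbon-free species use registry constants"
        )
    return (4.0 * n_C + n_H - 2.0 * n_O - 3.0 * n_N) / n_C


@dataclass(frozen=True)
class Compound:
    """One chemical species with elemental composition and derived quantities."""

    name: str
    n_C: int
    n_H: int
    n_O: int
    n_N: int = 0
    phase_hint: str = "liquid"  # liquid | gas | both
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if min(self.n_C, self.n_H, self.n_O, self.n_N) < 0:
            raise ValueError(f"{self.name}: negative atom count")
        if self.phase_hint not in ("liquid", "gas", "both"):
            raise ValueError(f"{self.name}: bad phase_hint {self.phase_hint!r}")

    @property
    def molar_mass(self) -> float:
        """g/mol from standard atomic masses."""
        return (
            self.n_C * ATOMIC_MASS["C"]
            + self.n_H * ATOMIC_MASS["H"]
            + self.n_O * ATOMIC_MASS["O"]
            + self.n_N * ATOMIC_MASS["N"]
        )

    @property
    def carbon_number(self) -> int:
        return self.n_C

    @property
    def gamma(self) -> float:
        """Degree of reduction per Cmol; 0.0 for carbon-free species."""
        if self.n_C == 0:
            return 0.0
        return degree_of_reduction(self.n_C, self.n_H, self.n_O, self.n_N)

    @property
    def electrons_per_mol(self) -> float:
        """Electron equivalents per mol on the gamma * n_C scale (H2 = 2)."""
        if self.n_C == 0:
            return _CARBON_FREE_ELECTRONS.get(self.name, 0.0)
        return self.gamma * self.n_C

    @property
    def atoms(self) -> dict[str, int]:
        return {"C": self.n_C, "H": self.n_H, "O": self.n_O, "N": self.n_N}


@dataclass(frozen=True)
class NormalConditions:
    """Reference state defining 'normal' gas volumes (NmL).

    Defaults to 273.15 K / 101.325 kPa, i.e. an ideal-gas molar volume of
    22.414 L/mol (22.414 NmL/mmol).
    """

    temperature_K: float = 273.15
    pressure_kPa: float = 101.325

    @property
    def molar_volume(self) -> float:
        """NmL per mmol (ideal gas)."""
        R = 8.31446  # J / mol / K
        return R * self.temperature_K / self.pressure_kPa  # L/mol == mL/mmol


#: Module-level default; 22.414 NmL/mmol to the precision used throughout.
STANDARD_CONDITIONS = NormalConditions()


def gas_volume_to_moles(
    volume_nml: float, conditions: NormalConditions | None = None
) -> float:
    """Convert a gas volume in NmL to mmol at the configured normal conditions.

    >>> round(gas_volume_to_moles(22.414), 3)
    1.0
    """
    if volume_nml < 0:
        raise ValueError(f"gas volume must be >= 0, got {volume_nml}")
    vm = (conditions or STANDARD_CONDITIONS).molar_volume
    return volume_nml / vm


def cmol_rate_to_mass_rate(rate_mcmol_l_d: float, compound: Compound) -> float:
    """Convert a volumetric rate from mCmol/L/d to mg/L/d.

    The reverse of :func:`mass_rate_to_cmol_rate`.  Rejects carbon-free
    species (a Cmol rate is meaningless for them).
    """
    if compound.carbon_number < 1:
        raise ValueError(f"{compound.name} carries no carbon; no Cmol rate exists")
    return rate_mcmol_l_d * compound.molar_mass / compound.carbon_number


def mass_rate_to_cmol_rate(rate_mg_l_d: float, compound: Compound) -> float:
    """Convert mg/L/d to mCmol/L/d."""
    if compound.carbon_number < 1:
        raise ValueError(f"{compound.name} carries no carbon; no Cmol rate exists")
    return rate_mg_l_d * compound.carbon_number / compound.molar_mass


class CompoundRegistry:
    """Name/synonym-addressable collection of :class:`Compound` objects."""

    def __init__(self, compounds: list[Compound]):
        self._by_name: dict[str, Compound] = {}
        self._alias: dict[str, str] = {}
        for c in compounds:
            self.add(c)

    def add(self, compound: Compound) -> None:
        if compound.name in self._by_name:
            raise ValueError(f"duplicate compound {compound.name!r}")
        self._by_name[compound.name] = compound
        self._alias[compound.name.lower()] = compound.name
        for syn in compound.synonyms:
            self._alias[syn.lower()] = compound.name

    def resolve(self, name: str) -> str:
        """Canonical name for ``name`` or any registered synonym."""
        key = name.strip().lower()
        if key not in self._alias:
            raise KeyError(f"unknown compound {name!r}")
        return self._alias[key]

    def __getitem__(self, name: str) -> Compound:
        return self._by_name[self.resolve(name)]

    def __contains__(self, name: str) -> bool:
        try:
            self.resolve(name)
        except KeyError:
            return False
        return True

    def __iter__(self) -> Iterator[Compound]:
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    @property
    def names(self) -> list[str]:
        return list(self._by_name)

    def reaction_element_imbalance(
        self, stoichiometry: Mapping[str, float]
    ) -> dict[str, float]:
        """Net atoms created by a reaction (should be 0 for C, H, O, N).

        ``stoichiometry`` maps compound name -> signed mol coefficient
        (products positive).
        """
        out = {el: 0.0 for el in ATOMIC_MASS}
        for name, coeff in stoichiometry.items():
            for el, n in self[name].atoms.items():
                out[el] += coeff * n
        return out

    def reaction_electron_imbalance(self, stoichiometry: Mapping[str, float]) -> float:
        """Net electron equivalents created by a reaction (0 if balanced)."""
        return sum(
            coeff * self[name].electrons_per_mol
            for name, coeff in stoichiometry.items()
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": c.name,
                "n_C": c.n_C,
                "n_H": c.n_H,
                "n_O": c.n_O,
                "n_N": c.n_N,
                "molar_mass": c.molar_mass,
                "gamma": c.gamma,
                "electrons_per_mol": c.electrons_per_mol,
                "phase_hint": c.phase_hint,
            }
            for c in self
        ]
        return pd.DataFrame(rows).set_index("name")


def _load_builtin_table() -> list[Compound]:
    with resources.files("ceflux.data").joinpath("compounds.csv").open() as fh:
        table = pd.read_csv(fh)
    compounds = []
    for row in table.itertuples(index=False):
        syn = () if pd.isna(row.synonyms) else tuple(str(row.synonyms).split(";"))
        compounds.append(
            Compound(
                name=row.name,
                n_C=int(row.n_C),
                n_H=int(row.n_H),
                n_O=int(row.n_O),
                n_N=int(row.n_N),
                phase_hint=row.phase_hint,
                synonyms=syn,
            )
        )
    return compounds


_DEFAULT: CompoundRegistry | None = None


def default_registry(include_biomass: bool = False) -> CompoundRegistry:
    """The built-in registry, loaded from the packaged CSV table.

    With ``include_biomass=True`` a generic biomass pseudo-species
    CH1.8O0.5N0.2 (gamma = 4.2) is appended; default balances exclude it.
    """
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = CompoundRegistry(_load_builtin_table())
    if not include_biomass:
        return _DEFAULT
    reg = CompoundRegistry(list(_DEFAULT))
    reg.add(biomass_compound())
    return reg


def biomass_compound(
    n_H: float = 1.8, n_O: float = 0.5, n_N: float = 0.2
) -> Compound:
    """Generic biomass CH1.8O0.5N0.2 per Cmol (gamma = 4.2 by default)."""
    c = Compound.__new__(Compound)
    object.__setattr__(c, "name", "biomass")
    object.__setattr__(c, "n_C", 1)
    object.__setattr__(c, "n_H", n_H)
    object.__setattr__(c, "n_O", n_O)
    object.__setattr__(c, "n_N", n_N)
    object.__setattr__(c, "phase_hint", "liquid")
    object.__setattr__(c, "synonyms", ("X",))
    return c


def validate_molar_masses(registry: CompoundRegistry, tol: float = 0.01) -> None:
    """Assert every molar mass matches its atom counts within ``tol`` g/mol."""
    for c in registry:
        expected = sum(ATOMIC_MASS[el] * n for el, n in c.atoms.items())
        if not math.isclose(c.molar_mass, expected, abs_tol=tol):
            raise AssertionError(f"{c.name}: molar mass drifted")
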