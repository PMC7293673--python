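"""Target compounds, molecular formulas, and mineralization stoichiometry.

A target compound is described by its molecular formula (C, H, N, O, S and
Na are supported), its molar mass, and its carbon count ``nc``, which seeds
the algorithmic generation of its degradation mechanism.

Complete mineralization by hydrogen peroxide is balanced as

    compound + x H2O2 -> nC CO2 + nN HNO3 + nS H2SO4 + nNa NaOH + w H2O

where ``x`` follows from the carbon/hydrogen/oxygen balance and the oxygen
balance is verified to close exactly.  Nitrogen leaves as nitrate (HNO3),
sulfur as sulfate and sodium as hydroxide.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "ATOMIC_MASSES",
    "Compound",
    "InvalidCompoundError",
    "StoichiometryError",
    "parse_formula",
    "formula_mass",
    "mineralization_stoichiometry",
    "stoichiometric_dose",
    "REGISTRY",
    "get_compound",
    "load_registry",
]

#: Standard atomic weights (g/mol) for the supported elements.
ATOMIC_MASSES: dict[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "Na": 22.98976928,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class InvalidCompoundError(ValueError):
    """Raised for formulas or carbon counts outside the supported domain."""


class StoichiometryError(ValueError):
    """Raised when the mineralization balance cannot be closed."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation formula string such as ``"C8H9NO2"``.

    Only C, H, N, O, S and Na are accepted; anything else raises
    :class:`InvalidCompoundError`.
    """
    if not formula or not formula.strip():
        raise InvalidCompoundError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula.strip()):
        if match.start() != pos:
            raise InvalidCompoundError(f"cannot parse formula {formula!r}")
        if not match.group(0):
            break
        pos = match.end()
        element, digits = match.group(1), match.group(2)
        if element not in ATOMIC_MASSES:
            raise InvalidCompoundError(
                f"unsupported element {element!r} in formula {formula!r}"
            )
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(formula.strip()):
        raise InvalidCompoundError(f"cannot parse formula {formula!r}")
    return counts


def formula_mass(formula: Mapping[str, int]) -> float:
    """Molar mass (g/mol) computed from a parsed formula."""
    return sum(ATOMIC_MASSES[el] * n for el, n in formula.items())


@dataclass(frozen=True)
class Compound:
    """A degradation target: formula, molar mass and carbon count.

    The carbon count ``nc`` drives the generated fragmentation cascade;
    the formula drives the mineralization stoichiometry.
    """

    name: str
    formula: Mapping[str, int]
    molar_mass: float

    def __post_init__(self) -> None:
        for el in self.formula:
            if el not in ATOMIC_MASSES:
                raise InvalidCompoundError(f"unsupported element {el!r}")
        if self.nc < 1:
            raise InvalidCompoundError(
                f"{self.name}: carbon count must be >= 1, got {self.nc}"
            )
        if self.molar_mass <= 0:
            raise InvalidCompoundError(f"{self.name}: molar mass must be positive")
        computed = formula_mass(self.formula)
        if abs(computed - self.molar_mass) > 0.5:
            raise InvalidCompoundError(
                f"{self.name}: molar mass {self.molar_mass} g/mol differs from "
                f"formula mass {computed:.3f} g/mol by more than 0.5"
            )

    @property
    def nc(self) -> int:
        """Number of carbon atoms."""
        return int(self.formula.get("C", 0))

    @classmethod
    def from_formula(
        cls, name: str, formula: str, molar_mass: float | None = None
    ) -> "Compound":
        parsed = parse_formula(formula)
        if molar_mass is None:
            molar_mass = formula_mass(parsed)
        return cls(name=name, formula=parsed, molar_mass=molar_mass)


def mineralization_stoichiometry(compound: Compound) -> float:
    """Moles of H2O2 needed per mole of compound for total mineralization.

    Balances ``compound + x H2O2 -> nC CO2 + nN HNO3 + nS H2SO4 +
    nNa NaOH + w H2O``.  Hydrogen fixes ``w``; carbon/H/O jointly fix
    ``x``; the oxygen balance is then re-checked independently and must
    close to machine precision.
    """
    f = compound.formula
    n_c = f.get("C", 0)
    n_h = f.get("H", 0)
    n_n = f.get("N", 0)
    n_o = f.get("O", 0)
    n_s = f.get("S", 0)
    n_na = f.get("Na", 0)
    x = (4 * n_c + 5 * n_n + 6 * n_s + n_na + n_h - 2 * n_o) / 2.0
    w = (n_h + 2 * x - n_n - 2 * n_s - n_na) / 2.0
    if x < 0 or w < 0:
        raise StoichiometryError(
            f"{compound.name}: mineralization balance has negative "
            f"coefficients (x={x}, w={w})"
        )
    # Independent oxygen closure check.
    o_lhs = n_o + 2 * x
    o_rhs = 2 * n_c + 3 * n_n + 4 * n_s + n_na + w
    if abs(o_lhs - o_rhs) > 1e-9:
        raise StoichiometryError(
            f"{compound.name}: oxygen balance does not close "
            f"({o_lhs} vs {o_rhs})"
        )
    return x


def stoichiometric_dose(compound: Compound, conc_mg_per_l: float) -> float:
    """Stoichiometric H2O2 dose (mmol/L) to mineralize ``conc_mg_per_l``.

    ``(conc / M) * x`` with ``x`` the mineralization coefficient; the
    mass concentration in mg/L divided by the molar mass in g/mol gives
    mmol/L directly.
    """
    if conc_mg_per_l <= 0:
        raise ValueError("concentration must be positive")
    return conc_mg_per_l / compound.molar_mass * mineralization_stoichiometry(compound)


#: Built-in registry of the three reference targets: paracetamol,
#: sulfaquinoxaline sodium salt and formic acid.
REGISTRY: dict[str, Compound] = {
    "PCT": Compound.from_formula("PCT", "C8H9NO2", 151.16),
    "SQX": Compound.from_formula("SQX", "C14H11N4NaO2S"),
    "FA": Compound.from_formula("FA", "CH2O2", 46.03),
}


def get_compound(name: str) -> Compound:
    try:
        return REGISTRY[name.upper()]
    except KeyError:
        raise InvalidCompoundError(
            f"unknown compound {name!r}; known: {sorted(REGISTRY)}"
        ) from None


def load_registry(path) -> dict[str, Compound]:
    """Load a compound registry from a YAML file.

    Expected layout::

        PCT: {formula: C8H9NO2, molar_mass: 151.16}
        FA:  {formula: CH2O2}
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    registry = {}
    for name, entry in raw.items():
        registry[name] = Compound.from_formula(
            name, entry["formula"], entry.get("molar_mass")
        )
    return registry
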