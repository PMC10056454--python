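"""Chemical species registry and degree-of-reduction arithmetic.

The common currency of the package is the *electron mole* (e-mol): the
number of electrons one mole of a compound transfers when it is fully
oxidised to CO2 and H2O (with NH3 as the nitrogen reference).  For a
species C_c H_h O_o N_n this is

    e per mol = 4c + h - 2o - 3n

so CO and H2 carry 2 e-mol/mol, acetic acid 8, ethanol 12, and CO2 zero
(its carbon is already fully oxidised).  Dividing by the carbon count
gives the degree of reduction (e-mol per C-mol), the quantity gas feeds
are matched against: acetate 4, butyrate 5, caproate 16/3, ethanol and
butanol 6.

N2, a filler gas, is flagged inert (e = 0) rather than evaluated by the
formula, which would give a meaningless -6.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import yaml

__all__ = [
    "ATOMIC_MASS",
    "Formula",
    "Compound",
    "CompoundRegistry",
    "UnknownCompoundError",
    "UnsupportedSpeciesError",
    "electrons_per_mole",
    "electrons_per_cmol",
    "to_millimoles",
    "to_concentration",
    "default_registry",
]

# IUPAC 2021 standard atomic weights, rounded to 3 decimals.
ATOMIC_MASS: dict[str, float] = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownCompoundError(KeyError):
    """A compound name is not present in the registry."""


class UnsupportedSpeciesError(ValueError):
    """A formula whose degree-of-reduction would be negative (and the
    species is not flagged inert)."""


@dataclass(frozen=True)
class Formula:
    """Element counts of a C/H/O/N species.

    Parameters
    ----------
    C, H, O, N
        Non-negative integer atom counts; at least one must be positive.
    """

    C: int = 0
    H: int = 0
    O: int = 0
    N: int = 0

    def __post_init__(self) -> None:
        for el in ("C", "H", "O", "N"):
            v = getattr(self, el)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"element count {el}={v!r} must be a non-negative integer")
        if self.C == self.H == self.O == self.N == 0:
            raise ValueError("formula must contain at least one atom")

    @classmethod
    def parse(cls, s: str) -> "Formula":
        """Parse a Hill-notation element-count string such as ``"C4H8O2"``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(s.strip()):
            if m.start() != pos or not m.group(0):
                break
            el, num = m.group(1), m.group(2)
            if el not in ATOMIC_MASS:
                raise ValueError(f"unsupported element {el!r} in formula {s!r}")
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
            pos = m.end()
        if pos != len(s.strip()) or not counts:
            raise ValueError(f"cannot parse formula {s!r}")
        return cls(**{el: counts.get(el, 0) for el in ("C", "H", "O", "N")})

    def __str__(self) -> str:
        out = []
        for el in ("C", "H", "N", "O") if self.C else ("H", "N", "O"):
            n = getattr(self, el)
            if n:
                out.append(el + (str(n) if n > 1 else ""))
        return "".join(out)

    @property
    def molar_mass(self) -> float:
        """Molar mass in g/mol."""
        return sum(getattr(self, el) * m for el, m in ATOMIC_MASS.items())


def electrons_per_mole(formula: Formula, *, inert: bool = False) -> int:
    """Electrons transferred when one mole is fully oxidised to CO2/H2O/NH3.

    Returns ``4C + H - 2O - 3N``; designated inert species (N2) return 0.
    A negative count for a non-inert species is rejected.
    """
    if inert:
        return 0
    e = 4 * formula.C + formula.H - 2 * formula.O - 3 * formula.N
    if e < 0:
        raise UnsupportedSpeciesError(
            f"formula {formula} has negative electron count {e}; "
            "flag the species inert or exclude it"
        )
    return e


@dataclass(frozen=True)
class Compound:
    """A registered species with derived electron/carbon bookkeeping.

    ``phase`` records where the species is measured (``"gas"`` headspace
    amounts in mmol, ``"liquid"`` broth concentrations).  ``major`` marks
    species included in default reports; minor calibrated analytes
    (1,3-propanediol, lactate, formate) are registered but hidden by
    default.
    """

    name: str
    formula: Formula
    phase: str
    inert: bool = False
    major: bool = True

    def __post_init__(self) -> None:
        if self.phase not in ("gas", "liquid"):
            raise ValueError(f"phase must be 'gas' or 'liquid', got {self.phase!r}")
        _ = self.e_per_mol  # validates non-negativity on construction

    @property
    def e_per_mol(self) -> int:
        return electrons_per_mole(self.formula, inert=self.inert)

    @property
    def c_per_mol(self) -> int:
        return self.formula.C

    @property
    def molar_mass(self) -> float:
        return self.formula.molar_mass


def electrons_per_cmol(compound: Compound) -> Fraction:
    """Degree of reduction: e-mol per C-mol, as an exact rational.

    Undefined for carbon-free species (H2, H2O): raises ``ValueError``.
    """
    if compound.c_per_mol == 0:
        raise ValueError(f"{compound.name} contains no carbon; e per C-mol is undefined")
    return Fraction(compound.e_per_mol, compound.c_per_mol)


def to_millimoles(concentration_g_per_l: float, volume_l: float, compound: Compound) -> float:
    """Convert a g/L concentration in a given liquid volume to mmol."""
    if concentration_g_per_l < 0:
        raise ValueError("concentration must be >= 0")
    if volume_l <= 0:
        raise ValueError("volume must be > 0")
    return concentration_g_per_l * volume_l / compound.molar_mass * 1000.0


def to_concentration(mmol: float, volume_l: float, compound: Compound) -> float:
    """Inverse of :func:`to_millimoles`: mmol in a volume back to g/L."""
    if volume_l <= 0:
        raise ValueError("volume must be > 0")
    return mmol * compound.molar_mass / 1000.0 / volume_l


# Alternate names accepted on lookup (case-insensitive).
_ALIASES = {
    "hac": "acetic acid",
    "acetate": "acetic acid",
    "etoh": "ethanol",
    "ba": "butyric acid",
    "butyrate": "butyric acid",
    "ca": "caproic acid",
    "caproate": "caproic acid",
    "hexanoic acid": "caproic acid",
    "buoh": "butanol",
    "1-butanol": "butanol",
    "1-hexanol": "hexanol",
    "propionate": "propionic acid",
    "1,3-pdo": "1,3-propanediol",
    "water": "H2O",
}


class CompoundRegistry:
    """Name-keyed collection of :class:`Compound` with alias lookup."""

    def __init__(self, compounds: Iterable[Compound] = ()):
        self._by_name: dict[str, Compound] = {}
        for c in compounds:
            self.add(c)

    def add(self, compound: Compound) -> None:
        key = compound.name.lower()
        if key in self._by_name:
            raise ValueError(f"duplicate compound name {compound.name!r}")
        self._by_name[key] = compound

    def __getitem__(self, name: str) -> Compound:
        key = name.lower()
        key = _ALIASES.get(key, key)
        try:
            return self._by_name[key.lower()]
        except KeyError:
            raise UnknownCompoundError(name) from None

    def __contains__(self, name: str) -> bool:
        try:
            self[name]
            return True
        except UnknownCompoundError:
            return False

    def __iter__(self) -> Iterator[Compound]:
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self]

    # ---- serialisation -------------------------------------------------
    def to_records(self) -> list[dict]:
        return [
            {
                "name": c.name,
                "formula": str(c.formula),
                "phase": c.phase,
                **({"inert": True} if c.inert else {}),
                **({"major": False} if not c.major else {}),
            }
            for c in self
        ]

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "CompoundRegistry":
        return cls(
            Compound(
                name=r["name"],
                formula=Formula.parse(r["formula"]),
                phase=r["phase"],
                inert=bool(r.get("inert", False)),
                major=bool(r.get("major", True)),
            )
            for r in records
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_records(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_records(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "CompoundRegistry":
        path = Path(path)
        text = path.read_text()
        records = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_records(records)


_DEFAULT_SPECIES: list[tuple[str, str, str, dict]] = [
    ("H2", "H2", "gas", {}),
    ("CO", "CO", "gas", {}),
    ("CO2", "CO2", "gas", {}),
    ("N2", "N2", "gas", {"inert": True}),
    ("H2O", "H2O", "liquid", {}),
    ("acetic acid", "C2H4O2", "liquid", {}),
    ("ethanol", "C2H6O", "liquid", {}),
    ("propionic acid", "C3H6O2", "liquid", {}),
    ("butyric acid", "C4H8O2", "liquid", {}),
    ("iso-butyric acid", "C4H8O2", "liquid", {}),
    ("iso-valeric acid", "C5H10O2", "liquid", {}),
    ("caproic acid", "C6H12O2", "liquid", {}),
    ("butanol", "C4H10O", "liquid", {}),
    ("hexanol", "C6H14O", "liquid", {}),
    ("1,3-propanediol", "C3H8O2", "liquid", {"major": False}),
    ("lactic acid", "C3H6O3", "liquid", {"major": False}),
    ("formic acid", "CH2O2", "liquid", {"major": False}),
]


def default_registry() -> CompoundRegistry:
    """The built-in registry covering every species tracked in batch vials."""
    return CompoundRegistry(
        Compound(name=n, formula=Formula.parse(f), phase=p, **kw)
        for n, f, p, kw in _DEFAULT_SPECIES
    )
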