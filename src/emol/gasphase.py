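"""Headspace bookkeeping and the Syngas Quality Index.

A sealed batch vessel is described by its total pressure, headspace
volume (vessel volume minus liquid working volume), temperature and gas
mole fractions; per-gas amounts follow from the ideal gas law.  The
Syngas Quality Index

    SQI = 2 (%CO + %H2) / (%CO + %CO2)

is the e-mol carried per C-mol of the feed gas (CO and H2 donate 2
electrons each; CO and CO2 each carry one carbon) and is matched to the
degree of reduction of the intended product when designing a feed: 5
for butyrate, 5.33 for caproate, 6 for butanol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "R_L_ATM",
    "ATM_PER_BAR",
    "GasLoading",
    "bar_to_atm",
    "atm_to_bar",
    "moles_from_headspace",
    "sqi",
    "partial_pressure",
    "Condition",
    "load_condition",
]

R_L_ATM = 0.082057  # L atm mol^-1 K^-1
ATM_PER_BAR = 1.0 / 1.01325

INCUBATION_K = 310.15  # 37 C, the incubation temperature used for vials


def bar_to_atm(p_bar: float) -> float:
    return p_bar * ATM_PER_BAR


def atm_to_bar(p_atm: float) -> float:
    return p_atm / ATM_PER_BAR


def _normalise_fractions(fractions: Mapping[str, float]) -> dict[str, float]:
    """Accept percentages or fractions; return fractions summing to 1."""
    if not fractions:
        raise ValueError("at least one gas fraction required")
    vals = dict(fractions)
    if any(v < 0 for v in vals.values()):
        raise ValueError("gas fractions must be >= 0")
    total = sum(vals.values())
    if total <= 0:
        raise ValueError("gas fractions must sum to a positive value")
    return {g: v / total for g, v in vals.items()}


@dataclass(frozen=True)
class GasLoading:
    """Headspace description of a sealed vessel.

    ``mole_fractions`` may be given as fractions or percentages; they are
    normalised on construction but must already sum to 1 (or 100) within
    1e-6 relative, guarding against a forgotten gas.
    """

    total_pressure_atm: float
    headspace_volume_l: float
    temperature_k: float = INCUBATION_K
    mole_fractions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_pressure_atm <= 0 or self.headspace_volume_l <= 0 or self.temperature_k <= 0:
            raise ValueError("pressure, volume and temperature must be > 0")
        raw = dict(self.mole_fractions)
        total = sum(raw.values())
        scale = 100.0 if total > 1.5 else 1.0
        if not math.isclose(total, scale, rel_tol=1e-6, abs_tol=1e-6):
            raise ValueError(
                f"mole fractions sum to {total:g}; expected 1 (fractions) or 100 (percent)"
            )
        object.__setattr__(self, "mole_fractions", _normalise_fractions(raw))

    @property
    def total_mmol(self) -> float:
        """Total headspace gas, mmol, by the ideal gas law."""
        return (
            self.total_pressure_atm
            * self.headspace_volume_l
            / (R_L_ATM * self.temperature_k)
            * 1000.0
        )


def moles_from_headspace(loading: GasLoading) -> dict[str, float]:
    """Per-gas amounts in mmol: fraction x PV/RT."""
    n = loading.total_mmol
    return {gas: frac * n for gas, frac in loading.mole_fractions.items()}


def partial_pressure(loading: GasLoading, gas: str) -> float:
    """Partial pressure of ``gas`` in atm (Dalton's law)."""
    try:
        frac = loading.mole_fractions[gas]
    except KeyError:
        raise KeyError(f"gas {gas!r} not in loading ({sorted(loading.mole_fractions)})") from None
    return frac * loading.total_pressure_atm


def sqi(mole_fractions: Mapping[str, float]) -> float:
    """Syngas Quality Index: e-mol per C-mol of a CO/H2/CO2(/N2) mixture.

    Invariant to rescaling all fractions by a positive constant, so
    percentages and fractions are both accepted.  Raises ``ValueError``
    when the mixture carries no carbon (%CO + %CO2 = 0), e.g. a pure
    H2/N2 feed, for which the index is undefined.
    """
    fr = _normalise_fractions(mole_fractions)
    co = fr.get("CO", 0.0)
    h2 = fr.get("H2", 0.0)
    co2 = fr.get("CO2", 0.0)
    denom = co + co2
    if denom == 0:
        raise ValueError("SQI undefined: mixture contains no CO or CO2 (no carbon)")
    return 2.0 * (co + h2) / denom


# ---------------------------------------------------------------------------
# Condition configs (one per experimental-series row)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Condition:
    """One experimental condition: vessel, gas feed and liquid additions.

    ``intermediates_mm`` are the nominal liquid additions in mM (e.g.
    acetate/ethanol at 39/93 mM for chain-elongation series, butyrate at
    15 mM for reduction series).
    """

    name: str
    vessel_total_ml: float
    liquid_ml: float
    pressure_atm: float
    temperature_k: float
    gas_percent: Mapping[str, float]
    intermediates_mm: Mapping[str, float] = field(default_factory=dict)
    initial_ph: float = 6.5
    target_products: tuple[str, ...] = ("butyric acid", "caproic acid", "butanol")

    def __post_init__(self) -> None:
        if self.liquid_ml <= 0 or self.vessel_total_ml <= self.liquid_ml:
            raise ValueError("need vessel_total_ml > liquid_ml > 0")
        if any(v < 0 for v in self.intermediates_mm.values()):
            raise ValueError("intermediate additions must be >= 0")

    @property
    def headspace_volume_l(self) -> float:
        return (self.vessel_total_ml - self.liquid_ml) / 1000.0

    @property
    def liquid_volume_l(self) -> float:
        return self.liquid_ml / 1000.0

    @property
    def gas_loading(self) -> GasLoading:
        return GasLoading(
            total_pressure_atm=self.pressure_atm,
            headspace_volume_l=self.headspace_volume_l,
            temperature_k=self.temperature_k,
            mole_fractions=dict(self.gas_percent),
        )

    def initial_gas_mmol(self) -> dict[str, float]:
        return moles_from_headspace(self.gas_loading)

    def initial_liquid_mmol(self) -> dict[str, float]:
        return {c: mm * self.liquid_volume_l for c, mm in self.intermediates_mm.items()}


def load_condition(path: str | Path) -> Condition:
    """Read a condition YAML file.

    Schema::

        name: syngas-acetate-ethanol
        vessel: {total_mL: 300, liquid_mL: 100}
        pressure: {value: 1.8, unit: atm}     # unit atm or bar
        temperature_C: 37
        gas: {H2: 70, CO: 10, CO2: 20}        # percent
        intermediates: {acetic acid: 39, ethanol: 93}   # mM
        initial_pH: 6.5
    """
    data = yaml.safe_load(Path(path).read_text())
    pressure = data["pressure"]
    p_atm = float(pressure["value"])
    unit = pressure.get("unit", "atm").lower()
    if unit == "bar":
        p_atm = bar_to_atm(p_atm)
    elif unit != "atm":
        raise ValueError(f"unsupported pressure unit {unit!r}")
    return Condition(
        name=data.get("name", Path(path).stem),
        vessel_total_ml=float(data["vessel"]["total_mL"]),
        liquid_ml=float(data["vessel"]["liquid_mL"]),
        pressure_atm=p_atm,
        temperature_k=float(data.get("temperature_C", 37.0)) + 273.15,
        gas_percent=dict(data["gas"]),
        intermediates_mm=dict(data.get("intermediates", {})),
        initial_ph=float(data.get("initial_pH", 6.5)),
        target_products=tuple(
            data.get("target_products", ("butyric acid", "caproic acid", "butanol"))
        ),
    )
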