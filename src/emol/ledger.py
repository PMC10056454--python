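"""Electron ledgers for batch vials: net e-mol changes, yields, recovery
and end-product distribution.

A vial is sampled once at the start and once at the end of a batch; the
signed change in electron content of each measured species partitions
the compounds into electron sources (consumed, negative change) and
products (positive change).  Three statistics summarise a batch:

* yield of compound i:  Y_i = 100 * d(e)_i / sum_j |d(e)_j|  over consumed j,
  so product yields are positive, source yields negative and sources sum
  to exactly -100;
* electron recovery: 100 * (total e-mol at end) / (total e-mol at start),
  which is 100% when every electron fed is found again in a measured
  compound;
* end-product distribution: each net product's share of the total net
  product electrons.

Liquid species enter as concentrations (mM or g/L) times the working
volume; gas species as headspace mmol.  A configurable dead-band (0.5%
of consumed e-mol by default) zeroes changes too small to distinguish
from replicate scatter, so measurement noise cannot flip a compound
between the source and product sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import json

import pandas as pd

from .compounds import CompoundRegistry, default_registry, to_millimoles

__all__ = [
    "DEFAULT_TARGETS",
    "BatchObservation",
    "LedgerResult",
    "net_mmol_changes",
    "net_emol_changes",
    "yields",
    "recovery",
    "distribution",
    "analyze_batch",
    "series_ledger",
    "observations_to_frame",
    "observations_from_frame",
    "read_observations_csv",
    "write_observations_csv",
]

DEFAULT_TARGETS: tuple[str, ...] = ("butyric acid", "caproic acid", "butanol")

DEAD_BAND_FRACTION = 0.005  # |d(e)| below this fraction of consumed e-mol counts as unchanged


@dataclass
class BatchObservation:
    """Start/end measurements of one vial in one batch.

    Liquid concentrations in mM keyed by compound name; gas amounts in
    mmol.  A compound absent from one of the paired maps is treated as 0.
    """

    vial: str
    transfer: int
    liquid_volume_l: float
    liquid_initial_mm: dict[str, float] = field(default_factory=dict)
    liquid_final_mm: dict[str, float] = field(default_factory=dict)
    gas_initial_mmol: dict[str, float] = field(default_factory=dict)
    gas_final_mmol: dict[str, float] = field(default_factory=dict)
    ph_initial: float | None = None
    ph_final: float | None = None

    def __post_init__(self) -> None:
        if self.liquid_volume_l <= 0:
            raise ValueError("liquid volume must be > 0")
        for m in (
            self.liquid_initial_mm,
            self.liquid_final_mm,
            self.gas_initial_mmol,
            self.gas_final_mmol,
        ):
            for name, v in m.items():
                if v < 0:
                    raise ValueError(f"negative amount for {name!r}: {v}")
        # symmetrise keys: absent at one end means zero
        for a, b in (
            (self.liquid_initial_mm, self.liquid_final_mm),
            (self.gas_initial_mmol, self.gas_final_mmol),
        ):
            for k in set(a) | set(b):
                a.setdefault(k, 0.0)
                b.setdefault(k, 0.0)

    # -- amount accessors ------------------------------------------------
    def amounts_mmol(self, when: str) -> dict[str, float]:
        """Combined per-compound mmol (liquid + gas) at ``"start"`` or ``"end"``."""
        if when == "start":
            liq, gas = self.liquid_initial_mm, self.gas_initial_mmol
        elif when == "end":
            liq, gas = self.liquid_final_mm, self.gas_final_mmol
        else:
            raise ValueError("when must be 'start' or 'end'")
        out: dict[str, float] = {}
        for name, mm in liq.items():
            out[name] = out.get(name, 0.0) + mm * self.liquid_volume_l
        for name, mmol in gas.items():
            out[name] = out.get(name, 0.0) + mmol
        return out


@dataclass
class LedgerResult:
    """Per-vial electron ledger."""

    vial: str
    transfer: int
    delta_mmol: dict[str, float]
    delta_emmol: dict[str, float]
    consumed: tuple[str, ...]
    produced: tuple[str, ...]
    yields_percent: dict[str, float]
    recovery_percent: float
    distribution_percent: dict[str, float]
    target_summary: dict[str, float]

    @property
    def target_yield(self) -> float:
        """Summed yield of the target products (the vial-selection score)."""
        return sum(self.target_summary.values())


def net_mmol_changes(obs: BatchObservation, registry: CompoundRegistry) -> dict[str, float]:
    """Signed net change in mmol per compound (end minus start)."""
    start = obs.amounts_mmol("start")
    end = obs.amounts_mmol("end")
    out = {}
    for name in set(start) | set(end):
        registry[name]  # raises UnknownCompoundError for unregistered species
        out[registry[name].name] = end.get(name, 0.0) - start.get(name, 0.0)
    return out


def net_emol_changes(obs: BatchObservation, registry: CompoundRegistry) -> dict[str, float]:
    """Signed net change in e-mmol per compound: d(mmol) x e-per-mol."""
    return {
        name: d * registry[name].e_per_mol for name, d in net_mmol_changes(obs, registry).items()
    }


def _split_sets(
    changes: Mapping[str, float], dead_band_fraction: float
) -> tuple[dict[str, float], list[str], list[str]]:
    """Apply the dead-band and classify compounds into consumed/produced."""
    consumed_total = -sum(d for d in changes.values() if d < 0)
    band = dead_band_fraction * consumed_total
    effective = {n: (0.0 if abs(d) < band else d) for n, d in changes.items()}
    consumed = sorted(n for n, d in effective.items() if d < 0)
    produced = sorted(n for n, d in effective.items() if d > 0)
    return effective, consumed, produced


def yields(
    changes: Mapping[str, float], *, dead_band_fraction: float = DEAD_BAND_FRACTION
) -> dict[str, float]:
    """Signed e-mol yields in percent of total consumed e-mol.

    Every compound gets a value: positive for products, negative for
    sources (summing to -100 by construction), 0 for unchanged species.
    Raises ``ValueError`` when nothing was consumed.
    """
    effective, consumed, _ = _split_sets(changes, dead_band_fraction)
    denom = -sum(effective[n] for n in consumed)
    if denom <= 0:
        raise ValueError("yield undefined: no compound with net electron consumption")
    return {n: d / denom * 100.0 for n, d in effective.items()}


def recovery(obs: BatchObservation, registry: CompoundRegistry) -> float:
    """Electron recovery, percent: total e-mmol at end over start."""
    start = sum(
        a * registry[n].e_per_mol for n, a in obs.amounts_mmol("start").items()
    )
    end = sum(a * registry[n].e_per_mol for n, a in obs.amounts_mmol("end").items())
    if start <= 0:
        raise ValueError("recovery undefined: zero electrons at batch start")
    return end / start * 100.0


def distribution(
    changes: Mapping[str, float], *, dead_band_fraction: float = DEAD_BAND_FRACTION
) -> dict[str, float]:
    """Share of net product electrons per net product, percent (sums to 100)."""
    effective, _, produced = _split_sets(changes, dead_band_fraction)
    total = sum(effective[n] for n in produced)
    if total <= 0:
        raise ValueError("distribution undefined: no net-produced compound")
    return {n: effective[n] / total * 100.0 for n in produced}


def analyze_batch(
    obs: BatchObservation,
    registry: CompoundRegistry | None = None,
    *,
    targets: Sequence[str] = DEFAULT_TARGETS,
    dead_band_fraction: float = DEAD_BAND_FRACTION,
) -> LedgerResult:
    """Full electron ledger for one vial."""
    registry = registry if registry is not None else default_registry()
    dmmol = net_mmol_changes(obs, registry)
    demmol = {n: d * registry[n].e_per_mol for n, d in dmmol.items()}
    effective, consumed, produced = _split_sets(demmol, dead_band_fraction)
    ylds = yields(demmol, dead_band_fraction=dead_band_fraction)
    dist = (
        distribution(demmol, dead_band_fraction=dead_band_fraction) if produced else {}
    )
    target_names = [registry[t].name for t in targets]
    return LedgerResult(
        vial=obs.vial,
        transfer=obs.transfer,
        delta_mmol=dmmol,
        delta_emmol=demmol,
        consumed=tuple(consumed),
        produced=tuple(produced),
        yields_percent=ylds,
        recovery_percent=recovery(obs, registry),
        distribution_percent=dist,
        target_summary={t: max(ylds.get(t, 0.0), 0.0) for t in target_names},
    )


def series_ledger(
    observations: Iterable[BatchObservation],
    registry: CompoundRegistry | None = None,
    **kwargs,
) -> list[LedgerResult]:
    """Ledger for a serial-transfer series, ordered by transfer.

    Transfer indices must run consecutively from 0 (replicate vials may
    share an index); a gap raises ``ValueError``.
    """
    obs = sorted(observations, key=lambda o: (o.transfer, o.vial))
    if not obs:
        raise ValueError("empty observation list")
    transfers = sorted({o.transfer for o in obs})
    if transfers != list(range(len(transfers))) or transfers[0] != 0:
        raise ValueError(f"transfer indices {transfers} are not consecutive from 0")
    return [analyze_batch(o, registry, **kwargs) for o in obs]


# ---------------------------------------------------------------------------
# Tidy I/O:  vial, transfer, phase, compound, time, amount, unit [, liquid_volume_l]
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["vial", "transfer", "phase", "compound", "time", "amount", "unit", "liquid_volume_l"]


def observations_to_frame(observations: Iterable[BatchObservation]) -> pd.DataFrame:
    rows = []
    for o in observations:
        for phase, time, data, unit in (
            ("liquid", "start", o.liquid_initial_mm, "mM"),
            ("liquid", "end", o.liquid_final_mm, "mM"),
            ("gas", "start", o.gas_initial_mmol, "mmol"),
            ("gas", "end", o.gas_final_mmol, "mmol"),
        ):
            for compound, amount in sorted(data.items()):
                rows.append(
                    dict(
                        vial=o.vial,
                        transfer=o.transfer,
                        phase=phase,
                        compound=compound,
                        time=time,
                        amount=amount,
                        unit=unit,
                        liquid_volume_l=o.liquid_volume_l,
                    )
                )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def observations_from_frame(
    frame: pd.DataFrame, registry: CompoundRegistry | None = None
) -> list[BatchObservation]:
    """Rebuild observations from the tidy table.

    Liquid amounts may be in mM or g/L (converted via the registry's
    molar masses); gas amounts must be mmol.
    """
    registry = registry if registry is not None else default_registry()
    missing = [c for c in _CSV_COLUMNS[:-1] if c not in frame.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    out = []
    for (vial, transfer), grp in frame.groupby(["vial", "transfer"], sort=True):
        vol = float(grp["liquid_volume_l"].iloc[0]) if "liquid_volume_l" in grp else 0.1
        liq_i: dict[str, float] = {}
        liq_f: dict[str, float] = {}
        gas_i: dict[str, float] = {}
        gas_f: dict[str, float] = {}
        for idx, row in grp.iterrows():
            amount, unit, phase = float(row["amount"]), str(row["unit"]), str(row["phase"])
            name = registry[str(row["compound"])].name
            if phase == "liquid":
                if unit == "mM":
                    mm = amount
                elif unit == "g/L":
                    mm = to_millimoles(amount, vol, registry[name]) / vol  # mmol/L = mM
                else:
                    raise ValueError(f"row {idx}: unsupported liquid unit {unit!r}")
                (liq_i if row["time"] == "start" else liq_f)[name] = mm
            elif phase == "gas":
                if unit != "mmol":
                    raise ValueError(f"row {idx}: unsupported gas unit {unit!r}")
                (gas_i if row["time"] == "start" else gas_f)[name] = amount
            else:
                raise ValueError(f"row {idx}: unknown phase {phase!r}")
        out.append(
            BatchObservation(
                vial=str(vial),
                transfer=int(transfer),
                liquid_volume_l=vol,
                liquid_initial_mm=liq_i,
                liquid_final_mm=liq_f,
                gas_initial_mmol=gas_i,
                gas_final_mmol=gas_f,
            )
        )
    return out


def write_observations_csv(observations: Iterable[BatchObservation], path: str | Path) -> None:
    observations_to_frame(observations).to_csv(path, index=False)


def read_observations_csv(
    path: str | Path, registry: CompoundRegistry | None = None
) -> list[BatchObservation]:
    return observations_from_frame(pd.read_csv(path), registry)


def ledger_to_json(results: Iterable[LedgerResult], path: str | Path | None = None) -> str:
    """Serialise ledger results; returns the JSON text."""
    payload = [
        dict(
            vial=r.vial,
            transfer=r.transfer,
            delta_mmol=r.delta_mmol,
            delta_emmol=r.delta_emmol,
            consumed=list(r.consumed),
            produced=list(r.produced),
            yields_percent=r.yields_percent,
            recovery_percent=r.recovery_percent,
            distribution_percent=r.distribution_percent,
            target_summary=r.target_summary,
        )
        for r in results
    ]
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
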