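"""Publication-style summary tables from ledger results.

Three views of an enrichment series:

* a final-transfer concentration table (mean +/- sd over replicate
  vials, g/L with mM alongside) with an electron-recovery row;
* a per-transfer signed e-mol yield long table for stacked-bar plots
  (products stack up, sources stack down);
* a net-product distribution table.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .compounds import CompoundRegistry, default_registry
from .ledger import BatchObservation, LedgerResult

__all__ = [
    "final_concentration_table",
    "yields_long_table",
    "distribution_table",
    "report_series",
]


def final_concentration_table(
    observations: Sequence[BatchObservation],
    results: Sequence[LedgerResult],
    registry: CompoundRegistry | None = None,
    *,
    major_only: bool = True,
) -> pd.DataFrame:
    """Mean +/- sd final concentrations of the last transfer's vials.

    One row per liquid compound (g/L and mM) plus an ``e-recovery, %``
    row, mirroring the layout of end-of-enrichment summary tables.
    """
    registry = registry if registry is not None else default_registry()
    if not observations:
        raise ValueError("no observations to report")
    last = max(o.transfer for o in observations)
    obs = [o for o in observations if o.transfer == last]
    res = [r for r in results if r.transfer == last]
    compounds = sorted(
        {
            name
            for o in obs
            for name in o.liquid_final_mm
            if name in registry
            and registry[name].phase == "liquid"
            and registry[name].name != "H2O"
            and (registry[name].major or not major_only)
        }
    )
    rows = []
    for name in compounds:
        c = registry[name]
        mm = np.array([o.liquid_final_mm.get(name, 0.0) for o in obs])
        gl = mm * c.molar_mass / 1000.0
        rows.append(
            dict(
                compound=c.name,
                mean_g_per_l=float(gl.mean()),
                sd_g_per_l=float(gl.std(ddof=1)) if len(gl) > 1 else 0.0,
                mean_mm=float(mm.mean()),
                sd_mm=float(mm.std(ddof=1)) if len(mm) > 1 else 0.0,
            )
        )
    rec = np.array([r.recovery_percent for r in res]) if res else np.array([np.nan])
    rows.append(
        dict(
            compound="e-recovery, %",
            mean_g_per_l=float(rec.mean()),
            sd_g_per_l=float(rec.std(ddof=1)) if len(rec) > 1 else 0.0,
            mean_mm=np.nan,
            sd_mm=np.nan,
        )
    )
    return pd.DataFrame(rows)


def yields_long_table(results: Iterable[LedgerResult]) -> pd.DataFrame:
    """Per-transfer signed e-mol yields in long format.

    ``role`` is ``product`` (positive, stacked up) or ``source``
    (negative, stacked down); zero-change compounds are omitted.
    """
    rows = []
    for r in results:
        for compound, y in sorted(r.yields_percent.items()):
            if y == 0:
                continue
            rows.append(
                dict(
                    transfer=r.transfer,
                    vial=r.vial,
                    compound=compound,
                    yield_percent=y,
                    role="product" if y > 0 else "source",
                )
            )
    return pd.DataFrame(rows, columns=["transfer", "vial", "compound", "yield_percent", "role"])


def distribution_table(results: Iterable[LedgerResult]) -> pd.DataFrame:
    """Net-product electron distribution per vial (sums to 100 within a vial)."""
    rows = []
    for r in results:
        for compound, d in sorted(r.distribution_percent.items()):
            rows.append(
                dict(transfer=r.transfer, vial=r.vial, compound=compound, distribution_percent=d)
            )
    return pd.DataFrame(
        rows, columns=["transfer", "vial", "compound", "distribution_percent"]
    )


def report_series(
    observations: Sequence[BatchObservation],
    results: Sequence[LedgerResult],
    registry: CompoundRegistry | None = None,
) -> dict[str, pd.DataFrame]:
    """All three summary tables for one enrichment series."""
    if not results:
        raise ValueError("no ledger results to report")
    return {
        "final_concentrations": final_concentration_table(observations, results, registry),
        "yields_long": yields_long_table(results),
        "distribution": distribution_table(results),
    }
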