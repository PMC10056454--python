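"""Electron ledger statistics: net changes, yields, recovery, distribution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emol.compounds import default_registry
from emol.ledger import (
    BatchObservation,
    analyze_batch,
    distribution,
    net_emol_changes,
    net_mmol_changes,
    observations_from_frame,
    observations_to_frame,
    recovery,
    series_ledger,
    yields,
)


class TestNetChanges:
    def test_ethanol_consumption_in_emol(self, registry):
        obs = BatchObservation(
            vial="A", transfer=0, liquid_volume_l=0.1,
            liquid_initial_mm={"ethanol": 93.0},
            liquid_final_mm={"ethanol": 43.0},
        )
        # 9.3 -> 4.3 mmol at 12 e per mole
        assert net_emol_changes(obs, registry)["ethanol"] == pytest.approx(-60.0)

    def test_co2_changes_carry_no_electrons(self, registry):
        obs = BatchObservation(
            vial="A", transfer=0, liquid_volume_l=0.1,
            gas_initial_mmol={"CO2": 2.8, "H2": 9.9},
            gas_final_mmol={"CO2": 5.0, "H2": 9.9},
        )
        changes = net_emol_changes(obs, registry)
        assert changes["CO2"] == 0.0

    def test_butyrate_production(self, registry):
        obs = BatchObservation(
            vial="A", transfer=0, liquid_volume_l=0.1,
            liquid_initial_mm={"butyric acid": 0.0},
            liquid_final_mm={"butyric acid": 40.0},
        )
        assert net_emol_changes(obs, registry)["butyric acid"] == pytest.approx(80.0)

    def test_unknown_compound_rejected(self, registry):
        obs = BatchObservation(
            vial="A", transfer=0, liquid_volume_l=0.1,
            liquid_initial_mm={"glucose": 1.0}, liquid_final_mm={"glucose": 0.0},
        )
        with pytest.raises(KeyError):
            net_mmol_changes(obs, registry)


class TestEq1Batch:
    """The worked 5:3 chain-elongation example: all substrate electrons
    (60 + 24 = 84 e-mmol) reappear in butyrate (80) and H2 (4)."""

    def test_recovery_is_exact(self, eq1_batch, registry):
        assert recovery(eq1_batch, registry) == pytest.approx(100.0, abs=1e-9)

    def test_yields(self, eq1_batch, registry):
        result = analyze_batch(eq1_batch, registry)
        assert result.yields_percent["butyric acid"] == pytest.approx(100 * 80 / 84)
        assert result.yields_percent["H2"] == pytest.approx(100 * 4 / 84)
        assert result.yields_percent["ethanol"] == pytest.approx(-100 * 60 / 84)
        assert result.yields_percent["acetic acid"] == pytest.approx(-100 * 24 / 84)

    def test_distribution(self, eq1_batch, registry):
        result = analyze_batch(eq1_batch, registry)
        assert result.distribution_percent["butyric acid"] == pytest.approx(95.238, abs=0.001)
        assert result.distribution_percent["H2"] == pytest.approx(4.762, abs=0.001)

    def test_target_summary(self, eq1_batch, registry):
        result = analyze_batch(eq1_batch, registry)
        assert result.target_summary["butyric acid"] == pytest.approx(95.238, abs=0.001)
        assert result.target_summary["caproic acid"] == 0.0
        assert result.target_yield == pytest.approx(95.238, abs=0.001)


class TestYieldAlgebra:
    def test_consumed_yields_sum_to_minus_100(self):
        changes = {"a": -30.0, "b": -12.0, "c": 20.0, "d": 5.0}
        y = yields(changes, dead_band_fraction=0.0)
        assert sum(v for v in y.values() if v < 0) == pytest.approx(-100.0)

    def test_single_full_conversion_gives_100(self):
        y = yields({"substrate": -42.0, "product": 42.0}, dead_band_fraction=0.0)
        assert y["product"] == pytest.approx(100.0)

    def test_nothing_produced_gives_zero_yields(self, registry):
        obs = BatchObservation(
            vial="A", transfer=0, liquid_volume_l=0.1,
            liquid_initial_mm={"ethanol": 10.0}, liquid_final_mm={"ethanol": 5.0},
        )
        result = analyze_batch(obs, registry)
        assert all(v <= 0 for v in result.yields_percent.values())
        assert result.recovery_percent < 100.0
        assert result.produced == ()

    def test_no_consumption_is_undefined(self):
        with pytest.raises(ValueError, match="no compound with net electron consumption"):
            yields({"a": 5.0, "b": 0.0})

    def test_zero_change_compounds_do_not_affect_anything(self, eq1_batch, registry):
        base = analyze_batch(eq1_batch, registry)
        eq1_batch.liquid_initial_mm["propionic acid"] = 7.0
        eq1_batch.liquid_final_mm["propionic acid"] = 7.0
        augmented = analyze_batch(eq1_batch, registry)
        for name, v in base.yields_percent.items():
            assert augmented.yields_percent[name] == pytest.approx(v, rel=1e-12)
        assert augmented.recovery_percent == pytest.approx(base.recovery_percent, rel=1e-12)
        assert augmented.distribution_percent == pytest.approx(base.distribution_percent)

    @given(
        deltas=st.dictionaries(
            st.sampled_from(["ethanol", "acetic acid", "butyric acid", "caproic acid", "H2"]),
            st.floats(min_value=-50, max_value=50),
            min_size=2,
            max_size=5,
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_yield_recovery_identity(self, deltas):
        """Sum of product yields minus 100 equals 100 x (electron gain) /
        (consumed electrons) — the algebraic link between the yield and
        recovery definitions — on arbitrary signed ledgers."""
        consumed = -sum(d for d in deltas.values() if d < 0)
        if consumed < 1e-6:
            return
        y = yields(deltas, dead_band_fraction=0.0)
        produced_sum = sum(v for v in y.values() if v > 0)
        gain = sum(deltas.values())
        assert produced_sum - 100.0 == pytest.approx(100.0 * gain / consumed, abs=1e-9)


class TestDistribution:
    def test_equal_products_split_evenly(self):
        d = distribution({"x": 10.0, "y": 10.0, "z": -20.0}, dead_band_fraction=0.0)
        assert d == {"x": pytest.approx(50.0), "y": pytest.approx(50.0)}

    def test_proportionality(self):
        d = distribution({"x": 40.0, "y": 40.0, "z": 20.0, "s": -100.0}, dead_band_fraction=0.0)
        assert d["x"] == pytest.approx(40.0)
        assert d["z"] == pytest.approx(20.0)

    def test_sums_to_100(self):
        d = distribution({"x": 13.0, "y": 29.0, "s": -50.0}, dead_band_fraction=0.0)
        assert sum(d.values()) == pytest.approx(100.0, abs=1e-9)

    def test_no_products_undefined(self):
        with pytest.raises(ValueError):
            distribution({"s": -50.0})


class TestDeadBand:
    def test_tiny_changes_classed_unchanged(self):
        # 0.1 e-mmol on a 100 e-mmol consumption is measurement noise
        y = yields({"s": -100.0, "p": 99.0, "noise": 0.1}, dead_band_fraction=0.005)
        assert y["noise"] == 0.0
        assert y["p"] == pytest.approx(99.0)

    def test_dead_band_cannot_flip_source_to_product(self, registry):
        obs = BatchObservation(
            vial="A", transfer=0, liquid_volume_l=0.1,
            liquid_initial_mm={"ethanol": 50.0, "propionic acid": 10.001},
            liquid_final_mm={"ethanol": 0.0, "propionic acid": 10.0,
                             "butyric acid": 30.0},
        )
        result = analyze_batch(obs, registry)
        assert "propionic acid" not in result.consumed
        assert "propionic acid" not in result.produced


class TestSeriesAndIO:
    def _series(self, registry, transfers=3):
        obs = []
        for t in range(transfers):
            o = BatchObservation(
                vial=f"T{t}", transfer=t, liquid_volume_l=0.1,
                liquid_initial_mm={"ethanol": 50.0, "acetic acid": 30.0},
                liquid_final_mm={"ethanol": 0.0, "acetic acid": 0.0,
                                 "butyric acid": 40.0},
                gas_final_mmol={"H2": 2.0},
            )
            obs.append(o)
        return obs

    def test_one_result_per_observation(self, registry):
        results = series_ledger(self._series(registry), registry)
        assert [r.transfer for r in results] == [0, 1, 2]

    def test_gap_in_transfers_rejected(self, registry):
        obs = self._series(registry)
        obs[1].transfer = 5
        with pytest.raises(ValueError, match="not consecutive"):
            series_ledger(obs, registry)

    def test_empty_series_rejected(self, registry):
        with pytest.raises(ValueError):
            series_ledger([], registry)

    def test_csv_round_trip(self, registry, tmp_path):
        obs = self._series(registry)
        frame = observations_to_frame(obs)
        back = observations_from_frame(frame, registry)
        assert len(back) == len(obs)
        for a, b in zip(sorted(obs, key=lambda o: o.vial), sorted(back, key=lambda o: o.vial)):
            ra = analyze_batch(a, registry)
            rb = analyze_batch(b, registry)
            for name in ra.yields_percent:
                assert rb.yields_percent[name] == pytest.approx(
                    ra.yields_percent[name], abs=1e-9
                )

    def test_units_g_per_l_equivalent_to_mm(self, registry):
        """Yields are invariant to the liquid concentration unit."""
        frame_mm = observations_to_frame(self._series(registry)[:1])
        frame_gl = frame_mm.copy()
        liquid = frame_gl["phase"] == "liquid"
        for idx in frame_gl[liquid].index:
            c = registry[frame_gl.loc[idx, "compound"]]
            frame_gl.loc[idx, "amount"] = frame_gl.loc[idx, "amount"] * c.molar_mass / 1000.0
            frame_gl.loc[idx, "unit"] = "g/L"
        r_mm = analyze_batch(observations_from_frame(frame_mm, registry)[0], registry)
        r_gl = analyze_batch(observations_from_frame(frame_gl, registry)[0], registry)
        for name in r_mm.yields_percent:
            assert r_gl.yields_percent[name] == pytest.approx(
                r_mm.yields_percent[name], rel=1e-9
            )

    def test_malformed_frame_rejected(self, registry):
        with pytest.raises(ValueError, match="missing columns"):
            observations_from_frame(pd.DataFrame({"vial": ["A"]}), registry)
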