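import numpy as np
import pandas as pd
import pytest

from grasspatch import SimulationConfig, run_simulation
from grasspatch.community import (annual_aggregate, apply_mowing, census,
                                  censuses_to_frame, read_mowing_csv)
from grasspatch.environment import generate_synthetic_climate

from conftest import build_community


class TestMowing:
    def test_short_plant_untouched(self, festuca):
        com = build_community([festuca], widths=[8.0 / festuca.hw],
                              heights=[8.0])
        harvest = apply_mowing(com, 10.0)
        assert harvest == 0.0
        assert com.height[0] == 8.0

    def test_proportional_removal(self, festuca):
        com = build_community([festuca], widths=[30.0 / festuca.hw],
                              heights=[30.0])
        shoot0 = com.sg[0] + com.ss[0]
        harvest = apply_mowing(com, 10.0)
        assert com.height[0] == 10.0
        assert com.sg[0] + com.ss[0] == pytest.approx(shoot0 / 3, rel=1e-12)
        assert harvest == pytest.approx(2 * shoot0 / 3, rel=1e-12)

    def test_exact_conservation(self, festuca):
        rng = np.random.default_rng(4)
        widths = rng.uniform(1, 30, 50)
        com = build_community([festuca], widths=widths)
        shoot0 = com.sg[:50].sum() + com.ss[:50].sum()
        harvest = apply_mowing(com, 10.0)
        shoot1 = com.sg[:50].sum() + com.ss[:50].sum()
        assert harvest + shoot1 == pytest.approx(shoot0, rel=1e-12)

    def test_idempotence(self, festuca):
        com = build_community([festuca], widths=np.linspace(2, 25, 20))
        apply_mowing(com, 10.0)
        state = (com.sg[:20].copy(), com.ss[:20].copy(),
                 com.height[:20].copy())
        assert apply_mowing(com, 10.0) == 0.0
        np.testing.assert_array_equal(com.sg[:20], state[0])
        np.testing.assert_array_equal(com.height[:20], state[2])

    def test_invalid_cut_height(self, festuca):
        com = build_community([festuca], widths=[5.0])
        with pytest.raises(ValueError):
            apply_mowing(com, 0.0)


class TestCensus:
    def test_empty_community_all_zero(self, festuca):
        com = build_community([festuca], widths=[])
        rec = census(com, pd.Timestamp("2003-06-19"))
        assert rec.agb.sum() == 0 and rec.lai == 0 and rec.height == 0

    def test_lai_ratio(self, festuca):
        # leaf area 5000 cm² on a 10000 cm² patch -> LAI 0.5
        green = 5000.0 / festuca.SLA
        com = build_community([festuca], widths=[10.0], shoot_green=[green])
        rec = census(com, pd.Timestamp("2003-06-19"))
        assert rec.lai == pytest.approx(0.5, rel=1e-12)

    def test_agb_per_area_and_height(self, festuca, poa):
        com = build_community([festuca, poa], widths=[10.0, 8.0],
                              species_idx=[0, 1])
        rec = census(com, pd.Timestamp("2003-06-19"))
        assert rec.agb[0] == pytest.approx(com.sg[0] + com.ss[0])
        assert rec.height == pytest.approx(com.height[:2].max())

    def test_cover_bounded_by_crowding(self, festuca):
        from grasspatch.demography import crowding_step
        rng = np.random.default_rng(0)
        com = build_community([festuca], widths=rng.uniform(5, 30, 100))
        crowding_step(com, rng)
        rec = census(com, pd.Timestamp("2003-06-19"))
        assert rec.cover.sum() <= 100.0 + 1e-9


class TestAnnualAggregate:
    def _record(self, date, agb):
        from grasspatch.community import CensusRecord
        a = np.array([agb])
        return CensusRecord(pd.Timestamp(date), ("sp",), a, np.array([50.0]),
                            np.array([1.0]), 1.0, 20.0)

    def test_mean_and_range(self):
        recs = [self._record("2003-06-19", 100.0),
                self._record("2003-09-19", 200.0)]
        out = annual_aggregate(recs, ["sp"])
        s = out["agb:sp"]
        assert s.mean[0] == 150.0
        assert (s.vmin[0], s.vmax[0]) == (100.0, 200.0)

    def test_single_census_degenerate_range(self):
        out = annual_aggregate([self._record("2003-06-19", 80.0)], ["sp"])
        s = out["agb:sp"]
        assert s.mean[0] == s.vmin[0] == s.vmax[0] == 80.0

    def test_mean_within_range_property(self, festuca, short_config):
        result = run_simulation([festuca], short_config, seed=5)
        for s in annual_aggregate(result.censuses).values():
            assert np.all(s.vmin - 1e-12 <= s.mean)
            assert np.all(s.mean <= s.vmax + 1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            annual_aggregate([])


class TestRunSimulation:
    def test_zero_seed_rain_stays_empty(self, festuca, short_config):
        result = run_simulation([festuca], short_config, seed=1,
                                seed_rain_override={festuca.species: 0.0})
        assert all(c.agb.sum() == 0 for c in result.censuses)
        assert result.community.n == 0

    def test_determinism_bit_identical(self, festuca, short_config):
        a = run_simulation([festuca], short_config, seed=77)
        b = run_simulation([festuca], short_config, seed=77)
        for ca, cb in zip(a.censuses, b.censuses):
            np.testing.assert_array_equal(ca.agb, cb.agb)
            np.testing.assert_array_equal(ca.cover, cb.cover)
            assert ca.height == cb.height

    def test_censuses_in_date_order(self, festuca, short_config):
        result = run_simulation([festuca], short_config, seed=2)
        dates = [c.date for c in result.censuses]
        assert dates == sorted(dates)
        assert len(dates) == short_config.years * 2

    def test_interval_censuses_inside_season(self, festuca, short_config):
        import dataclasses
        cfg = dataclasses.replace(short_config, census_interval_days=14)
        result = run_simulation([festuca], cfg, seed=2)
        lo, hi = cfg.census_season_doy
        interval = [c for c in result.censuses
                    if lo <= c.date.dayofyear <= hi]
        assert len(interval) >= cfg.years * (hi - lo) // 14
        # every in-season date on the 14-day grid, pre-mowing censuses kept
        grid = {d for c in result.censuses
                if (d := c.date.dayofyear) >= lo and d <= hi}
        assert any((d - lo) % 14 == 0 for d in grid)
        assert len(result.censuses) > cfg.years * 2

    def test_mowing_restores_height(self, festuca, short_config):
        result = run_simulation([festuca], short_config, seed=3)
        for ev in result.mowing_events:
            assert ev.max_height_after <= ev.cut_height + 1e-9
            assert ev.harvest + ev.post_cut_shoot == \
                pytest.approx(ev.pre_cut_shoot, rel=1e-12)

    def test_explicit_mowing_schedule(self, festuca):
        cfg = SimulationConfig(years=1)
        mow = pd.DataFrame({"date": ["2003-07-01"], "cut_height_cm": [5.0]})
        result = run_simulation([festuca], cfg, mowing=mow, seed=4)
        assert len(result.mowing_events) == 1
        assert result.mowing_events[0].cut_height == 5.0

    def test_mowing_date_outside_span_rejected(self, festuca):
        cfg = SimulationConfig(years=1)
        mow = pd.DataFrame({"date": ["2010-07-01"], "cut_height_cm": [10.0]})
        with pytest.raises(ValueError, match="outside"):
            run_simulation([festuca], cfg, mowing=mow, seed=0)

    def test_climate_gap_rejected(self, festuca, short_config):
        clim = generate_synthetic_climate(years=2, seed=0)
        gappy = pd.concat([clim.iloc[:100], clim.iloc[150:]])
        with pytest.raises(ValueError, match="missing driver"):
            run_simulation([festuca], short_config, climate=gappy, seed=0)

    def test_crowding_constraint_every_day(self, festuca, short_config):
        result = run_simulation([festuca], short_config, seed=6)
        assert np.all(result.daily_occupied <=
                      short_config.patch_area_cm2 * (1 + 1e-12))

    def test_whole_system_carbon_balance(self, festuca, short_config):
        b = run_simulation([festuca], short_config, seed=8).balance
        lhs = b["plant_mass_final"] - b["plant_mass_initial"]
        rhs = (b["gpp_lim"] - b["respiration"] - b["litter_above"]
               - b["litter_below"] - b["harvest"] + b["seed_mass_in"])
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)

    def test_census_export_schema(self, festuca, short_config, tmp_path):
        result = run_simulation([festuca], short_config, seed=9)
        df = censuses_to_frame(result.censuses)
        assert set(df.columns) == {"date", "species", "agb_g_m2", "cover_pct",
                                   "lai", "height_cm"}
        assert len(df) == len(result.censuses)

    def test_builtin_mowing_fixture_loads(self):
        from importlib import resources
        ref = resources.files("grasspatch.data").joinpath("mowing_schedule_example.csv")
        import io
        df = read_mowing_csv(io.StringIO(ref.read_text()))
        assert len(df) == 14
        assert (df["cut_height_cm"] == 10).all()
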