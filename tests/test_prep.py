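import numpy as np
import pandas as pd
import pytest

from hybridevap.prep import (
    COVARIATES,
    FEATURE_NAMES,
    build_feature_frame,
    build_training_table,
    crown_area,
    filter_rain_days,
    partition_et,
    seasonal_anomaly,
    stress_target,
    upscale_sapflow,
)


class TestPartitionEt:
    def test_no_leaves_no_transpiration(self):
        assert partition_et(3.0, 0.0) == 0.0

    def test_dense_canopy_saturates_to_total(self):
        assert partition_et(3.0, 50.0) == pytest.approx(3.0, rel=1e-8)

    def test_hand_value(self):
        assert partition_et(3.0, 2.0, k=0.6) == pytest.approx(3.0 * (1 - np.exp(-1.2)))

    def test_negative_lai_rejected(self):
        with pytest.raises(ValueError):
            partition_et(1.0, -0.5)


class TestFilterRainDays:
    def test_all_dry_unchanged(self):
        df = pd.DataFrame({"P": [0.0, 0.1, 0.0]})
        out, counts = filter_rain_days(df)
        assert len(out) == 3 and counts == {"retained": 3, "removed": 0}

    def test_counting_oracle(self):
        df = pd.DataFrame({"P": [0, 5, 0, 2, 0, 0, 1, 0, 0, 0]}, dtype=float)
        out, counts = filter_rain_days(df)
        assert counts == {"retained": 7, "removed": 3}
        assert (out["P"] <= 0.5).all()

    def test_infinite_threshold_keeps_everything(self):
        df = pd.DataFrame({"P": [0.0, 100.0]})
        out, counts = filter_rain_days(df, rain_threshold_mm=np.inf)
        assert counts["removed"] == 0


class TestStressTarget:
    @pytest.mark.parametrize("et,ept,expected", [(4.0, 4.0, 1.0), (0.0, 4.0, 0.0), (2.0, 4.0, 0.5)])
    def test_ratio_values(self, et, ept, expected):
        st, valid = stress_target(np.array([et]), np.array([ept]))
        assert valid[0] and st[0] == pytest.approx(expected)

    def test_clamped_above_potential(self):
        st, _ = stress_target(np.array([5.0]), np.array([4.0]))
        assert st[0] == 1.0

    def test_near_zero_potential_dropped_not_failed(self):
        st, valid = stress_target(np.array([1.0, 1.0]), np.array([0.05, 2.0]))
        assert not valid[0] and valid[1]
        assert np.isnan(st[0])


class TestCrownArea:
    def test_unit_tree_reference(self):
        assert crown_area(1.0, 0.0, 0.0) == pytest.approx(np.exp(-2.53), rel=1e-6)

    def test_hand_value_temperate_site(self):
        # exp(-2.53 + 0.602*ln 0.05 + 0.096*10 - 5.48e-5*800) ~ 0.0328? see below
        expected = np.exp(-2.53 + 0.602 * np.log(0.05) + 0.0960 * 10 - 5.48e-5 * 800)
        assert crown_area(0.05, 10.0, 800.0) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.0328, abs=5e-4)

    def test_nonpositive_basal_area_rejected(self):
        with pytest.raises(ValueError):
            crown_area(0.0, 10.0, 800.0)


def _sapflow_table(flows_by_species):
    """Single-day table: flows_by_species maps species -> list of
    (A_b, daily_volume_cm3); volumes given as one 24 h row."""
    recs = []
    i = 0
    for sp, trees in flows_by_species.items():
        for ab, vol in trees:
            recs.append(("2020-06-01", f"t{i}", sp, ab, vol))
            i += 1
    return pd.DataFrame(recs, columns=["date", "tree_id", "species", "A_b", "sapflow_cm3h"])


class TestUpscaleSapflow:
    MAT, MAP = 0.0, 0.0  # crown area = exp(-2.53 + 0.602 ln A_b)

    def test_identical_trees_equal_single_tree(self):
        one = upscale_sapflow(_sapflow_table({"oak": [(0.05, 500.0)]}), self.MAT, self.MAP)
        many = upscale_sapflow(
            _sapflow_table({"oak": [(0.05, 500.0)] * 4}), self.MAT, self.MAP
        )
        assert many.iloc[0] == pytest.approx(one.iloc[0])

    def test_basal_area_weighted_species_mean(self):
        """Two species with basal-area weights 0.75/0.25 and per-crown flows
        2 and 4 mm/day give a stand value of 2.5 mm/day."""
        ac = lambda ab: crown_area(ab, self.MAT, self.MAP)
        table = _sapflow_table(
            {
                "a": [(0.3, 2.0 / 1e-3 * ac(0.3))],  # 2 mm/day per crown area
                "b": [(0.1, 4.0 / 1e-3 * ac(0.1))],  # 4 mm/day
            }
        )
        out = upscale_sapflow(table, self.MAT, self.MAP)
        assert out.iloc[0] == pytest.approx(0.75 * 2.0 + 0.25 * 4.0)

    def test_invariant_to_row_order_and_labels(self):
        table = _sapflow_table({"a": [(0.3, 900.0), (0.2, 700.0)], "b": [(0.1, 300.0)]})
        shuffled = table.sample(frac=1.0, random_state=1)
        relabeled = table.replace({"a": "x", "b": "y"})
        base = upscale_sapflow(table, self.MAT, self.MAP).iloc[0]
        assert upscale_sapflow(shuffled, self.MAT, self.MAP).iloc[0] == pytest.approx(base)
        assert upscale_sapflow(relabeled, self.MAT, self.MAP).iloc[0] == pytest.approx(base)

    def test_missing_basal_area_dropped_with_warning(self):
        table = _sapflow_table({"a": [(0.3, 900.0), (0.2, 700.0)]})
        table.loc[1, "A_b"] = np.nan
        with pytest.warns(UserWarning):
            out = upscale_sapflow(table, self.MAT, self.MAP)
        expected = upscale_sapflow(_sapflow_table({"a": [(0.3, 900.0)]}), self.MAT, self.MAP)
        assert out.iloc[0] == pytest.approx(expected.iloc[0])

    def test_roundtrip_with_generator(self):
        """Upscaling a generated per-tree table recovers the stand
        transpiration the generator used."""
        from hybridevap.synthetic import SiteMeta, generate_sapflow_table

        site = SiteMeta(mat_C=10.0, map_mm=800.0)
        table, series = generate_sapflow_table(n_trees=4, n_days=20, site=site, seed=3)
        stand = upscale_sapflow(table, site.mat_C, site.map_mm)
        np.testing.assert_allclose(
            stand.to_numpy(), series["E_t_true"].to_numpy(), atol=1e-10
        )


class TestSeasonalAnomaly:
    def _series(self, values, start="2015-01-01"):
        return pd.Series(values, index=pd.date_range(start, periods=len(values), freq="D"))

    def test_constant_series_gives_zero(self):
        s = self._series(np.full(800, 5.0))
        np.testing.assert_allclose(seasonal_anomaly(s), 0.0, atol=1e-12)

    def test_repeating_sinusoid_near_zero(self):
        doy = pd.date_range("2015-01-01", periods=1460, freq="D").dayofyear
        s = self._series(np.sin(2 * np.pi * doy / 365.25))
        # the 31-day window slightly attenuates the harmonic; anomalies stay small
        assert np.abs(seasonal_anomaly(s)).max() < 0.05

    def test_additive_spike_recovered(self):
        doy = pd.date_range("2015-01-01", periods=1095, freq="D").dayofyear.to_numpy()
        base = 10 + 3 * np.sin(2 * np.pi * doy / 365.25)
        vals = base.copy()
        vals[500] += 7.0  # one-day excursion
        anom = seasonal_anomaly(self._series(vals))
        assert anom.iloc[500] == pytest.approx(7.0, abs=0.3)

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            seasonal_anomaly(self._series(np.arange(100.0)))


class TestFeatureFrame:
    def test_ordering_and_constant_anomalies(self):
        idx = pd.date_range("2015-01-01", periods=800, freq="D")
        rng = np.random.default_rng(0)
        drivers = pd.DataFrame({c: rng.random(800) for c in COVARIATES}, index=idx)
        drivers["CO2"] = 400.0  # constant driver -> zero anomaly
        feats = build_feature_frame(drivers)
        assert list(feats.columns) == list(FEATURE_NAMES)
        np.testing.assert_allclose(feats["CO2_anom"], 0.0, atol=1e-12)

    def test_noise_free_world_targets_equal_truth(self):
        """With zero observation noise and no potential-transpiration
        distortion, the stress-target pipeline returns the ground-truth
        stress exactly on every retained day."""
        from hybridevap.metrics import kge
        from hybridevap.soil import SoilParams
        from hybridevap.synthetic import TruthStressSpec, generate_forcing, generate_observations

        forcing = generate_forcing(5, 1095)
        series = generate_observations(
            forcing,
            TruthStressSpec(noise_sd_mm=0.0),
            SoilParams.tall(),
            seed=6,
            interception_coef=0.0,
        )
        tab = build_training_table(
            series.rename(columns={"E_obs": "E_t"}),
            ept_scaling="none",
            already_transpiration=True,
        )
        truth = series.loc[tab.index, "S_t_true"]
        np.testing.assert_allclose(tab["S_t_target"], truth, atol=1e-12)
        assert kge(tab["S_t_target"], truth).kge == pytest.approx(1.0, abs=1e-12)
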