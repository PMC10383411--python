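import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paddyrisk.soil_spectral import (GREEN_MINUS_RED, FeatureSpec,
                                     build_feature_table, feature_inventory,
                                     fertility_mesh_map, fit_san_model, ndi,
                                     ndvi_raster, predict_san_raster,
                                     screen_features)
from paddyrisk.raster_core import FieldBoundary, Raster, make_mesh_grid
from paddyrisk.synthetic_data import (SAN_INTERCEPT, SAN_SLOPE, FieldConfig,
                                      generate_san_field, render_bands,
                                      sample_points)

from conftest import make_raster, oracle_circle_mean

positive_dn = st.floats(min_value=1.0, max_value=1e5)


class TestNdi:
    def test_equal_bands_give_zero(self):
        assert ndi(1234.0, 1234.0) == 0.0

    def test_three_to_one_gives_half(self):
        assert ndi(3.0, 1.0) == pytest.approx(0.5)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            ndi(1.0, -1.0)

    @given(positive_dn, positive_dn)
    @settings(derandomize=True, max_examples=100)
    def test_antisymmetric_and_bounded(self, a, b):
        v = ndi(a, b)
        assert -1.0 <= v <= 1.0
        assert v == pytest.approx(-ndi(b, a))


class TestNdviRaster:
    def test_equal_bands_give_zero_everywhere(self, rng):
        band = make_raster(rng.uniform(100, 200, (4, 4)))
        assert np.allclose(ndvi_raster(band, band).values, 0.0)

    def test_triple_nir_gives_half(self):
        red = make_raster(np.full((3, 3), 500.0))
        nir = make_raster(np.full((3, 3), 1500.0))
        assert np.allclose(ndvi_raster(nir, red).values, 0.5)

    def test_nodata_propagates(self):
        mask = np.zeros((2, 2), dtype=bool)
        mask[1, 1] = True
        red = Raster(np.full((2, 2), 500.0), 1.0, (0, 2), mask)
        nir = make_raster(np.full((2, 2), 800.0))
        out = ndvi_raster(nir, red)
        assert out.nodata_mask[1, 1] and not out.nodata_mask[0, 0]


class TestFeatureInventory:
    def test_twenty_eight_features_in_family_blocks(self):
        inv = feature_inventory()
        assert len(inv) == 28
        by_family = pd.Series([f.family for f in inv]).value_counts()
        assert by_family["single"] == 4
        assert (by_family[["difference", "sum", "ratio", "ndi"]] == 6).all()
        assert len({f.name for f in inv}) == 28

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            FeatureSpec("difference", "red", "red")
        with pytest.raises(ValueError):
            FeatureSpec("single", "red", "nir")
        with pytest.raises(ValueError):
            FeatureSpec("magic", "red", "nir")


class TestFeatureTable:
    @pytest.fixture
    def flat_bands(self):
        return {b: make_raster(np.full((30, 30), 1000.0), cell_size=0.1)
                for b in ("green", "red", "red_edge", "nir")}

    def test_constant_bands_give_trivial_features(self, flat_bands):
        samples = pd.DataFrame({"id": [0], "x": [1.5], "y": [1.5],
                                "san": [150.0]})
        table = build_feature_table(flat_bands, samples, radius=0.5)
        for spec in feature_inventory():
            if spec.family == "difference":
                assert table[spec.name].iloc[0] == 0.0
            elif spec.family == "sum":
                assert table[spec.name].iloc[0] == 2000.0
            elif spec.family == "ratio":
                assert table[spec.name].iloc[0] == 1.0
            elif spec.family == "ndi":
                assert table[spec.name].iloc[0] == 0.0

    def test_buffer_means_match_oracle(self, small_config):
        san = generate_san_field(small_config)
        bands, _ = render_bands(san, small_config)
        samples = sample_points(san, small_config).head(5)
        table = build_feature_table(bands, samples, radius=0.5)
        for k, rec in enumerate(samples.itertuples(index=False)):
            for name in ("green", "nir"):
                expected, _ = oracle_circle_mean(bands[name], rec.x, rec.y, 0.5)
                assert table[f"dn_{name}"].iloc[k] == pytest.approx(expected)

    def test_empty_buffer_names_the_sample(self, flat_bands):
        samples = pd.DataFrame({"id": [7], "x": [250.0], "y": [250.0],
                                "san": [150.0]})
        with pytest.raises(Exception, match="sample 7"):
            build_feature_table(flat_bands, samples, radius=0.5)


class TestScreening:
    def _table_from(self, cfg):
        san = generate_san_field(cfg)
        bands, _ = render_bands(san, cfg)
        return build_feature_table(bands, sample_points(san, cfg), radius=0.5)

    def test_constructed_green_red_signal_ranks_first(self, small_config):
        table = self._table_from(small_config)
        ranked = screen_features(table, "san")
        assert ranked[0].feature.name == "green-red"
        assert ranked[0].pearson_cc < 0  # richer soil is darker in green-red

    def test_pure_noise_yields_weak_correlations(self):
        """35 samples of band-independent chemistry: max |cc| stays small."""
        rng = np.random.default_rng(7)
        exceed = 0
        for _ in range(20):
            table = pd.DataFrame({
                b: rng.uniform(500, 1500, 35)
                for b in ("green", "red", "red_edge", "nir")}).add_prefix("dn_")
            for spec in feature_inventory():
                if spec.family != "single":
                    table[spec.name] = spec.compute(
                        {b: table[f"dn_{b}"] for b in
                         ("green", "red", "red_edge", "nir")})
            table["san"] = rng.normal(140, 25, 35)
            top = screen_features(table, "san")[0]
            exceed += abs(top.pearson_cc) >= 0.5
        assert exceed <= 2  # ~95% of null draws stay below 0.5

    def test_perfectly_linear_feature_has_unit_correlation(self, small_config):
        table = self._table_from(small_config)
        table["san"] = 5.0 - 2.0 * table["green-red"]
        ranked = screen_features(table, "san")
        assert ranked[0].feature.name == "green-red"
        assert abs(ranked[0].pearson_cc) == pytest.approx(1.0)

    def test_invariant_to_affine_rescaling_of_chemistry(self, small_config):
        table = self._table_from(small_config)
        base = {r.feature.name: r.pearson_cc
                for r in screen_features(table, "san")}
        table["san"] = 3.7 * table["san"] + 11.0
        rescaled = {r.feature.name: r.pearson_cc
                    for r in screen_features(table, "san")}
        for name in base:
            assert rescaled[name] == pytest.approx(base[name])

    def test_constant_feature_recorded_as_missing(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({
            "dn_green": rng.uniform(900, 1100, 10),
            "dn_red": np.full(10, 1000.0),
            "dn_red_edge": rng.uniform(900, 1100, 10),
            "dn_nir": rng.uniform(900, 1100, 10),
            "san": rng.normal(140, 20, 10)})
        for spec in feature_inventory():
            if spec.family != "single":
                table[spec.name] = spec.compute(
                    {b: table[f"dn_{b}"] for b in
                     ("green", "red", "red_edge", "nir")})
        results = screen_features(table, "san")
        red_single = [r for r in results if r.feature.name == "red"]
        assert len(red_single) == 1 and np.isnan(red_single[0].pearson_cc)


class TestSanModel:
    def test_exact_line_recovered(self):
        table = pd.DataFrame({"green-red": [0.0, 1.0, 2.0],
                              "san": [5.0, 7.5, 10.0]})
        model = fit_san_model(table, GREEN_MINUS_RED)
        assert model.intercept == pytest.approx(5.0)
        assert model.slope == pytest.approx(2.5)
        assert model.r_squared == pytest.approx(1.0)

    def test_noise_free_inversion_recovers_published_coefficients(self):
        """Samples built by inverting the estimating equation give back the
        generating intercept and slope to six significant digits."""
        san = np.linspace(78.0, 200.0, 35)
        table = pd.DataFrame({"green-red": (SAN_INTERCEPT - san) / (-SAN_SLOPE),
                              "san": san})
        model = fit_san_model(table, GREEN_MINUS_RED)
        assert model.intercept == pytest.approx(287.86, rel=1e-6)
        assert model.slope == pytest.approx(-0.046, rel=1e-6)
        assert model.r_squared == pytest.approx(1.0)

    def test_parameter_recovery_under_default_noise(self):
        """At the reference field conditions the fitted equation stays
        within 10% of the generating coefficients despite measurement and
        band noise."""
        for seed in range(3):
            cfg = FieldConfig(seed=seed)
            san = generate_san_field(cfg)
            bands, _ = render_bands(san, cfg)
            table = build_feature_table(bands, sample_points(san, cfg), 0.5)
            model = fit_san_model(table, GREEN_MINUS_RED)
            assert model.intercept == pytest.approx(SAN_INTERCEPT, rel=0.10)
            assert model.slope == pytest.approx(SAN_SLOPE, rel=0.10)

    def test_constant_chemistry_flagged(self):
        table = pd.DataFrame({"green-red": [0.0, 1.0, 2.0],
                              "san": [5.0, 5.0, 5.0]})
        model = fit_san_model(table, GREEN_MINUS_RED)
        assert model.slope == pytest.approx(0.0)
        assert model.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_feature_rejected(self):
        table = pd.DataFrame({"green-red": [1.0, 1.0, 1.0],
                              "san": [5.0, 6.0, 7.0]})
        with pytest.raises(ValueError):
            fit_san_model(table, GREEN_MINUS_RED)


class TestPrediction:
    def _model(self):
        gr = np.array([0.0, 1000.0, 2000.0])
        table = pd.DataFrame({"green-red": gr,
                              "san": SAN_INTERCEPT + SAN_SLOPE * gr})
        return fit_san_model(table, GREEN_MINUS_RED)

    def test_published_coefficients_evaluate_correctly(self):
        model = self._model()
        green = make_raster(np.full((2, 2), 2910.0))
        red = make_raster(np.full((2, 2), 1000.0))  # green - red = 1910
        out = predict_san_raster(model, {"green": green, "red": red})
        assert np.allclose(out.values, 200.0, atol=1e-9)

    def test_zero_difference_returns_intercept(self):
        model = self._model()
        band = make_raster(np.full((2, 2), 1500.0))
        out = predict_san_raster(model, {"green": band, "red": band})
        assert np.allclose(out.values, 287.86)

    def test_nodata_propagates(self):
        model = self._model()
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 0] = True
        green = Raster(np.full((2, 2), 2000.0), 1.0, (0, 2), mask)
        red = make_raster(np.full((2, 2), 1000.0))
        out = predict_san_raster(model, {"green": green, "red": red})
        assert out.nodata_mask[0, 0] and not out.nodata_mask[1, 1]

    def test_missing_band_rejected(self):
        with pytest.raises(KeyError):
            predict_san_raster(self._model(),
                               {"green": make_raster(np.ones((2, 2)))})

    def test_roundtrip_reproduces_latent_surface_without_noise(self, small_config):
        """Fit on noise-free samples, predict: latent SAN comes back at the
        sampled pixels."""
        cfg = dataclasses.replace(small_config, noise_sd_san=0.0,
                                  noise_sd_band=0.0, red_spatial_sd=0.0,
                                  red_edge_spatial_sd=0.0)
        san = generate_san_field(cfg)
        bands, _ = render_bands(san, cfg)
        samples = sample_points(san, cfg)
        table = samples.copy()
        # per-pixel feature value at the exact sample pixel (no buffer smoothing)
        row, col = bands["green"].index_of(samples["x"].to_numpy(),
                                           samples["y"].to_numpy())
        table["green-red"] = (bands["green"].values[row, col]
                              - bands["red"].values[row, col])
        model = fit_san_model(table, GREEN_MINUS_RED)
        pred = predict_san_raster(model, bands)
        assert np.allclose(pred.values[row, col], samples["latent_san"],
                           atol=1e-6)


class TestFertilityMap:
    def test_constant_field_all_in_optimum(self):
        san = make_raster(np.full((12, 12), 156.0), cell_size=0.5)
        grid = make_mesh_grid(FieldBoundary.rectangle(6, 6), 1.0, 2.0)
        out = fertility_mesh_map(san, grid)
        assert np.allclose(out["san_est"], 156.0)
        assert out["in_optimum"].all()

    def test_excess_nitrogen_flagged(self):
        san = make_raster(np.full((12, 12), 220.0), cell_size=0.5)
        grid = make_mesh_grid(FieldBoundary.rectangle(6, 6), 1.0, 0.0)
        out = fertility_mesh_map(san, grid)
        assert not out["in_optimum"].any()
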