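import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from isoprov.locality import (
    DeltaTable,
    classify_local,
    compute_deltas,
    delta_group_tests,
    extract_buffered,
    forest_cover_regression,
    group_difference_test,
    scan_buffer_radius,
)
from isoprov.raster import haversine_km
from isoprov.synthetic import simulate_individuals

from .conftest import toy_raster


def brute_force_buffer(raster, lon, lat, radius_km):
    lon2d, lat2d = raster.cell_centers()
    d = haversine_km(lon, lat, lon2d, lat2d)
    inside = d <= radius_km
    if not inside.any():  # fallback contract: the containing cell
        return raster.value_at(lon, lat)
    vals = raster.values[inside & np.isfinite(raster.values)]
    return float(vals.mean()) if vals.size else np.nan


class TestExtractBuffered:
    def test_tiny_radius_falls_back_to_containing_cell(self):
        r = toy_raster(np.arange(16, dtype=float).reshape(4, 4))
        lon, lat = r.transform.cell_center(2, 3)
        # evaluate slightly off-center so no cell center is within 100 m
        assert extract_buffered(r, lon + 0.02, lat + 0.02, 0.1) == r.values[2, 3]

    def test_constant_raster_any_radius(self, constant_raster):
        for radius in (0.5, 5, 50):
            assert extract_buffered(constant_raster, 10.3, 59.7, radius) == 0.715

    def test_two_cell_toy_mean(self):
        r = toy_raster(np.array([[0.710, 0.730]]))
        lon, lat = r.transform.cell_center(0, 0)
        got = extract_buffered(r, lon, lat, 20.0)
        assert got == pytest.approx(0.720)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        vals = rng.uniform(0.70, 0.76, (15, 15))
        vals[3, 4] = np.nan
        r = toy_raster(vals, x0=12.0, y0=64.0, cell=0.12)
        for _ in range(25):
            lon = rng.uniform(12.1, 13.6)
            lat = rng.uniform(62.5, 63.9)
            radius = rng.uniform(1, 120)
            assert extract_buffered(r, lon, lat, radius) == pytest.approx(
                brute_force_buffer(r, lon, lat, radius)
            )

    def test_off_grid_rejected_and_all_nodata_flagged(self):
        r = toy_raster(np.full((4, 4), np.nan))
        with pytest.raises(ValueError, match="outside"):
            extract_buffered(r, 50.0, 50.0, 5.0)
        with pytest.warns(UserWarning, match="nodata"):
            assert np.isnan(extract_buffered(r, 10.2, 59.8, 5.0))


class TestComputeDeltas:
    def _samples(self, values_sr, values_o, lon, lat):
        n = len(values_sr)
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "lon": lon,
                "lat": lat,
                "sr87_86": values_sr,
                "d18O_water_vsmow": values_o,
            }
        )

    def test_zero_delta_when_sample_equals_surface(self, constant_raster):
        o = toy_raster(np.full((8, 8), -12.0))
        s = self._samples([0.715] * 4, [-12.0] * 4, [10.3] * 4, [59.6] * 4)
        dt = compute_deltas(s, constant_raster, o, 5.0)
        np.testing.assert_allclose(dt.per_sample["delta_sr"], 0.0)
        np.testing.assert_allclose(dt.per_sample["delta_o"], 0.0)

    def test_affine_equivariance_constant_shift(self, constant_raster):
        o = toy_raster(np.full((8, 8), -12.0))
        s = self._samples([0.712, 0.716, 0.72], [-13.0, -12.0, -11.0], [10.3] * 3, [59.6] * 3)
        base = compute_deltas(s, constant_raster, o, 5.0)
        shifted = s.copy()
        shifted["sr87_86"] += 0.01
        got = compute_deltas(shifted, constant_raster, o, 5.0)
        np.testing.assert_allclose(
            got.per_sample["delta_sr"], base.per_sample["delta_sr"] + 0.01
        )


class TestScanRadius:
    def test_single_radius_returned(self, small_truth, small_individuals):
        best, table = scan_buffer_radius(
            small_individuals, small_truth.sr_field, [10.0]
        )
        assert best == 10.0 and len(table) == 1

    def test_r2_bounded_and_best_within_correlation_length(self, small_truth):
        # locals sampled at cell scale: averaging beyond the field's
        # correlation length degrades the fit
        ind = simulate_individuals(small_truth, 150, 0.0, 0.0, seed=41)
        radii = [2.0, 10.0, 50.0, 150.0, 400.0]
        best, table = scan_buffer_radius(ind, small_truth.sr_field, radii)
        assert (table["r2"] <= 1.0).all()
        assert best <= small_truth.correlation_length_km

    def test_classification_shift_invariance(self, small_truth):
        # adding a constant to samples AND isoscape leaves flags unchanged
        ind = simulate_individuals(small_truth, 60, 0.2, 300.0, seed=42)
        sr2 = small_truth.sr_field.copy_with(small_truth.sr_field.values + 0.005)
        o = small_truth.o_field
        base = classify_local(compute_deltas(ind, small_truth.sr_field, o, 10.0))
        shifted_samples = ind.copy()
        shifted_samples["sr87_86"] += 0.005
        moved = classify_local(compute_deltas(shifted_samples, sr2, o, 10.0))
        np.testing.assert_array_equal(
            base.per_sample["local_flag"], moved.per_sample["local_flag"]
        )


class TestClassifyLocal:
    def _delta_table(self, deltas_sr, deltas_o=None):
        n = len(deltas_sr)
        deltas_o = deltas_o if deltas_o is not None else [0.0] * n
        per = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "delta_sr": deltas_sr,
                "delta_o": deltas_o,
                "buffered_sr": 0.71,
                "buffered_o": -12.0,
                "local_flag": True,
            }
        )
        return DeltaTable(
            per_sample=per,
            mean_sr=float(np.mean(deltas_sr)),
            sd_sr=float(np.std(deltas_sr, ddof=1)),
            mean_o=float(np.mean(deltas_o)),
            sd_o=float(np.std(deltas_o, ddof=1)),
            radius_km=10.0,
        )

    def test_identical_deltas_all_local_with_warning(self):
        dt = self._delta_table([0.1] * 5)
        with pytest.warns(UserWarning, match="identical"):
            out = classify_local(dt)
        assert out.per_sample["local_flag"].all()

    def test_single_extreme_sample_flagged(self):
        # nine zeros and one ten: mean 1, SD sqrt(10) ~ 3.16; only the
        # extreme sample is outside one SD
        dt = self._delta_table([0.0] * 9 + [10.0])
        out = classify_local(dt)
        flags = out.per_sample["local_flag"].to_numpy()
        assert flags[:9].all() and not flags[9]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            classify_local(self._delta_table([0.0, 1.0]))

    def test_detection_performance_on_simulated_mixture(self, small_truth):
        # displacement 3x the landscape correlation length, tissue Sr noise
        # equal to the field noise; averaged over 10 replicates
        from isoprov.isoscape import fit_isoscape, predict_surface
        from isoprov.synthetic import sample_training_points

        tr = sample_training_points(small_truth, 200, 0.002, seed=50)
        model = fit_isoscape(tr, small_truth.predictor_stack, ["geo_proxy"], 300, 4)
        sr = predict_surface(model, small_truth.predictor_stack)
        disp = 3 * small_truth.correlation_length_km
        sens, spec = [], []
        for rep in range(10):
            ind = simulate_individuals(small_truth, 200, 0.15, disp, seed=900 + rep)
            dt = classify_local(compute_deltas(ind, sr, small_truth.o_field, 10.0))
            per = dt.per_sample.merge(ind, on="sample_id")
            nl = ~per["is_local"]
            fl = ~per["local_flag"]
            sens.append((fl & nl).sum() / nl.sum())
            spec.append((~fl & ~nl).sum() / (~nl).sum())
        assert np.mean(sens) >= 0.6
        assert np.mean(spec) >= 0.8


class TestMannWhitney:
    def test_identical_groups_exact_p_one(self):
        u, p = group_difference_test([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert p == pytest.approx(1.0)

    def test_complete_separation_u_zero(self):
        u, p = group_difference_test([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert u == 0.0

    def test_rank_sum_identity(self):
        rng = np.random.default_rng(8)
        vals = rng.integers(0, 5, 12).astype(float)
        labels = ["a"] * 5 + ["b"] * 7
        u_a, _ = group_difference_test(vals, labels)
        u_b, _ = group_difference_test(vals, labels[::-1])  # swap group roles
        # recompute directly with the identity U_A + U_B = n_A * n_B
        ranks = sps.rankdata(vals)
        u_first = ranks[:5].sum() - 5 * 6 / 2
        assert u_first + (5 * 7 - u_first) == 35

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.5, 1, 7)
        u, p = group_difference_test(
            np.concatenate([a, b]), ["a"] * 6 + ["b"] * 7
        )
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_groups_use_tie_corrected_normal(self):
        rng = np.random.default_rng(13)
        a = rng.integers(0, 4, 20).astype(float)
        b = rng.integers(1, 5, 25).astype(float)
        u, p = group_difference_test(np.concatenate([a, b]), ["a"] * 20 + ["b"] * 25)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_difference_test([1.0, 2.0], ["a", "a"])


class TestGroupSuiteAndForestCover:
    def test_delta_group_tests_runs_standard_comparisons(self, small_truth, small_individuals):
        dt = compute_deltas(small_individuals, small_truth.sr_field, small_truth.o_field, 10.0)
        table = delta_group_tests(dt, small_individuals)
        assert {"sex_all", "tissue_all"} <= set(table["comparison"])
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()

    def test_exact_linear_cover_gives_r2_one(self):
        rng = np.random.default_rng(2)
        cover = toy_raster(rng.uniform(0, 90, (10, 10)), cell=0.05)
        lon2d, lat2d = cover.cell_centers()
        idx = rng.choice(100, 12, replace=False)
        lons, lats = lon2d.ravel()[idx], lat2d.ravel()[idx]
        cov_at = np.array([extract_buffered(cover, lo, la, 0.1) for lo, la in zip(lons, lats)])
        samples = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(12)],
                "lon": lons,
                "lat": lats,
                "tissue": ["bone"] * 6 + ["antler"] * 6,
                "d13C_vpdb_1994": -20 + 0.05 * cov_at,
            }
        )
        res = forest_cover_regression(samples, cover, radius_km=0.1)
        combined = res[res["group"] == "combined"].iloc[0]
        assert combined["r2"] == pytest.approx(1.0)
        assert combined["slope"] == pytest.approx(0.05)

    def test_constant_cover_rejected(self):
        cover = toy_raster(np.full((10, 10), 40.0), cell=0.05)
        samples = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "d"],
                "lon": [10.1, 10.2, 10.3, 10.35],
                "lat": [59.8, 59.7, 59.6, 59.75],
                "tissue": ["bone"] * 4,
                "d13C_vpdb_1994": [-15.0, -14.0, -16.0, -15.5],
            }
        )
        with pytest.raises(ValueError, match="constant"):
            forest_cover_regression(samples, cover, radius_km=1.0)
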