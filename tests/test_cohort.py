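"""Synthetic-cohort generator: field statistics, geometry, determinism."""

import numpy as np
import pytest

import slidesample as ss
from slidesample.cohort import (
    DEFAULT_CROSS_TYPE_CORRELATION,
    elliptical_foreground,
    lag1_autocorrelation,
    nearest_correlation_psd,
)
from slidesample.profiling import CELL_TYPES, tile_area_factor


class TestIntensityField:
    def test_zero_density_gives_zero_field(self):
        field = ss.generate_intensity_field(
            (20, 20), 2.0, mean_density=[0, 0, 0, 0], seed=0
        )
        assert np.all(field == 0)

    def test_uncorrelated_field_has_no_lag1_autocorrelation(self):
        # correlation_length 0: tiles are independent draws
        rs = [
            lag1_autocorrelation(
                ss.generate_intensity_field((100, 100), 0.0, seed=s)[0]
            )
            for s in range(5)
        ]
        assert all(abs(r) < 0.05 for r in rs)

    def test_field_mean_recovers_epithelial_density(self):
        # log-normal mean correction: E[field] = mean density exactly
        means = [
            ss.generate_intensity_field((100, 100), 1.0, seed=s)[0].mean()
            for s in range(5)
        ]
        assert abs(np.mean(means) - 21.3) / 21.3 < 0.02

    def test_autocorrelation_monotone_in_correlation_length(self):
        lengths = [0.0, 1.0, 2.0, 4.0]
        mean_r = []
        for L in lengths:
            rs = [
                lag1_autocorrelation(
                    ss.generate_intensity_field((60, 60), L, seed=100 + s)[0]
                )
                for s in range(5)
            ]
            mean_r.append(np.mean(rs))
        assert all(b >= a - 0.02 for a, b in zip(mean_r, mean_r[1:]))
        assert mean_r[-1] > 0.5  # strongly correlated at 4 tiles

    def test_field_nonnegative(self):
        field = ss.generate_intensity_field((30, 30), 2.0, seed=3)
        assert np.all(field >= 0)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            ss.generate_intensity_field((0, 10), 1.0)
        with pytest.raises(ValueError):
            ss.generate_intensity_field((10, 10), -1.0)
        with pytest.raises(ValueError):
            ss.generate_intensity_field((10, 10), 1.0, mean_density=[1, 2, 3])


class TestCorrelationRepair:
    def test_psd_matrix_unchanged(self):
        out = nearest_correlation_psd(DEFAULT_CROSS_TYPE_CORRELATION)
        assert np.allclose(out, DEFAULT_CROSS_TYPE_CORRELATION)

    def test_repair_preserves_signs_or_raises(self):
        # a slightly indefinite matrix that a sign-respecting repair can fix
        bad = np.array(
            [
                [1.0, 0.9, -0.9, 0.0],
                [0.9, 1.0, -0.1, 0.0],
                [-0.9, -0.1, 1.0, 0.0],
                [0.0, 0.0, 0.0, 1.0],
            ]
        )
        fixed = nearest_correlation_psd(bad)
        assert np.linalg.eigvalsh(fixed).min() >= 0
        assert np.allclose(np.diag(fixed), 1.0)
        off = ~np.eye(4, dtype=bool)
        same_sign = np.sign(fixed[off]) == np.sign(bad[off])
        assert np.all(same_sign | (np.abs(bad[off]) < 1e-8))

    def test_unrepairable_target_raises(self):
        # indefinite, with a weak entry whose sign flips under clipping
        hostile = np.array(
            [
                [1.0, -0.891, -0.42, 0.454],
                [-0.891, 1.0, -0.007, 0.228],
                [-0.42, -0.007, 1.0, -0.27],
                [0.454, 0.228, -0.27, 1.0],
            ]
        )
        with pytest.raises(ValueError):
            nearest_correlation_psd(hostile)


class TestForegroundGeometry:
    def test_exact_tile_count_and_connectivity(self, rng):
        mask = elliptical_foreground((30, 30), 400, rng)
        assert mask.sum() == 400
        from scipy import ndimage

        _, n_components = ndimage.label(mask)
        assert 1 <= n_components <= 4  # one or a few blobs

    def test_capacity_exceeded_raises(self, rng):
        with pytest.raises(ValueError):
            elliptical_foreground((5, 5), 26, rng)

    def test_config_capacity_check(self):
        with pytest.raises(ValueError):
            ss.CohortConfig(grid_shape=(10, 10), target_foreground_tiles=101)


class TestGenerateSlide:
    def test_determinism_bit_identical(self, small_config):
        a = ss.generate_slide(small_config, 3, seed=9)
        b = ss.generate_slide(small_config, 3, seed=9)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.tile_grid.tissue, b.tile_grid.tissue)
        r, c = a.tile_grid.usable_tiles()[0]
        ma, mb = a.cell_map(r, c), b.cell_map(r, c)
        assert np.array_equal(ma.x, mb.x) and np.array_equal(ma.labels, mb.labels)

    def test_foreground_tile_count_matches_target(self, small_slide, small_config):
        assert small_slide.tile_grid.n_F == small_config.target_foreground_tiles

    def test_no_artifacts_means_all_foreground_processable(self, small_slide):
        assert small_slide.tile_grid.n_usable == small_slide.tile_grid.n_F
        for r, c in small_slide.tile_grid.usable_tiles()[:5]:
            small_slide.cell_map(r, c)  # does not raise

    def test_artifact_tiles_carry_no_cell_maps(self):
        cfg = ss.CohortConfig(
            n_slides=1, grid_shape=(10, 10), target_foreground_tiles=80,
            artifact_fraction=0.4,
        )
        slide = ss.generate_slide(cfg, 0, seed=5)
        grid = slide.tile_grid
        assert 0 < grid.n_artifact < grid.n_F
        r, c = grid.tiles_where(grid.artifact)[0]
        with pytest.raises(ValueError):
            slide.cell_map(r, c)
        assert np.all(slide.counts[grid.artifact] == 0)

    def test_background_tile_has_no_cell_map(self, small_slide):
        bg = np.argwhere(~small_slide.tile_grid.tissue)[0]
        with pytest.raises(ValueError):
            small_slide.cell_map(int(bg[0]), int(bg[1]))

    def test_cell_coordinates_within_tile(self, small_slide):
        r, c = small_slide.tile_grid.usable_tiles()[0]
        cm = small_slide.cell_map(r, c)
        P = small_slide.tile_grid.patch_size_px
        assert np.all((cm.x >= 0) & (cm.x < P))
        assert np.all((cm.y >= 0) & (cm.y < P))

    def test_expected_cells_per_tile_is_density_times_area(self):
        # 500 px at 0.5 µm/px is a 250-µm tile: 6.25 hundred-µm squares
        assert tile_area_factor(500, 0.5) == pytest.approx(6.25)
        cfg = ss.CohortConfig(
            n_slides=1, grid_shape=(40, 40), target_foreground_tiles=1500,
            spatial_log_sd=0.0, slide_log_sd=0.0, correlation_length=0.0,
        )
        slide = ss.generate_slide(cfg, 0, seed=21)
        counts = slide.counts[slide.tile_grid.usable]
        lam = 21.3 * 6.25
        se = np.sqrt(lam / counts.shape[0])
        assert abs(counts[:, 0].mean() - lam) < 3 * se


class TestClinicalCohort:
    def test_cohort_size_and_labels(self, small_config):
        cfg = ss.CohortConfig(
            n_slides=10, grid_shape=(10, 10), target_foreground_tiles=60,
            clinical_effects=(ss.ClinicalEffect("grp", 0.3),),
        )
        slides, clinical = ss.generate_clinical_cohort(cfg, seed=4)
        assert len(slides) == 10
        assert set(clinical["grp"]) == {"0", "1"}
        assert (clinical["grp"] == "1").sum() == 3  # exact allocation

    def test_effect_recovers_group_mean_densities(self):
        cfg = ss.CohortConfig(
            n_slides=141, grid_shape=(16, 16), target_foreground_tiles=200,
            clinical_effects=(ss.metastasis_effect(),), slide_log_sd=0.1,
        )
        slides, clinical = ss.generate_clinical_cohort(cfg, seed=8)
        prof = ss.cohort_profiles(slides)
        fib = prof["fibroblast"]
        m0 = fib[clinical["metastasis"] == "M0"]
        m1 = fib[clinical["metastasis"] == "M1"]
        assert len(m0) == 120 and len(m1) == 21
        for observed, target in ((m0, 5.3), (m1, 7.7)):
            se = observed.std(ddof=1) / np.sqrt(len(observed))
            assert abs(observed.mean() - target) < 3 * se

    def test_null_effect_groups_symmetric(self):
        cfg = ss.CohortConfig(
            n_slides=80, grid_shape=(12, 12), target_foreground_tiles=100,
            clinical_effects=(ss.ClinicalEffect("coin", 0.5),),
        )
        slides, clinical = ss.generate_clinical_cohort(cfg, seed=13)
        prof = ss.cohort_profiles(slides)
        for t in CELL_TYPES:
            g0 = prof.loc[clinical["coin"] == "0", t]
            g1 = prof.loc[clinical["coin"] == "1", t]
            pooled_se = np.sqrt(
                g0.var(ddof=1) / len(g0) + g1.var(ddof=1) / len(g1)
            )
            assert abs(g0.mean() - g1.mean()) < 3 * pooled_se

    def test_mean_density_recovery_on_cohort(self):
        cfg = ss.CohortConfig(
            n_slides=142, grid_shape=(14, 14), target_foreground_tiles=150
        )
        slides, _ = ss.generate_clinical_cohort(cfg, seed=3)
        prof = ss.cohort_profiles(slides)
        for j, t in enumerate(CELL_TYPES):
            se = prof[t].std(ddof=1) / np.sqrt(len(prof))
            assert abs(prof[t].mean() - cfg.mean_density[j]) < 3 * se

    def test_cross_type_correlation_signs(self):
        # signs distinguishable from zero at this size (|target| >= 0.2)
        cfg = ss.CohortConfig(
            n_slides=300, grid_shape=(12, 12), target_foreground_tiles=100
        )
        slides, _ = ss.generate_clinical_cohort(cfg, seed=2)
        corr = ss.cell_correlation_matrix(ss.cohort_profiles(slides))
        target = DEFAULT_CROSS_TYPE_CORRELATION
        for i in range(4):
            for j in range(i + 1, 4):
                if abs(target[i, j]) >= 0.2:
                    assert np.sign(corr.iloc[i, j]) == np.sign(target[i, j])
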