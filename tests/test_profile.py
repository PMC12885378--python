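"""Multi-Otsu masking, A-P profiles, region ratios, bootstrap profiles."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from skimage.filters import threshold_multiotsu

from larvalight.phantom import PhantomConfig, generate_snapshot, generate_transcript_table
from larvalight.profile import (
    APProfile,
    ap_profile,
    bootstrap_ap_transcript_profile,
    extract_signal_mask,
    normalize_and_average,
    region_ratios,
)


def oracle_multiotsu(image, nbins):
    """Exhaustive 2-threshold search maximising between-class variance on an
    ``nbins``-bin histogram (same binning convention as the histogram-based
    implementation)."""
    hist, edges = np.histogram(image.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    p = hist / hist.sum()
    best, best_var = None, -1.0
    for i, j in itertools.combinations(range(1, nbins), 2):
        var = 0.0
        for sel in (slice(0, i), slice(i, j), slice(j, nbins)):
            w = p[sel].sum()
            if w > 0:
                mu = (p[sel] * centers[sel]).sum() / w
                var += w * mu**2
        if var > best_var:
            best_var, best = var, (centers[i - 1], centers[j - 1])
    return best


class TestExtractSignalMask:
    def test_three_level_image_masks_top_third(self):
        img = np.ones((30, 90))
        img[:, 30:60] = 100.0
        img[:, 60:] = 10000.0
        mask, thresholds = extract_signal_mask(img)
        expected = np.zeros_like(img, dtype=bool)
        expected[:, 60:] = True
        np.testing.assert_array_equal(mask, expected)
        assert len(thresholds) == 2

    def test_thresholds_match_exhaustive_search(self, rng):
        img = np.log1p(rng.choice([1.0, 100.0, 10000.0], size=(40, 40), p=[0.5, 0.3, 0.2]))
        ours = threshold_multiotsu(img, classes=3, nbins=64)
        oracle = oracle_multiotsu(img, nbins=64)
        np.testing.assert_allclose(ours, oracle, atol=np.ptp(img) / 64)

    def test_constant_image_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            extract_signal_mask(np.full((20, 20), 3.0))

    def test_negative_projection_raises(self):
        with pytest.raises(ValueError, match="nonnegative"):
            extract_signal_mask(np.full((5, 5), -1.0))

    def test_phantom_mask_covers_bright_cells_not_background(self, small_config):
        image, truth = generate_snapshot(small_config)
        reporter = np.clip(image.data[0], 0, None)
        mask, _ = extract_signal_mask(reporter)
        ant = truth.cells[truth.cells["region"] == "anterior"]
        hit = [mask[r.y, r.x] for r in ant.itertuples()]
        assert np.mean(hit) >= 0.95
        background = np.zeros_like(mask)
        background[:20, :] = True  # far from the larva body
        assert mask[background].mean() <= 0.05


class TestAPProfile:
    def test_intensity_in_first_bin_only(self):
        img = np.zeros((10, 100))
        img[:, :5] = 2.0
        prof = ap_profile(img, img > 0, (0, 100), n_bins=10)
        assert prof.values[0] == pytest.approx(img.sum())
        assert prof.values[1:].sum() == 0

    def test_uniform_intensity_gives_equal_bins(self):
        img = np.ones((10, 100))
        prof = ap_profile(img, np.ones_like(img, bool), (0, 100), n_bins=10)
        np.testing.assert_allclose(prof.values, prof.values[0])

    def test_conserves_total_masked_intensity(self, rng):
        img = rng.random((30, 157))
        mask = rng.random((30, 157)) > 0.4
        prof = ap_profile(img, mask, (0, 157), n_bins=14)
        assert prof.values.sum() == pytest.approx(np.where(mask, img, 0).sum())

    def test_scaling_image_scales_profile_linearly(self, rng):
        img = rng.random((20, 80))
        mask = img > 0.5
        p1 = ap_profile(img, mask, (0, 80), n_bins=8)
        p2 = ap_profile(3.0 * img, mask, (0, 80), n_bins=8)
        np.testing.assert_allclose(p2.values, 3.0 * p1.values)

    def test_empty_mask_warns_and_zeroes(self, caplog):
        prof = ap_profile(np.ones((5, 10)), np.zeros((5, 10), bool), (0, 10), n_bins=5)
        assert prof.values.sum() == 0

    def test_phantom_partial_response_is_u_shaped(self, small_config):
        image, truth = generate_snapshot(small_config)
        reporter = np.clip(image.data[0], 0, None)
        mask, _ = extract_signal_mask(reporter)
        prof = ap_profile(reporter, mask, truth.fatbody_extent, n_bins=14)
        ends = max(prof.values[:3].mean(), prof.values[-3:].mean())
        middle = prof.values[5:9].mean()
        assert ends > 2 * middle


class TestNormalizeAndAverage:
    def test_identical_profiles(self):
        p = APProfile(np.linspace(0, 1, 4), [2.0, 4.0, 1.0])
        avg = normalize_and_average([p, p, p])
        np.testing.assert_allclose(avg.values, [0.5, 1.0, 0.25])
        np.testing.assert_allclose(avg.error, 0.0)
        assert avg.normalized

    def test_orthogonal_profiles_use_sample_sd(self):
        edges = np.linspace(0, 1, 3)
        avg = normalize_and_average(
            [APProfile(edges, [1.0, 0.0]), APProfile(edges, [0.0, 1.0])]
        )
        np.testing.assert_allclose(avg.values, [0.5, 0.5])
        # sample sd (ddof=1) of {0, 1} is 1/sqrt(2)
        np.testing.assert_allclose(avg.error, [2**-0.5, 2**-0.5])

    def test_single_profile_has_zero_sd(self):
        avg = normalize_and_average([APProfile(np.linspace(0, 1, 3), [3.0, 6.0])])
        np.testing.assert_allclose(avg.values, [0.5, 1.0])
        np.testing.assert_allclose(avg.error, 0.0)

    def test_zero_profile_excluded(self):
        edges = np.linspace(0, 1, 3)
        avg = normalize_and_average(
            [APProfile(edges, [0.0, 0.0]), APProfile(edges, [1.0, 2.0])]
        )
        np.testing.assert_allclose(avg.values, [0.5, 1.0])


class TestRegionRatios:
    def cell_table(self, regions, intensities):
        return pd.DataFrame({"region": regions, "intensity": intensities})

    def test_uniform_expression_gives_unit_ratios(self):
        stats = region_ratios(
            self.cell_table(["anterior", "middle", "posterior"], [3.0, 3.0, 3.0])
        )
        assert stats.anterior_middle == pytest.approx(1.0)
        assert stats.posterior_middle == pytest.approx(1.0)
        assert stats.max_end_middle == pytest.approx(1.0)

    def test_ratio_arithmetic(self):
        stats = region_ratios(
            self.cell_table(["anterior", "middle", "posterior"], [14.0, 1.0, 5.0])
        )
        assert stats.anterior_middle == pytest.approx(14.0)
        assert stats.posterior_middle == pytest.approx(5.0)
        assert stats.max_end_middle == pytest.approx(14.0)

    def test_zero_middle_reports_nan_not_inf(self):
        stats = region_ratios(
            self.cell_table(["anterior", "middle", "posterior"], [2.0, 0.0, 1.0])
        )
        assert np.isnan(stats.anterior_middle)

    def test_empty_region_raises_with_name(self):
        with pytest.raises(ValueError, match="posterior"):
            region_ratios(self.cell_table(["anterior", "middle"], [1.0, 1.0]))

    def test_profile_input_with_fine_bins(self):
        edges = np.linspace(0, 1, 101)
        values = np.where(
            edges[:-1] < 0.25, 14.0, np.where(edges[:-1] < 0.65, 1.0, 5.0)
        )
        stats = region_ratios(APProfile(edges, values))
        assert stats.anterior_middle == pytest.approx(14.0, rel=0.01)


class TestBootstrapProfile:
    def table(self, ap, gene, total):
        return pd.DataFrame(
            {"cell_id": range(len(ap)), "ap_fraction": ap, "gene_count": gene,
             "total_count": total}
        )

    def test_single_cell_bins_have_zero_sd(self):
        t = self.table([0.1, 0.5, 0.9], [5, 1, 2], [100, 100, 100])
        prof = bootstrap_ap_transcript_profile(t, n_bins=3, seed=0)
        np.testing.assert_allclose(prof.error, 0.0)

    def test_equal_frequencies_give_flat_profile(self):
        ap = np.linspace(0.01, 0.99, 60)
        t = self.table(ap, [10] * 60, [100] * 60)
        prof = bootstrap_ap_transcript_profile(t, n_bins=6, seed=0)
        np.testing.assert_allclose(prof.values, 0.1)
        np.testing.assert_allclose(prof.error, 0.0, atol=1e-12)

    def test_empty_bins_are_missing(self):
        t = self.table([0.05, 0.95], [1, 1], [10, 10])
        prof = bootstrap_ap_transcript_profile(t, n_bins=4, seed=0)
        assert np.isnan(prof.values[1]) and np.isnan(prof.values[2])
        assert prof.n_contributors[0] == 1

    def test_recovers_step_profile_within_bootstrap_error(self, small_config):
        cfg = dataclasses.replace(small_config, n_cells=3000)
        table = generate_transcript_table(cfg)
        prof = bootstrap_ap_transcript_profile(table, n_bins=10, seed=1)
        truth = np.where(
            prof.bin_centers < cfg.transcripts.step_at,
            cfg.transcripts.freq_high,
            cfg.transcripts.freq_low,
        )
        # the step straddles one bin; require agreement within 2 bootstrap sds
        # in at least 90% of bins
        ok = np.abs(prof.values - truth) <= 2 * np.maximum(prof.error, 1e-12) + 1e-3
        assert ok.mean() >= 0.9
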