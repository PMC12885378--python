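"""Generator contracts: determinism, manifest faithfulness, dosage
linearity, conservation, and the configured effect sizes."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from larvalight.phantom import (
    BacteriaSpec,
    PhantomConfig,
    TranscriptSpec,
    ball_offsets,
    generate_bacteria_field,
    generate_snapshot,
    generate_timeseries,
    generate_transcript_table,
)


class TestSnapshot:
    def test_same_seed_is_bit_identical(self, small_config):
        img1, t1 = generate_snapshot(small_config)
        img2, t2 = generate_snapshot(small_config)
        np.testing.assert_array_equal(img1.data, img2.data)
        pd.testing.assert_frame_equal(t1.cells, t2.cells)

    def test_uniform_case_has_equal_cell_means(self, clean_config):
        cfg = dataclasses.replace(clean_config, expression_contrast=(1.0, 1.0))
        _, truth = generate_snapshot(cfg)
        assert truth.cells["mean_intensity"].nunique() == 1

    def test_manifest_contrast_ratio_is_exact(self, clean_config):
        cfg = dataclasses.replace(clean_config, expression_contrast=(14.0, 5.0))
        _, truth = generate_snapshot(cfg)
        by_region = truth.cells.groupby("region")["mean_intensity"].mean()
        assert by_region["anterior"] / by_region["middle"] == pytest.approx(14.0)
        assert by_region["posterior"] / by_region["middle"] == pytest.approx(5.0)

    def test_dosage_linearity_is_exact_noiseless(self, clean_config):
        cfg1 = dataclasses.replace(clean_config, allele_copies=1, intensity_cv=0.35)
        cfg2 = dataclasses.replace(clean_config, allele_copies=2, intensity_cv=0.35)
        _, t1 = generate_snapshot(cfg1)
        _, t2 = generate_snapshot(cfg2)
        np.testing.assert_allclose(
            t2.cells["mean_intensity"], 2.0 * t1.cells["mean_intensity"]
        )

    def test_total_intensity_conservation(self, clean_config):
        image, truth = generate_snapshot(clean_config)
        reporter = image.data[0]
        assert reporter.sum() == pytest.approx(
            truth.cells["deposited_intensity"].sum()
        )

    def test_every_rendered_cell_is_in_the_manifest(self, clean_config):
        image, truth = generate_snapshot(clean_config)
        n_px = len(ball_offsets(clean_config.cell_radius_px, 2))
        assert len(truth.cells) == clean_config.n_cells
        # each disc's pixels carry exactly the manifest value
        for row in truth.cells.itertuples():
            offs = ball_offsets(clean_config.cell_radius_px, 2)
            vals = image.data[0][offs[:, 0] + row.y, offs[:, 1] + row.x]
            np.testing.assert_allclose(vals, row.mean_intensity)

    def test_regions_follow_boundaries(self, small_config):
        _, truth = generate_snapshot(small_config)
        b0, b1 = small_config.region_boundaries
        cells = truth.cells
        assert (cells.loc[cells["ap_fraction"] < b0, "region"] == "anterior").all()
        assert (cells.loc[cells["ap_fraction"] >= b1, "region"] == "posterior").all()

    def test_cells_outside_image_are_rejected(self):
        cfg = PhantomConfig(image_shape=(12, 40), n_cells=40, cell_radius_px=4)
        with pytest.raises(ValueError, match="outside the image"):
            generate_snapshot(cfg)

    @pytest.mark.parametrize(
        "bad",
        [
            {"region_boundaries": (0.7, 0.3)},
            {"expression_contrast": (0.5, 5.0)},
            {"allele_copies": 3},
        ],
    )
    def test_invalid_configs_raise(self, bad):
        with pytest.raises(ValueError):
            PhantomConfig(**bad).validate()


class TestTimeseries:
    def test_noiseless_single_region_line(self, clean_config):
        cfg = dataclasses.replace(
            clean_config,
            rate_medians={"anterior": 5.0, "middle": 5.0, "posterior": 5.0},
            rate_cv=0.0,
            body_level=7.0,
        )
        frames, truth = generate_timeseries(cfg, [0.0, 1.0, 2.0])
        cell = truth.cells.iloc[0]
        vals = [f.data[0][cell.y, cell.x] for f in frames]
        np.testing.assert_allclose(vals, [7.0, 12.0, 17.0])

    def test_zero_rate_cv_gives_identical_slopes_per_region(self, clean_config):
        cfg = dataclasses.replace(clean_config, rate_cv=0.0)
        _, truth = generate_timeseries(cfg, [0, 1, 2, 3])
        assert (truth.cells.groupby("region")["slope"].nunique() == 1).all()

    def test_drawn_slope_medians_match_config(self):
        cfg = PhantomConfig(image_shape=(220, 900), n_cells=200)
        _, truth = generate_timeseries(cfg, [0, 1, 2])
        medians = truth.cells.groupby("region")["slope"].median()
        for region, target in cfg.rate_medians.items():
            assert medians[region] == pytest.approx(target, rel=0.10)

    def test_too_few_timepoints_raise(self, small_config):
        with pytest.raises(ValueError, match="3 points"):
            generate_timeseries(small_config, [0.0, 1.0])
        with pytest.raises(ValueError):
            generate_timeseries(small_config, [0.0, 2.0, 1.0])


class TestBacteriaField:
    def test_manifest_counts(self, small_config):
        spec = BacteriaSpec(n_singles=10, n_doublets=0, cluster_sizes=())
        cfg = dataclasses.replace(small_config, bacteria_spec=spec)
        _, truth = generate_bacteria_field(cfg)
        assert len(truth.bacteria) == 10
        assert (truth.bacteria["count"] == 1).all()

    def test_total_count_arithmetic(self, small_config):
        spec = BacteriaSpec(n_singles=3, n_doublets=0, cluster_sizes=(5,))
        cfg = dataclasses.replace(small_config, bacteria_spec=spec)
        _, truth = generate_bacteria_field(cfg)
        assert truth.bacteria["count"].sum() == 8

    def test_rendered_intensity_matches_count_times_unit(self, small_config):
        # objects spaced widely so each integration patch sees one object
        spec = BacteriaSpec(
            n_singles=8, n_doublets=3, cluster_sizes=(5,), min_separation_px=45.0
        )
        cfg = dataclasses.replace(
            small_config,
            image_shape=(220, 900),
            bacteria_spec=spec,
            noise_sd=0.0,
            background_level=0.0,
        )
        image, truth = generate_bacteria_field(cfg)
        unit = cfg.bacteria_spec.unit_intensity
        img = image.data
        for row in truth.bacteria.itertuples():
            r = int(np.ceil(4 * row.sigma_px)) + 2
            iy, ix = int(round(row.y)), int(round(row.x))
            patch = img[max(iy - r, 0) : iy + r + 1, max(ix - r, 0) : ix + r + 1]
            assert patch.sum() == pytest.approx(row.count * unit, rel=0.02)

    def test_empty_spec_raises(self, small_config):
        spec = BacteriaSpec(n_singles=0, n_doublets=0, cluster_sizes=())
        cfg = dataclasses.replace(small_config, bacteria_spec=spec)
        with pytest.raises(ValueError, match="empty"):
            generate_bacteria_field(cfg)


class TestTranscripts:
    def test_flat_profile_gives_equal_frequencies(self, small_config):
        cfg = dataclasses.replace(
            small_config,
            n_cells=4000,
            transcripts=TranscriptSpec(kind="flat", freq_high=0.02),
        )
        table = generate_transcript_table(cfg)
        lo = table[table["ap_fraction"] < 0.5]
        hi = table[table["ap_fraction"] >= 0.5]
        f_lo = (lo["gene_count"] / lo["total_count"]).mean()
        f_hi = (hi["gene_count"] / hi["total_count"]).mean()
        assert f_lo == pytest.approx(f_hi, rel=0.1)

    def test_anterior_step_is_anterior_high(self, small_config):
        cfg = dataclasses.replace(small_config, n_cells=2000)
        table = generate_transcript_table(cfg)
        spec = cfg.transcripts
        ant = table[table["ap_fraction"] < spec.step_at]
        post = table[table["ap_fraction"] >= spec.step_at]
        assert (ant["gene_count"] / ant["total_count"]).mean() > (
            post["gene_count"] / post["total_count"]
        ).mean()

    def test_zero_frequency_gives_zero_counts(self, small_config):
        cfg = dataclasses.replace(
            small_config,
            transcripts=TranscriptSpec(kind="flat", freq_high=0.0, freq_low=0.0),
        )
        table = generate_transcript_table(cfg)
        assert (table["gene_count"] == 0).all()
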