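"""Segmentation, class ratios, patient aggregation, overlays, agreement."""

import numpy as np
import pytest

from stromaquant import quantification as quant
from stromaquant.preprocessing import patch_label_from_mask, tile_slide
from stromaquant.simulate import RaterPairSpec, gen_rater_pairs
from stromaquant.synthetic import CLASS_NAMES, TexturePalette, gen_slide


def _uniform_weights():
    return np.full(9, 1 / 9)


@pytest.fixture(scope="module")
def tumor_slide(easy_palette):
    w = np.zeros(9)
    w[CLASS_NAMES.index("tumor") - 1] = 1.0
    return gen_slide(easy_palette, 512, 512, 10, w, background_margin=0, seed=41)


@pytest.fixture(scope="module")
def mixed_slide(easy_palette):
    return gen_slide(easy_palette, 512, 512, 40, _uniform_weights(), seed=42)


class TestSegmentation:
    def test_single_class_slide_mostly_predicted_correctly(self, trained_model, tumor_slide):
        cmap = quant.segment_slide(trained_model, tumor_slide.image, tile_size=64)
        kept = cmap.kept_classes
        assert len(kept) > 0
        assert (kept == CLASS_NAMES.index("tumor")).mean() >= 0.95

    def test_rerun_is_identical(self, trained_model, mixed_slide):
        a = quant.segment_slide(trained_model, mixed_slide.image, tile_size=64)
        b = quant.segment_slide(trained_model, mixed_slide.image, tile_size=64)
        np.testing.assert_array_equal(a.tile_classes, b.tile_classes)

    def test_classified_tiles_equal_kept_tiles(self, trained_model, mixed_slide):
        cmap = quant.segment_slide(trained_model, mixed_slide.image, tile_size=64)
        np.testing.assert_array_equal(cmap.tile_classes >= 0, cmap.grid.keep_flags)

    def test_blank_image_raises_no_tissue(self, trained_model):
        blank = np.full((256, 256, 3), 245, dtype=np.uint8)
        with pytest.raises(ValueError, match="no tissue"):
            quant.segment_slide(trained_model, blank, tile_size=64)


class TestRatios:
    def _class_map_from_counts(self, counts: dict[str, int]) -> quant.ClassMap:
        classes = np.concatenate(
            [np.full(n, CLASS_NAMES.index(name)) for name, n in counts.items()]
        )
        n = len(classes)
        side = int(np.ceil(np.sqrt(n)))
        grid = tile_slide(np.zeros((side * 64, side * 64, 3), dtype=np.uint8), 64)
        tile_classes = np.full(grid.n_tiles, -1, dtype=np.int64)
        tile_classes[:n] = classes
        return quant.ClassMap(grid=grid, tile_classes=tile_classes)

    def test_hand_counts_give_expected_mtsr(self):
        cmap = self._class_map_from_counts(
            {"tumor": 30, "stroma": 20, "mixed_tumor_stroma": 10, "muscle": 40}
        )
        profile = quant.compute_ratios(cmap)
        assert profile.mtsr == 10.0
        assert profile.percentages["tumor"] == 30.0

    def test_single_class_is_one_hundred_percent(self):
        profile = quant.compute_ratios(self._class_map_from_counts({"necrosis": 25}))
        assert profile.percentages["necrosis"] == 100.0
        assert sum(v for k, v in profile.percentages.items() if k != "necrosis") == 0.0

    def test_percentages_sum_to_hundred(self, trained_model, mixed_slide):
        cmap = quant.segment_slide(trained_model, mixed_slide.image, tile_size=64)
        profile = quant.compute_ratios(cmap)
        assert abs(sum(profile.percentages.values()) - 100.0) < 1e-9

    def test_background_only_map_rejected(self):
        with pytest.raises(ValueError):
            quant.compute_ratios(self._class_map_from_counts({"background": 5}))

    def test_oracle_labels_recover_true_ratios_within_mixed_tile_bound(self, easy_palette):
        slide = gen_slide(easy_palette, 640, 640, 30, _uniform_weights(), seed=43)
        cmap = quant.oracle_class_map(slide, tile_size=64)
        profile = quant.compute_ratios(cmap)
        # brute force: fraction of tiles containing more than one tissue class
        grid = tile_slide(slide.label_map, 64)
        impure = sum(
            len(np.unique(sub[sub > 0])) > 1 or (sub == 0).any()
            for _, sub in grid.windows(slide.label_map)
        )
        bound = impure / grid.n_tiles * 100
        for name in slide.true_ratios:
            err = abs(profile.percentages[name] - slide.true_ratios[name] * 100)
            assert err <= bound

    def test_halving_tile_size_reduces_mtsr_error(self, easy_palette):
        errs = {}
        for ts in (64, 32):
            tot = 0.0
            for seed in range(5):
                slide = gen_slide(easy_palette, 512, 512, 30, _uniform_weights(), seed=50 + seed)
                profile = quant.compute_ratios(quant.oracle_class_map(slide, tile_size=ts))
                tot += abs(profile.mtsr - slide.true_ratios["mixed_tumor_stroma"] * 100)
            errs[ts] = tot / 5
        assert errs[32] < errs[64]


class TestPatientAggregation:
    def _profile(self, mtsr, tiles, sid="s"):
        pct = {c: 0.0 for c in CLASS_NAMES[1:]}
        pct["mixed_tumor_stroma"] = mtsr
        pct["tumor"] = 100.0 - mtsr
        return quant.ClassRatioProfile(sid, pct, mtsr, tiles)

    @pytest.mark.parametrize("rule", ["mean", "tile-weighted mean", "max"])
    def test_single_slide_equals_slide_mtsr(self, rule):
        p = quant.aggregate_patient([self._profile(12.5, 80)], rule=rule)
        assert p.mtsr == 12.5
        assert p.rule == rule

    def test_equal_tile_counts_average(self):
        p = quant.aggregate_patient(
            [self._profile(10.0, 50, "a"), self._profile(20.0, 50, "b")]
        )
        assert p.mtsr == 15.0

    def test_weighted_mean_equals_pooled_tile_counts(self):
        profiles = [self._profile(10.0, 30, "a"), self._profile(25.0, 90, "b")]
        p = quant.aggregate_patient(profiles)
        pooled_mixed = 0.10 * 30 + 0.25 * 90
        assert p.mtsr == pytest.approx(pooled_mixed / 120 * 100)

    def test_patient_mtsr_within_slide_range(self):
        profiles = [self._profile(m, t) for m, t in [(5, 10), (30, 40), (12, 25)]]
        for rule in ("mean", "tile-weighted mean", "max"):
            p = quant.aggregate_patient(profiles, rule=rule)
            assert 5 <= p.mtsr <= 30

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            quant.aggregate_patient([self._profile(5, 5)], rule="median")


class TestOverlay:
    def test_overlay_matches_grid_dimensions(self, trained_model, mixed_slide):
        cmap = quant.segment_slide(trained_model, mixed_slide.image, tile_size=64)
        overlay, legend = quant.render_overlay(cmap)
        assert overlay.shape == (cmap.grid.n_rows, cmap.grid.n_cols, 3)
        assert legend

    def test_color_histogram_matches_class_histogram(self, trained_model, mixed_slide):
        cmap = quant.segment_slide(trained_model, mixed_slide.image, tile_size=64)
        overlay, _ = quant.render_overlay(cmap)
        for idx in np.unique(cmap.kept_classes):
            color = np.array(quant.OVERLAY_COLORS[CLASS_NAMES[idx]])
            n_pixels = (overlay == color).all(axis=2).sum()
            assert n_pixels == (cmap.tile_classes == idx).sum()


class TestAgreement:
    def test_identical_series(self):
        x = np.array([10.0, 20.0, 30.0, 40.0, 55.0])
        rep = quant.agreement(x, x)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.icc == pytest.approx(1.0)
        assert rep.mean_diff == 0.0
        assert rep.loa == (0.0, 0.0)

    def test_constant_offset(self):
        x = np.array([10.0, 20.0, 30.0, 40.0])
        rep = quant.agreement(x, x + 5)
        assert rep.mean_diff == pytest.approx(5.0)
        assert rep.loa == (pytest.approx(5.0), pytest.approx(5.0))
        assert rep.mean_diff_ci == (pytest.approx(5.0), pytest.approx(5.0))

    def test_constant_series_leaves_r_undefined(self):
        rep = quant.agreement(np.full(5, 7.0), np.arange(5.0))
        assert np.isnan(rep.pearson_r)

    def test_icc_matches_variance_component_prediction(self):
        """Two raters with noise sd 2 on truth sd 10: expected ICC is
        var_truth / (var_truth + var_noise) = 100 / 104."""
        df = gen_rater_pairs(
            RaterPairSpec(n_slides=500, truth_mean=40, truth_sd=10, rater_noise_sd=2, seed=9)
        )
        rep = quant.agreement(df["rater1"].to_numpy(), df["rater2"].to_numpy())
        assert abs(rep.icc - 100 / 104) < 0.05

    def test_icc_against_reference_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(4)
        a = rng.normal(20, 8, 40)
        b = a + rng.normal(1.0, 3.0, 40)
        icc, ci = quant.icc_2_1(a, b)
        long = pd.DataFrame(
            {
                "target": np.tile(np.arange(40), 2),
                "rater": np.repeat(["a", "b"], 40),
                "score": np.concatenate([a, b]),
            }
        )
        ref = pingouin.intraclass_corr(long, "target", "rater", "score")
        ref_row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        assert icc == pytest.approx(ref_row["ICC"], abs=1e-9)
        assert ci[0] == pytest.approx(ref_row["CI95"][0], abs=0.01)
        assert ci[1] == pytest.approx(ref_row["CI95"][1], abs=0.01)

    def test_icc_decreases_with_rater_noise(self):
        iccs = []
        for sd in (0.5, 2.0, 5.0, 10.0):
            df = gen_rater_pairs(
                RaterPairSpec(n_slides=400, truth_mean=40, truth_sd=10, rater_noise_sd=sd, seed=11)
            )
            rep = quant.agreement(df["rater1"].to_numpy(), df["rater2"].to_numpy())
            iccs.append(rep.icc)
        assert all(a > b for a, b in zip(iccs, iccs[1:]))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            quant.agreement(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


def test_oracle_class_map_uses_ninety_percent_rule(easy_palette):
    slide = gen_slide(easy_palette, 256, 256, 12, _uniform_weights(), seed=60)
    cmap = quant.oracle_class_map(slide, tile_size=64)
    grid = tile_slide(slide.label_map, 64)
    for i, (_, sub) in enumerate(grid.windows(slide.label_map)):
        if np.all(sub == 0):
            assert cmap.tile_classes[i] == -1
        else:
            assert cmap.tile_classes[i] == CLASS_NAMES.index(patch_label_from_mask(sub))
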