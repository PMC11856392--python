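"""Stage-3 components: blob counting, the stratified correction factor, and
the count/weight regression network."""

import numpy as np
import pandas as pd
import pytest

from grapeyield import (
    CNNYieldRegressor,
    OcclusionRatioCorrector,
    apply_correction,
    count_visible_blobs,
    estimate_correction_factor,
    mae,
    predict_yield,
)

RNG = np.random.Generator(np.random.PCG64(17))


def draw_disks(shape, centers, radius):
    mask = np.zeros(shape, dtype=np.uint8)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    for (r, c) in centers:
        mask[(rr - r) ** 2 + (cc - c) ** 2 <= radius**2] = 1
    return mask


class TestBlobCounting:
    def test_empty_mask(self):
        assert count_visible_blobs(np.zeros((20, 20))) == 0

    def test_seven_separate_disks(self):
        centers = [(10, 10), (10, 30), (10, 50), (30, 10), (30, 30), (30, 50), (50, 30)]
        mask = draw_disks((64, 64), centers, radius=5)
        assert count_visible_blobs(mask) == 7

    def test_two_merged_disks_with_two_peaks(self):
        mask = draw_disks((32, 48), [(16, 16), (16, 27)], radius=6)
        from scipy import ndimage

        assert ndimage.label(mask)[1] == 1  # genuinely merged into one component
        assert count_visible_blobs(mask, min_peak_distance=4) == 2

    def test_small_specks_removed(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[3, 3] = 1  # single-pixel noise
        mask = mask | draw_disks((20, 20), [(12, 12)], radius=4)
        assert count_visible_blobs(mask, min_blob_area=8) == 1


class TestCorrectionFactor:
    @staticmethod
    def manifest(records):
        return pd.DataFrame.from_records(
            records, columns=["color_variety", "foliage_level", "visible_count",
                              "total_count"]
        )

    def test_fully_visible_gives_unit_ratios(self):
        df = self.manifest([("blue", "low", 20, 20)] * 6 + [("green", "low", 15, 15)] * 6)
        cf = estimate_correction_factor(df)
        assert cf.global_ratio_ == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in cf.per_stratum_ratios_.values())

    def test_small_stratum_falls_back_to_global(self):
        records = [("blue", "low", 10, 13)] * 8 + [("green", "high", 10, 20)] * 2
        cf = estimate_correction_factor(self.manifest(records), n_min=5)
        assert cf.per_stratum_ratios_[("green", "high")] == pytest.approx(cf.global_ratio_)
        assert cf.per_stratum_ratios_[("blue", "low")] == pytest.approx(1.3)

    def test_zero_visible_records_excluded_with_warning(self):
        records = [("blue", "low", 10, 13)] * 5 + [("blue", "low", 0, 9)]
        with pytest.warns(UserWarning, match="visible_count == 0"):
            cf = estimate_correction_factor(self.manifest(records))
        assert cf.global_ratio_ == pytest.approx(1.3)

    def test_all_excluded_is_an_error(self):
        with pytest.raises(ValueError):
            estimate_correction_factor(self.manifest([("blue", "low", 0, 9)] * 3))

    def test_apply_correction_examples(self):
        cf = OcclusionRatioCorrector()
        cf.global_ratio_ = 1.0
        cf.per_stratum_ratios_ = {("blue", "low"): 1.30}
        cf.n_per_stratum_ = {("blue", "low"): 10}
        assert apply_correction(20, cf, ("blue", "low")) == 26
        cf.per_stratum_ratios_[("blue", "low")] = 1.0
        assert apply_correction(20, cf, ("blue", "low")) == 20
        assert apply_correction(0, cf, ("blue", "low")) == 0
        cf.per_stratum_ratios_[("blue", "low")] = 1.30
        assert apply_correction(40, cf, ("blue", "low")) == 52

    def test_unknown_stratum_warns_and_uses_global(self):
        cf = OcclusionRatioCorrector()
        cf.global_ratio_ = 1.2
        cf.per_stratum_ratios_ = {}
        cf.n_per_stratum_ = {}
        with pytest.warns(UserWarning, match="unknown stratum"):
            assert cf.correct(10, ("purple", "high")) == 12

    def test_monotone_in_visible_estimate(self):
        cf = OcclusionRatioCorrector()
        cf.global_ratio_ = 1.27
        cf.per_stratum_ratios_ = {}
        cf.n_per_stratum_ = {}
        values = [cf.correct(v) for v in range(0, 60)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_json_roundtrip(self):
        cf = OcclusionRatioCorrector()
        cf.global_ratio_ = 1.21
        cf.per_stratum_ratios_ = {("blue", "low"): 1.1}
        cf.n_per_stratum_ = {("blue", "low"): 9}
        clone = OcclusionRatioCorrector.from_json(cf.to_json())
        assert clone.global_ratio_ == cf.global_ratio_
        assert clone.per_stratum_ratios_ == cf.per_stratum_ratios_


class TestCounterNetwork:
    def test_unfitted_predict_rejected(self):
        with pytest.raises(ValueError, match="not fitted"):
            CNNYieldRegressor().predict(RNG.random((1, 48, 64, 3)))

    def test_epochs_zero_contract(self, noocc_scenes):
        X = np.stack([s.image for s in noocc_scenes[:10]])
        Y = np.array([[s.total_count, s.weight_g] for s in noocc_scenes[:10]], float)
        model = CNNYieldRegressor(epochs=0, seed=0).fit(X, Y)
        pred = model.predict(X[:3])
        assert pred.shape == (3, 2)
        assert np.isfinite(pred).all()

    def test_batch_equals_one_by_one(self, noocc_counters):
        models, Xte, _ = noocc_counters
        batch = models[0].predict(Xte[:6])
        single = np.vstack([models[0].predict(Xte[i : i + 1]) for i in range(6)])
        assert np.allclose(batch, single)

    def test_learns_counts_on_unoccluded_scenes(self, noocc_counters):
        """Count MAE <= 10% of the mean count (3-seed median)."""
        models, Xte, Yte = noocc_counters
        errors = [mae(Yte[:, 0], m.predict(Xte)[:, 0]) for m in models]
        assert np.median(errors) <= 0.10 * Yte[:, 0].mean()

    def test_weight_head_recovers_per_berry_mass(self, noocc_counters):
        """With weight = 1.5 g/berry and no noise, regressing predicted
        weight on true count recovers the slope within 10% (3-seed median)."""
        models, Xte, Yte = noocc_counters
        slopes = [
            np.polyfit(Yte[:, 0], m.predict(Xte)[:, 1], 1)[0] for m in models
        ]
        assert abs(np.median(slopes) - 1.5) <= 0.15

    def test_repeat_run_identical(self, noocc_scenes):
        X = np.stack([s.image for s in noocc_scenes[:24]])
        Y = np.array([[s.total_count, s.weight_g] for s in noocc_scenes[:24]], float)
        kw = dict(epochs=2, seed=9)
        a = CNNYieldRegressor(**kw).fit(X, Y)
        b = CNNYieldRegressor(**kw).fit(X, Y)
        assert a.loss_curve_ == b.loss_curve_
        assert np.array_equal(a.predict(X[:4]), b.predict(X[:4]))

    def test_checkpoint_roundtrip(self, tmp_path, noocc_counters):
        models, Xte, _ = noocc_counters
        path = tmp_path / "counter.npz"
        models[0].save(path)
        clone = CNNYieldRegressor.load(path)
        assert np.array_equal(models[0].predict(Xte[:4]), clone.predict(Xte[:4]))

    def test_predict_yield_wrapper(self, noocc_counters):
        models, Xte, Yte = noocc_counters
        pred = predict_yield(models[0], Xte[0])
        assert np.isfinite(pred.count_raw) and np.isfinite(pred.weight_g)
        assert pred.count_int == round(pred.count_raw)
        assert abs(pred.count_raw - Yte[0, 0]) < 0.3 * Yte[:, 0].mean()

    def test_missing_targets_rejected(self, noocc_scenes):
        X = np.stack([s.image for s in noocc_scenes[:4]])
        with pytest.raises(ValueError):
            CNNYieldRegressor().fit(X, np.full((4, 2), np.nan))
        with pytest.raises(ValueError):
            CNNYieldRegressor().fit(X[:0], np.zeros((0, 2)))
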