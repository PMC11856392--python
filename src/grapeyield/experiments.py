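"""Experiment harness: ablation and segmentation studies plus the paired t-test.

The ablation study trains the stage-3 counter twice per condition and seed —
once on raw images ("without segmentation") and once on mask-overlaid images
("with segmentation") — using byte-identical group-aware splits in both
arms, and reports count MAE and R^2 per arm.  The segmentation studies train
the U-Net per resolution tier or per grape colour and report mean test IoU
and F1.  Across-seed medians summarise each condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import metrics
from .counting import CNNYieldRegressor
from .overlay import overlay
from .segmentation import UNetSegmenter, load_training_arrays, split_by_group

__all__ = [
    "TTestResult",
    "DegenerateVarianceError",
    "paired_t_test",
    "run_ablation",
    "run_segmentation_study",
    "summarize_report",
]


class DegenerateVarianceError(ValueError):
    """All paired differences are equal; the t statistic is undefined."""


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    p_value: float
    df: int
    mean_diff: float


def paired_t_test(a, b) -> TTestResult:
    """Two-sided paired t-test on matched series (e.g. MAE with/without a stage).

    t = mean(d) / (sd(d) / sqrt(n)) on the differences d = a - b, with n - 1
    degrees of freedom.  Raises :class:`DegenerateVarianceError` when every
    difference is identical (zero sample variance).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise DegenerateVarianceError("all paired differences are equal; t is undefined")
    mean_d = float(np.mean(d))
    t = mean_d / (sd / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return TTestResult(t_statistic=float(t), p_value=p, df=n - 1, mean_diff=mean_d)


def _filter_condition(manifest: pd.DataFrame, condition: dict) -> pd.DataFrame:
    sub = manifest
    for col, val in condition.items():
        if col not in sub.columns:
            raise KeyError(f"condition column {col!r} not in manifest")
        sub = sub[sub[col] == val]
    if sub.empty:
        raise ValueError(f"no manifest records match condition {condition!r}")
    return sub


def _condition_label(condition: dict) -> str:
    return ",".join(f"{k}={v}" for k, v in sorted(condition.items()))


def run_ablation(manifest: pd.DataFrame, data_dir, conditions, seeds,
                 segmenter: UNetSegmenter | None = None,
                 counter_params: dict | None = None,
                 test_fraction: float = 0.2, image_shape=(48, 64)) -> pd.DataFrame:
    """Counter accuracy with vs without the segmentation stage.

    For every condition and seed the manifest subset is split once by group
    and the split is shared by both arms.  The "with" arm feeds the counter
    mask-overlaid images — masks predicted by ``segmenter`` if given, else
    the ground-truth masks (an idealised stage 1 isolating the stage-3
    effect).  Returns one row per (condition, arm, seed) with MAE and R^2 on
    total count.
    """
    counter_params = dict(counter_params or {})
    rows = []
    for condition in conditions:
        sub = _filter_condition(manifest, condition)
        for seed in seeds:
            train_df, test_df = split_by_group(sub, test_fraction, seed)
            xtr, mtr = load_training_arrays(train_df, data_dir, shape=image_shape)
            xte, mte = load_training_arrays(test_df, data_dir, shape=image_shape)
            ytr = train_df[["total_count", "weight_g"]].to_numpy(float)
            yte_count = test_df["total_count"].to_numpy(float)
            if segmenter is not None:
                mtr = segmenter.predict(xtr)
                mte = segmenter.predict(xte)
            arms = {
                False: (xtr, xte),
                True: (
                    np.stack([overlay(im, mk).image for im, mk in zip(xtr, mtr)]),
                    np.stack([overlay(im, mk).image for im, mk in zip(xte, mte)]),
                ),
            }
            for with_seg, (arm_xtr, arm_xte) in arms.items():
                model = CNNYieldRegressor(seed=seed, **counter_params).fit(arm_xtr, ytr)
                pred = model.predict(arm_xte)[:, 0]
                rows.append(
                    dict(
                        experiment="ablation",
                        condition=_condition_label(condition),
                        with_segmentation=with_seg,
                        seed=seed,
                        MAE=metrics.mae(yte_count, pred),
                        R2=metrics.r_squared(yte_count, pred),
                        n=len(test_df),
                    )
                )
    return pd.DataFrame(rows)


# Tier sizes used when resizing reference imagery for the resolution study
# (3:4 aspect, ordered low < medium < high).
STUDY_TIER_SHAPES = {"low": (24, 32), "medium": (36, 48), "high": (48, 64)}


def _mean_iou_f1(preds, truths):
    import warnings as _w

    ious, f1s = [], []
    with _w.catch_warnings():
        _w.simplefilter("ignore", metrics.DegenerateMetricWarning)
        for p, t in zip(preds, truths):
            ious.append(metrics.iou(p, t))
            f1s.append(metrics.f1(metrics.confusion_from_masks(p, t)))
    return float(np.mean(ious)), float(np.mean(f1s))


def run_segmentation_study(manifest: pd.DataFrame, data_dir, axis: str, seeds,
                           unet_params: dict | None = None,
                           test_fraction: float = 0.2,
                           tier_shapes: dict | None = None,
                           image_shape=(48, 64)) -> pd.DataFrame:
    """U-Net IoU/F1 per level of one experimental axis.

    ``axis="resolution"``: every record's image is resized to each tier's
    size (``tier_shapes``), a segmenter is trained per tier, and predicted
    masks are scored against the ground truth at the reference (largest)
    size — so lower tiers genuinely lose boundary information, as when one
    set of captures is downsampled.  ``axis="color"``: a segmenter is
    trained per grape colour at a fixed size.  Returns one row per
    (level, seed) with mean test-set IoU and F1.
    """
    from . import io as gio

    if axis not in ("resolution", "color"):
        raise ValueError("axis must be 'resolution' or 'color'")
    unet_params = dict(unet_params or {})
    rows = []
    if axis == "resolution":
        shapes = dict(tier_shapes or STUDY_TIER_SHAPES)
        ref_shape = max(shapes.values())  # largest tier is the reference
        for level, shape in shapes.items():
            for seed in seeds:
                train_df, test_df = split_by_group(manifest, test_fraction, seed)
                xtr, mtr = load_training_arrays(train_df, data_dir, shape=shape)
                xte_ref, mte_ref = load_training_arrays(test_df, data_dir,
                                                        shape=ref_shape)
                xte = np.stack([gio.resize_image(im, shape) for im in xte_ref])
                model = UNetSegmenter(seed=seed, **unet_params).fit(xtr, mtr)
                pred = [gio.resize_mask(p, ref_shape) for p in model.predict(xte)]
                iou_m, f1_m = _mean_iou_f1(pred, mte_ref)
                rows.append(
                    dict(
                        experiment="segmentation/resolution",
                        condition=f"resolution_tier={level}",
                        seed=seed,
                        IoU=iou_m,
                        F1=f1_m,
                        n=len(test_df),
                    )
                )
        return pd.DataFrame(rows)

    levels = list(pd.unique(manifest["color_variety"]))
    for level in levels:
        sub = manifest[manifest["color_variety"] == level]
        if sub.empty:
            raise ValueError(f"no records for color_variety={level!r}")
        for seed in seeds:
            train_df, test_df = split_by_group(sub, test_fraction, seed)
            xtr, mtr = load_training_arrays(train_df, data_dir, shape=image_shape)
            xte, mte = load_training_arrays(test_df, data_dir, shape=image_shape)
            model = UNetSegmenter(seed=seed, **unet_params).fit(xtr, mtr)
            iou_m, f1_m = _mean_iou_f1(model.predict(xte), mte)
            rows.append(
                dict(
                    experiment="segmentation/color",
                    condition=f"color_variety={level}",
                    seed=seed,
                    IoU=iou_m,
                    F1=f1_m,
                    n=len(test_df),
                )
            )
    return pd.DataFrame(rows)


def summarize_report(report: pd.DataFrame, value_cols=None) -> pd.DataFrame:
    """Across-seed medians per (experiment, condition[, segmentation arm])."""
    if value_cols is None:
        value_cols = [c for c in ("MAE", "R2", "IoU", "F1") if c in report.columns]
    keys = [c for c in ("experiment", "condition", "with_segmentation")
            if c in report.columns]
    agg = report.groupby(keys, sort=False)[value_cols].median().reset_index()
    counts = report.groupby(keys, sort=False).size().rename("seeds").reset_index()
    return agg.merge(counts, on=keys)
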