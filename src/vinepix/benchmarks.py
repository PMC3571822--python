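"""End-to-end synthetic benchmarks of the full method.

Two study-scale exercises, run entirely from the synthetic generator:

* ``classification_benchmark`` — render a cohort of full-size scenes,
  build a 40-pixel-per-class reference registry, classify, clean the grape
  class, and score aggregated leaf recall, post-cleanup grape recall, and
  per-class count recovery against the exact truth.
* ``calibration_benchmark`` — simulate a record-level cohort (counts
  exactly proportional to the physical quantity, noisy measurements),
  split 2/3 train / 1/3 validation, fit the OLS calibration, and report
  validation R² and RMSE.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .postprocess import MorphParams, clean_grape_class
from .classifier import classify_image
from .quantify import evaluate, fit_linear, split_train_validation
from .synthimage import (
    SceneParams,
    make_reference_registry,
    render_scene,
    simulate_calibration_cohort,
)


def classification_benchmark(
    n_scenes: int = 10,
    scene_seed: int = 42,
    registry_seed: int = 7,
    params: SceneParams | None = None,
    shrinkage: float = 0.1,
    morph: MorphParams = MorphParams(),
    lower_fraction: float = 0.5,
    stage: str = "I0",
) -> dict:
    """Classify a cohort of synthetic scenes and score against exact truth.

    Returns a dict with ``leaf_recall_pct`` (truth-leaf pixels assigned to
    any leaf class by raw classification), ``grape_recall_pct`` (truth
    grape pixels labeled Grape after the cleanup pass), per-class truth and
    predicted totals over the cohort, and the per-class relative count
    recovery errors.
    """
    base = params if params is not None else SceneParams()
    registry = make_reference_registry(base, n_per_class=40, seed=registry_seed)
    leaf_idx = set(registry.leaf_indices)
    g = registry.grape_index
    K = registry.K

    leaf_truth_total = 0
    leaf_hit_total = 0
    grape_truth_total = 0
    grape_hit_total = 0
    truth_totals = np.zeros(K, dtype=np.int64)
    pred_totals = np.zeros(K, dtype=np.int64)

    for i in range(n_scenes):
        scene = render_scene(replace(base, seed=scene_seed + i), stage)
        raw, stack = classify_image(
            scene.image, registry, keep_distances=True, shrinkage=shrinkage
        )
        cleaned = clean_grape_class(raw, stack, morph, lower_fraction)

        truth = scene.truth.labels
        leaf_truth = np.isin(truth, list(leaf_idx))
        leaf_pred = np.isin(raw.labels, list(leaf_idx))
        leaf_truth_total += int(leaf_truth.sum())
        leaf_hit_total += int((leaf_truth & leaf_pred).sum())

        grape_truth = truth == g
        grape_truth_total += int(grape_truth.sum())
        grape_hit_total += int((grape_truth & (cleaned.labels == g)).sum())

        truth_totals += np.bincount(truth.ravel(), minlength=K)
        pred_totals += np.bincount(cleaned.labels.ravel(), minlength=K)

    recovery = {}
    for k, name in enumerate(registry.names):
        if truth_totals[k] > 0:
            recovery[name] = float(
                abs(int(pred_totals[k]) - int(truth_totals[k])) / truth_totals[k]
            )
    return {
        "leaf_recall_pct": 100.0 * leaf_hit_total / leaf_truth_total,
        "grape_recall_pct": 100.0 * grape_hit_total / grape_truth_total,
        "n_leaf_truth_px": leaf_truth_total,
        "n_grape_truth_px": grape_truth_total,
        "truth_totals": {n: int(v) for n, v in zip(registry.names, truth_totals)},
        "pred_totals": {n: int(v) for n, v in zip(registry.names, pred_totals)},
        "count_recovery_rel_err": recovery,
    }


def calibration_benchmark(
    target: str = "leaf_area_m2",
    n_vines: int = 10,
    seed: int = 11,
    noise_sd: float = 0.3,
    train_fraction: float = 2.0 / 3.0,
) -> dict:
    """Fit and validate the pixel-count calibration on a simulated cohort."""
    records = simulate_calibration_cohort(target=target, n_vines=n_vines, seed=seed, noise_sd=noise_sd)
    pairs = [(count, measurement) for _, count, measurement in records]
    train, validation = split_train_validation(pairs, train_fraction, seed=seed)
    predictor = "leaf_pixels" if target == "leaf_area_m2" else "grape_pixels"
    model = fit_linear(train, target=target, predictor=predictor)
    report = evaluate(model, validation)
    return {
        "r2": report.r2,
        "rmse": report.rmse,
        "n_train": len(train),
        "n_validation": report.n,
        "slope": model.slope,
        "intercept": model.intercept,
        "r2_train": model.r2_train,
    }
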