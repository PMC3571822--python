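"""Per-class agreement between predicted and ground-truth label images.

Mirrors the manual validation protocol: over a rectangular ROI (30x30 by
convention), cross-tabulate truth vs predicted labels and report per-class
recall percentages.  For the Leaves figure the young and old grades are
merged: any leaf-grade pixel predicted into any leaf grade counts as
correct.  Because a manual-count comparison can also be read as an
agreement of class *fractions* rather than pixel recall, both metrics are
exposed; recall is the headline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import ClassRegistry, LabelImage, check_roi

#: Conventional validation window size.
DEFAULT_ROI_SIZE = 30


@dataclass
class ConfusionMatrix:
    """K x K cross-tabulation, truth on rows, predicted on columns."""

    matrix: np.ndarray
    registry: ClassRegistry
    roi: tuple[int, int, int, int] | None = None

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


def confusion(
    pred: LabelImage,
    truth: LabelImage,
    roi: tuple[int, int, int, int] | None = None,
) -> ConfusionMatrix:
    """Exact (truth, predicted) cross-tabulation over the ROI."""
    if not pred.registry.compatible_with(truth.registry):
        raise ValueError(
            "predicted and truth label images use different class registries"
        )
    if pred.labels.shape != truth.labels.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.labels.shape} vs truth {truth.labels.shape}"
        )
    H, W = pred.labels.shape
    if roi is not None:
        r0, r1, c0, c1 = check_roi(roi, H, W)
    else:
        r0, r1, c0, c1 = 0, H, 0, W
    t = truth.labels[r0:r1, c0:c1].ravel()
    p = pred.labels[r0:r1, c0:c1].ravel()
    if t.min() < 0 or p.min() < 0:
        raise ValueError("unprocessed pixels inside the validation ROI")
    K = pred.registry.K
    matrix = np.bincount(t * K + p, minlength=K * K).reshape(K, K)
    return ConfusionMatrix(matrix=matrix, registry=pred.registry, roi=(r0, r1, c0, c1))


def class_accuracy(cm: ConfusionMatrix, class_names) -> float:
    """Recall percentage for a class or an aggregated set of classes.

    With an aggregated set (e.g. all four leaf grades), any within-set
    assignment counts as correct, so aggregation forgives inter-grade
    confusion but never cross-set errors.
    """
    if isinstance(class_names, str):
        class_names = [class_names]
    idx = [cm.registry.index_of(name) for name in class_names]
    truth_total = int(cm.matrix[idx, :].sum())
    if truth_total == 0:
        raise ValueError(f"no truth pixels for class set {sorted(class_names)}")
    correct = int(cm.matrix[np.ix_(idx, idx)].sum())
    return 100.0 * correct / truth_total


def class_fractions(cm: ConfusionMatrix, class_names) -> tuple[float, float]:
    """Area-ratio agreement: (truth %, predicted %) of the ROI for a class set."""
    if isinstance(class_names, str):
        class_names = [class_names]
    idx = [cm.registry.index_of(name) for name in class_names]
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    truth_pct = 100.0 * float(cm.matrix[idx, :].sum()) / total
    pred_pct = 100.0 * float(cm.matrix[:, idx].sum()) / total
    return truth_pct, pred_pct
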