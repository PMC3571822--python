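"""Pixel counting, result export, and linear calibration to leaf area / yield.

The physical link between an image and the vine is deliberately simple: the
number of pixels a class occupies is proportional to the physical quantity
behind it (total one-sided leaf area in m², harvested grape mass in kg), so
an ordinary least-squares line per target converts counts to estimates.
Models are trained on two thirds of the records and validated on the rest,
reporting R² (squared Pearson correlation of predicted vs observed — the
headline convention here — alongside the 1 - SSE/SST form) and RMSE in the
target's units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import ClassRegistry, LabelImage


@dataclass
class ClassCounts:
    """Per-class pixel tallies for one image (or ROI)."""

    image_id: str
    counts: dict[str, int]
    total: int
    roi: tuple[int, int, int, int] | None = None


def count_pixels(label_image: LabelImage, image_id: str = "") -> ClassCounts:
    """Exact per-class tallies over the ROI; the counts sum to the ROI size."""
    labels = label_image.labels_in_roi()
    if labels.min() < 0:
        raise ValueError("label image contains unprocessed pixels inside its ROI")
    K = label_image.registry.K
    tallies = np.bincount(labels.ravel(), minlength=K)
    counts = {name: int(tallies[i]) for i, name in enumerate(label_image.registry.names)}
    return ClassCounts(
        image_id=image_id, counts=counts, total=int(labels.size), roi=label_image.roi
    )


def aggregate_leaf_count(counts: ClassCounts, registry: ClassRegistry) -> int:
    """Total leaf pixels: the young and old leaf grades added together."""
    leaf_names = [registry.classes[i].name for i in registry.leaf_indices]
    if not leaf_names:
        raise ValueError("registry defines no leaf-role class")
    return sum(counts.counts.get(name, 0) for name in leaf_names)


def grape_count(counts: ClassCounts, registry: ClassRegistry) -> int:
    g = registry.grape_index
    if g is None:
        raise ValueError("registry defines no grape-role class")
    return counts.counts.get(registry.classes[g].name, 0)


def split_train_validation(
    records: list,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    stages: list | None = None,
) -> tuple[list, list]:
    """Random, seeded, disjoint and exhaustive train/validation partition.

    The train size is ``round(n * train_fraction)`` (clamped so both parts
    are non-empty).  If ``stages`` labels are given, the split is stratified:
    each stage contributes its own rounded share to the training set.
    """
    n = len(records)
    if n < 3:
        raise ValueError(f"need at least 3 records to split, got {n}")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)

    def _pick(idx: np.ndarray, frac: float) -> np.ndarray:
        k = int(round(len(idx) * frac))
        return rng.permutation(idx)[:k]

    all_idx = np.arange(n)
    if stages is None:
        train_idx = _pick(all_idx, train_fraction)
    else:
        if len(stages) != n:
            raise ValueError("stages must label every record")
        picks = []
        for stage in sorted(set(map(str, stages))):
            members = np.array([i for i in all_idx if str(stages[i]) == stage])
            picks.append(_pick(members, train_fraction))
        train_idx = np.concatenate(picks)
    n_train = min(max(len(train_idx), 1), n - 1)
    train_set = set(int(i) for i in train_idx[:n_train])
    train = [records[i] for i in range(n) if i in train_set]
    validation = [records[i] for i in range(n) if i not in train_set]
    return train, validation


@dataclass
class CalibrationModel:
    """A straight line y = slope * x + intercept from pixel count to target."""

    slope: float
    intercept: float
    target: str = "leaf_area_m2"
    predictor: str = "leaf_pixels"
    n_train: int = 0
    r2_train: float = float("nan")

    def predict(self, count) -> np.ndarray | float:
        return self.slope * np.asarray(count, dtype=np.float64) + self.intercept

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "target": self.target,
                    "predictor": self.predictor,
                    "n_train": self.n_train,
                    "r2_train": self.r2_train,
                },
                fh,
                indent=2,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(**doc)


def fit_linear(
    train: list[tuple[float, float]],
    target: str = "leaf_area_m2",
    predictor: str = "leaf_pixels",
) -> CalibrationModel:
    """Ordinary least squares of measurement on pixel count."""
    if len(train) < 3:
        raise ValueError(f"need at least 3 training points, got {len(train)}")
    x = np.asarray([p[0] for p in train], dtype=np.float64)
    y = np.asarray([p[1] for p in train], dtype=np.float64)
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: pixel counts are all equal")
    res = stats.linregress(x, y)
    fitted = res.slope * x + res.intercept
    r2 = _squared_pearson(fitted, y)
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        target=target,
        predictor=predictor,
        n_train=len(train),
        r2_train=r2,
    )


def _squared_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


@dataclass
class EvalReport:
    """Validation diagnostics for a calibration model."""

    r2: float  # squared Pearson correlation, predicted vs observed
    rmse: float  # in the target's units
    n: int
    pairs: list[tuple[float, float]] = field(default_factory=list)
    r2_one_to_one: float = float("nan")  # 1 - SSE/SST convention
    degenerate: bool = False  # observed values constant; r2 undefined


def evaluate(model: CalibrationModel, validation: list[tuple[float, float]]) -> EvalReport:
    """Predict the validation records and report R² and RMSE."""
    if len(validation) < 2:
        raise ValueError(f"need at least 2 validation points, got {len(validation)}")
    x = np.asarray([p[0] for p in validation], dtype=np.float64)
    obs = np.asarray([p[1] for p in validation], dtype=np.float64)
    pred = np.asarray(model.predict(x), dtype=np.float64)
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    degenerate = bool(np.ptp(obs) == 0)
    r2 = float("nan") if degenerate else _squared_pearson(pred, obs)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    r2_sse = float("nan") if sst == 0 else 1.0 - float(np.sum((obs - pred) ** 2)) / sst
    return EvalReport(
        r2=r2,
        rmse=rmse,
        n=len(validation),
        pairs=list(zip(obs.tolist(), pred.tolist())),
        r2_one_to_one=r2_sse,
        degenerate=degenerate,
    )


def write_results(counts: list[ClassCounts], path) -> None:
    """Step-10 spreadsheet: one row per (image, class), with class fractions."""
    rows = []
    for cc in counts:
        for name, value in cc.counts.items():
            rows.append(
                {
                    "image_id": cc.image_id,
                    "class": name,
                    "pixel_count": int(value),
                    "fraction_of_total": (value / cc.total) if cc.total else 0.0,
                }
            )
    frame = pd.DataFrame(rows, columns=["image_id", "class", "pixel_count", "fraction_of_total"])
    try:
        frame.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"could not write results to {path}: {exc}") from exc


def read_results(path) -> list[ClassCounts]:
    """Round-trip reader for the results CSV."""
    frame = pd.read_csv(path)
    out: list[ClassCounts] = []
    for image_id, group in frame.groupby("image_id", sort=False):
        counts = {str(r["class"]): int(r["pixel_count"]) for _, r in group.iterrows()}
        out.append(ClassCounts(image_id=str(image_id), counts=counts, total=sum(counts.values())))
    return out


def records_from_tables(
    counts: list[ClassCounts],
    measurements: pd.DataFrame,
    registry: ClassRegistry,
    predictor: str = "leaf_pixels",
    target: str = "leaf_area_m2",
) -> list[tuple[str, float, float]]:
    """Join per-image counts with a ground-truth measurement table.

    ``measurements`` needs an ``image_id`` column plus the target column.
    Returns (image_id, pixel_count, measurement) records for calibration.
    """
    lookup = {str(r["image_id"]): float(r[target]) for _, r in measurements.iterrows()}
    records = []
    for cc in counts:
        if cc.image_id not in lookup:
            continue
        if predictor == "leaf_pixels":
            x = aggregate_leaf_count(cc, registry)
        elif predictor == "grape_pixels":
            x = grape_count(cc, registry)
        else:
            raise ValueError(f"unknown predictor {predictor!r}")
        records.append((cc.image_id, float(x), lookup[cc.image_id]))
    return records
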