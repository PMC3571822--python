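"""Synthetic vine scenes with exact ground truth.

The generator emulates the study layout the classifier was designed for: a
vertically shoot-positioned vine photographed against a white screen — a
near-white background, a trunk/cordon/shoot wood skeleton, dark bluish
grape clusters confined to the lower half of the frame, and leaf blobs in
four grades of green.  Each painted pixel's colour is drawn from its
class's colour distribution (independent per-channel Gaussians, clipped to
[0, 255]), so the class-conditional structure the Mahalanobis classifier
assumes holds by construction, and the truth label map is recorded while
painting.

A seven-stage defoliation / de-fruiting series mirrors the field protocol:
leaves are removed in roughly equal thirds at steps 1, 3 and 5 (complete
defoliation), clusters are thinned by every third at step 2, every second
remaining at step 4, and entirely at step 6.  True leaf area and yield are
exact linear functions of the truth pixel counts via the per-pixel
conversion factors, which is precisely the structure the downstream linear
calibration assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .classifier import ClassRegistry, LabelImage
from .color_model import PixelSample, fit_reference_class

STAGES = ("I0", "I1", "I2", "I3", "I4", "I5", "I6")


@dataclass(frozen=True)
class ClassSpec:
    """Mean colour, per-channel spread, and role flags for one scene class."""

    name: str
    mean: tuple[float, float, float]
    sd: float = 12.0
    roles: tuple[str, ...] = ()


#: Default palette: realistic yet separable canopy colours (sd 12 each channel).
DEFAULT_PALETTE: tuple[ClassSpec, ...] = (
    ClassSpec("Background", (235.0, 235.0, 235.0), 12.0, ("background",)),
    ClassSpec("Wood", (105.0, 75.0, 45.0), 12.0, ()),
    ClassSpec("Grape", (50.0, 45.0, 75.0), 12.0, ("grape",)),
    ClassSpec("Old leaves grade 1", (55.0, 105.0, 45.0), 12.0, ("leaf",)),
    ClassSpec("Old leaves grade 2", (80.0, 120.0, 40.0), 12.0, ("leaf",)),
    ClassSpec("Young leaves grade 1", (95.0, 155.0, 70.0), 12.0, ("leaf",)),
    ClassSpec("Young leaves grade 2", (120.0, 170.0, 90.0), 12.0, ("leaf",)),
)


@dataclass(frozen=True)
class SceneParams:
    """Geometry, palette, and physical conversion factors of a scene.

    Conversion factors (m² of leaf per leaf pixel, kg of fruit per grape
    pixel) make the truth measurements exact linear functions of truth
    pixel counts.  Grape clusters are always placed wholly in the lower
    half of the frame.
    """

    H: int = 600
    W: int = 800
    palette: tuple[ClassSpec, ...] = DEFAULT_PALETTE
    leaf_blobs_per_grade: int = 14
    leaf_radius: tuple[int, int] = (20, 40)
    grape_clusters: int = 8
    grape_radius_col: tuple[int, int] = (22, 40)
    grape_radius_row: tuple[int, int] = (16, 28)
    n_shoots: int = 12
    trunk_width: int = 22
    shoot_width: int = 7
    area_per_leaf_px: float = 2e-5  # m² per leaf pixel
    kg_per_grape_px: float = 1e-4  # kg per grape pixel
    occlusion: bool = False  # paint leaves over grapes (dense-canopy mode)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.H < 16 or self.W < 16:
            raise ValueError("scene must be at least 16x16")
        for spec in self.palette:
            if min(spec.mean) < 0 or max(spec.mean) > 255:
                raise ValueError(f"palette mean out of range for {spec.name!r}")
            if spec.sd <= 0:
                raise ValueError(f"palette sd must be > 0 for {spec.name!r}")
        if self.area_per_leaf_px <= 0 or self.kg_per_grape_px <= 0:
            raise ValueError("conversion factors must be > 0")

    def class_index(self, role_or_name: str) -> int:
        for i, spec in enumerate(self.palette):
            if spec.name == role_or_name or role_or_name in spec.roles:
                return i
        raise KeyError(role_or_name)

    @property
    def leaf_grade_indices(self) -> tuple[int, ...]:
        return tuple(i for i, s in enumerate(self.palette) if "leaf" in s.roles)


@dataclass
class SyntheticScene:
    """A rendered scene with its exact ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    truth: LabelImage
    true_leaf_area_m2: float
    true_yield_kg: float
    stage: str


@dataclass(frozen=True)
class _Layout:
    """One vine's blob geometry, fixed for all stages of its series."""

    leaf_blobs: tuple  # (grade_class_index, row, col, radius) in paint order
    leaf_removal_order: tuple  # indices into leaf_blobs, removal priority
    grapes: tuple  # (row, col, r_row, r_col)
    wood_segments: tuple  # ((r0, c0), (r1, c1), width)


def _make_layout(params: SceneParams) -> _Layout:
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 0]))
    H, W = params.H, params.W

    # Wood skeleton: trunk, bilateral cordon, upright shoots (VSP training).
    cordon_row = int(0.45 * H)
    trunk_col = W // 2 + int(rng.integers(-W // 20, W // 20 + 1))
    segments = [((cordon_row, trunk_col), (H - 1, trunk_col), params.trunk_width)]
    arm = int(0.35 * W)
    segments.append(
        ((cordon_row, max(trunk_col - arm, 4)), (cordon_row, min(trunk_col + arm, W - 5)), 12)
    )
    xs = np.linspace(max(trunk_col - arm, 10), min(trunk_col + arm, W - 11), params.n_shoots)
    for x in xs:
        x0 = int(x + rng.integers(-8, 9))
        top = int(rng.integers(max(H // 20, 2), H // 6))
        slant = int(rng.integers(-W // 20, W // 20 + 1))
        x1 = int(np.clip(x0 + slant, 1, W - 2))
        segments.append(((cordon_row, np.clip(x0, 1, W - 2)), (top, x1), params.shoot_width))

    # Grape clusters: ellipses wholly inside the lower half.
    cut = math.ceil(H / 2)
    grapes = []
    for _ in range(params.grape_clusters):
        rr = int(rng.integers(params.grape_radius_row[0], params.grape_radius_row[1] + 1))
        rc = int(rng.integers(params.grape_radius_col[0], params.grape_radius_col[1] + 1))
        row = int(rng.integers(cut + rr, H - rr))
        col = int(rng.integers(rc, W - rc))
        grapes.append((row, col, rr, rc))

    # Leaf blobs, one list per grade, painted in a shuffled global order so no
    # grade is systematically occluded by another.  Without the occlusion
    # option, leaves are placed clear of every grape cluster so that cluster
    # thinning never changes the visible leaf area (and vice versa).
    def _clear_of_grapes(row: int, col: int, r: int) -> bool:
        for g_row, g_col, r_row, r_col in grapes:
            du = (row - g_row) / (r_row + r)
            dv = (col - g_col) / (r_col + r)
            if du * du + dv * dv <= 1.0:
                return False
        return True

    blobs = []
    for grade in params.leaf_grade_indices:
        for _ in range(params.leaf_blobs_per_grade):
            r = int(rng.integers(params.leaf_radius[0], params.leaf_radius[1] + 1))
            for _attempt in range(200):
                row = int(rng.integers(0, int(0.85 * H)))
                col = int(rng.integers(0, W))
                if params.occlusion or _clear_of_grapes(row, col, r):
                    break
            blobs.append((grade, row, col, r))
    order = rng.permutation(len(blobs))
    blobs = tuple(blobs[i] for i in order)
    removal = tuple(int(i) for i in rng.permutation(len(blobs)))
    return _Layout(
        leaf_blobs=blobs,
        leaf_removal_order=removal,
        grapes=tuple(grapes),
        wood_segments=tuple(segments),
    )


def _active_subsets(layout: _Layout, stage: str) -> tuple[tuple, tuple]:
    """Blob subsets surviving the cumulative manipulation up to ``stage``."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    si = STAGES.index(stage)
    n = len(layout.leaf_blobs)
    removed: set[int] = set()
    if si >= 1:
        removed.update(layout.leaf_removal_order[: n // 3])
    if si >= 3:
        removed.update(layout.leaf_removal_order[: 2 * (n // 3)])
    if si >= 5:
        removed.update(range(n))
    leaves = tuple(b for i, b in enumerate(layout.leaf_blobs) if i not in removed)

    grapes = list(layout.grapes)
    if si >= 2:  # remove every third cluster
        grapes = [g for i, g in enumerate(grapes) if i % 3 != 2]
    if si >= 4:  # remove every second remaining cluster
        grapes = [g for i, g in enumerate(grapes) if i % 2 == 0]
    if si >= 6:
        grapes = []
    return leaves, tuple(grapes)


def _paint_labels(params: SceneParams, layout: _Layout, stage: str) -> np.ndarray:
    H, W = params.H, params.W
    bg = params.class_index("background")
    wood = params.class_index("Wood")
    grape = params.class_index("grape")
    labels = np.full((H, W), bg, dtype=np.int32)

    for (r0, c0), (r1, c1), width in layout.wood_segments:
        half = width // 2
        for off in range(-half, width - half):
            horizontal = abs(c1 - c0) > abs(r1 - r0)
            if horizontal:
                rr, cc = draw_line(r0 + off, c0, r1 + off, c1)
            else:
                rr, cc = draw_line(r0, c0 + off, r1, c1 + off)
            keep = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            labels[rr[keep], cc[keep]] = wood

    leaves, grapes = _active_subsets(layout, stage)
    for row, col, r_row, r_col in grapes:
        rr, cc = draw_ellipse(row, col, r_row, r_col, shape=(H, W))
        labels[rr, cc] = grape

    for grade, row, col, radius in leaves:
        rr, cc = draw_disk((row, col), radius, shape=(H, W))
        if not params.occlusion:
            keep = labels[rr, cc] != grape
            rr, cc = rr[keep], cc[keep]
        labels[rr, cc] = grade
    return labels


def _colorize(params: SceneParams, labels: np.ndarray, stage: str) -> np.ndarray:
    rng = np.random.default_rng(
        np.random.SeedSequence([int(params.seed), 1, STAGES.index(stage)])
    )
    image = np.empty((*labels.shape, 3), dtype=np.uint8)
    for k, spec in enumerate(params.palette):
        m = labels == k
        n = int(m.sum())
        if n == 0:
            continue
        colors = rng.normal(loc=spec.mean, scale=spec.sd, size=(n, 3))
        image[m] = np.clip(np.rint(colors), 0, 255).astype(np.uint8)
    return image


def scene_registry(params: SceneParams, seed: int = 0) -> ClassRegistry:
    """A lightweight registry carrying the palette's names and roles."""
    return make_reference_registry(params, n_per_class=8, seed=seed)


def render_scene(params: SceneParams, stage: str = "I0") -> SyntheticScene:
    """Render one stage of one vine; bit-identical for identical inputs."""
    layout = _make_layout(params)
    labels = _paint_labels(params, layout, stage)
    image = _colorize(params, labels, stage)
    registry = scene_registry(params)
    truth = LabelImage(labels, registry, roi=None)
    leaf_px = int(np.isin(labels, params.leaf_grade_indices).sum())
    grape_px = int((labels == params.class_index("grape")).sum())
    return SyntheticScene(
        image=image,
        truth=truth,
        true_leaf_area_m2=params.area_per_leaf_px * leaf_px,
        true_yield_kg=params.kg_per_grape_px * grape_px,
        stage=stage,
    )


def defoliation_series(params: SceneParams) -> list[SyntheticScene]:
    """All seven stages I0..I6 of one vine, sharing a single blob layout."""
    return [render_scene(params, stage) for stage in STAGES]


def make_reference_registry(
    params: SceneParams,
    n_per_class: int = 40,
    seed: int = 0,
    shrinkage: float = 0.1,
) -> ClassRegistry:
    """Sample reference pixels per class from the palette distributions.

    Stands in for manual reference-pixel picking: ``n_per_class`` draws per
    class (default 40, the conventional reference-group size).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    classes = []
    for spec in params.palette:
        colors = rng.normal(loc=spec.mean, scale=spec.sd, size=(n_per_class, 3))
        pixels = np.clip(np.rint(colors), 0, 255)
        classes.append(
            fit_reference_class(
                spec.name, PixelSample(pixels), shrinkage=shrinkage, roles=spec.roles
            )
        )
    return ClassRegistry(classes)


# ---------------------------------------------------------------------------
# Record-level calibration cohorts (no rendering): the regression structure
# of the study — pixel counts exactly proportional to the physical quantity,
# plus measurement noise on the ground truth.
# ---------------------------------------------------------------------------

#: Fraction of the stage-0 quantity surviving at each calibration stage:
#: thirds, matching removal of ~a third of leaves (or clusters) per step.
LEAF_STAGE_FACTORS = {"I0": 1.0, "I2": 2.0 / 3.0, "I4": 1.0 / 3.0}
YIELD_STAGE_FACTORS = {"I1": 1.0, "I3": 2.0 / 3.0, "I5": 1.0 / 3.0}


def simulate_calibration_cohort(
    target: str = "leaf_area_m2",
    n_vines: int = 10,
    seed: int = 0,
    noise_sd: float = 0.3,
    area_per_leaf_px: float = 2e-5,
    kg_per_grape_px: float = 1e-4,
) -> list[tuple[str, float, float]]:
    """Simulated (image_id, pixel_count, observed_measurement) records.

    Leaf-area cohorts use stages I0/I2/I4 with a per-vine baseline uniform
    on [1, 6] m²; yield cohorts use I1/I3/I5 with baseline uniform on
    [1, 5] kg.  Counts are exact linear images of the true quantity;
    observations add Gaussian measurement noise (sd ``noise_sd``, in the
    target's units).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    if target == "leaf_area_m2":
        factors, lo, hi, per_px = LEAF_STAGE_FACTORS, 1.0, 6.0, area_per_leaf_px
    elif target == "yield_kg":
        factors, lo, hi, per_px = YIELD_STAGE_FACTORS, 1.0, 5.0, kg_per_grape_px
    else:
        raise ValueError(f"unknown target {target!r}")
    records = []
    for vine in range(n_vines):
        base = rng.uniform(lo, hi)
        for stage, factor in factors.items():
            true_value = base * factor
            count = true_value / per_px
            observed = true_value + rng.normal(0.0, noise_sd)
            records.append((f"vine{vine:02d}_{stage}", float(count), float(observed)))
    return records
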