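"""Minimum-Mahalanobis-distance pixel classification.

Every pixel of an image (or of a rectangular ROI) is assigned to the
reference class with the lowest Mahalanobis colour distance.  Coordinate
convention, fixed once here and reused everywhere: 0-based, row-major,
row 0 is the TOP of the image; ROI rectangles are half-open
``(row_start, row_end, col_start, col_end)``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .color_model import (
    PixelSample,
    ReferenceClass,
    channel_covariance,
    fit_reference_class,
    mahalanobis_distances,
    regularize_covariance,
)

#: Label value for pixels outside the processed ROI.
UNPROCESSED = -1

VALID_ROLES = ("leaf", "grape", "background")

#: Pixel block size for the chunked nearest-reference distance computation.
_CHUNK = 65536


class RegistryError(ValueError):
    """Raised for an invalid class registry or reference file."""


class ROIError(ValueError):
    """Raised for an empty or out-of-bounds region of interest."""


@dataclass
class ClassRegistry:
    """An ordered collection of fitted reference classes.

    Class indices are the positions in ``classes`` (0..K-1).  At most one
    class may carry the ``"grape"`` role; any number may carry ``"leaf"``
    or ``"background"`` roles.
    """

    classes: list[ReferenceClass]

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise RegistryError(
                f"a registry needs at least 2 classes, got {len(self.classes)}"
            )
        names = [c.name for c in self.classes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise RegistryError(f"duplicate class name(s): {sorted(dupes)}")
        self.classes = [c.with_index(i) for i, c in enumerate(self.classes)]
        grapes = [c.name for c in self.classes if "grape" in c.roles]
        if len(grapes) > 1:
            raise RegistryError(f"at most one grape-role class allowed, got {grapes}")

    @property
    def K(self) -> int:
        return len(self.classes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.classes)

    def index_of(self, name: str) -> int:
        for c in self.classes:
            if c.name == name:
                return c.index
        raise KeyError(name)

    def indices_with_role(self, role: str) -> tuple[int, ...]:
        return tuple(c.index for c in self.classes if role in c.roles)

    @property
    def leaf_indices(self) -> tuple[int, ...]:
        return self.indices_with_role("leaf")

    @property
    def background_indices(self) -> tuple[int, ...]:
        return self.indices_with_role("background")

    @property
    def grape_index(self) -> int | None:
        idx = self.indices_with_role("grape")
        return idx[0] if idx else None

    def compatible_with(self, other: "ClassRegistry") -> bool:
        """Same class names, order, and roles (fitted statistics may differ)."""
        return self.names == other.names and all(
            a.roles == b.roles for a, b in zip(self.classes, other.classes)
        )


@dataclass
class LabelImage:
    """Per-pixel class assignments over an image or ROI."""

    labels: np.ndarray  # (H, W) int32; UNPROCESSED outside the ROI
    registry: ClassRegistry
    roi: tuple[int, int, int, int] | None = None

    @property
    def H(self) -> int:
        return self.labels.shape[0]

    @property
    def W(self) -> int:
        return self.labels.shape[1]

    @property
    def roi_slices(self) -> tuple[slice, slice]:
        if self.roi is None:
            return slice(0, self.H), slice(0, self.W)
        r0, r1, c0, c1 = self.roi
        return slice(r0, r1), slice(c0, c1)

    def labels_in_roi(self) -> np.ndarray:
        rs, cs = self.roi_slices
        return self.labels[rs, cs]

    def copy(self) -> "LabelImage":
        return LabelImage(self.labels.copy(), self.registry, self.roi)


@dataclass
class DistanceStack:
    """Per-class distance grids; argmin over classes reproduces the labels."""

    distances: np.ndarray  # (K, H, W) float64; +inf outside the ROI
    registry: ClassRegistry


def check_roi(roi, H: int, W: int) -> tuple[int, int, int, int]:
    r0, r1, c0, c1 = (int(v) for v in roi)
    if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
        raise ROIError(
            f"ROI {roi!r} is empty or outside an image of size {H}x{W} "
            "(expected half-open (row_start, row_end, col_start, col_end))"
        )
    return r0, r1, c0, c1


def _as_rgb_array(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {arr.shape}")
    return arr


def _nearest_reference_distances(
    pixels: np.ndarray, ref: ReferenceClass, S_inv: np.ndarray
) -> np.ndarray:
    """Min over the class's reference pixels instead of its centroid."""
    refs = ref.sample.pixels  # (R, 3)
    out = np.empty(pixels.shape[0])
    for start in range(0, pixels.shape[0], _CHUNK):
        block = pixels[start : start + _CHUNK]
        d = block[:, None, :] - refs[None, :, :]  # (n, R, 3)
        q = np.einsum("nrj,jk,nrk->nr", d, S_inv, d)
        out[start : start + _CHUNK] = np.sqrt(np.maximum(q.min(axis=1), 0.0))
    return out


def classify_image(
    image,
    registry: ClassRegistry,
    roi: tuple[int, int, int, int] | None = None,
    keep_distances: bool = False,
    covariance: str = "per_class",
    representative: str = "centroid",
    shrinkage: float = 0.1,
) -> tuple[LabelImage, DistanceStack | None]:
    """Label every in-ROI pixel with its minimum-distance class.

    Parameters
    ----------
    covariance : {"per_class", "pooled_image"}
        ``per_class`` (default) uses each class's own covariance estimated
        from its reference pixels.  ``pooled_image`` estimates one
        covariance from the pixels of the image under analysis (regularized
        with ``shrinkage``) and uses it for every class.
    representative : {"centroid", "nearest_reference"}
        Distance to the class mean (default) or the minimum distance over
        the individual reference pixels.

    Ties are broken toward the lowest class index.  Returns
    ``(label_image, distance_stack)``; the stack is ``None`` unless
    ``keep_distances`` is set.
    """
    arr = _as_rgb_array(image)
    H, W = arr.shape[:2]
    if roi is not None:
        r0, r1, c0, c1 = check_roi(roi, H, W)
    else:
        r0, r1, c0, c1 = 0, H, 0, W
    pixels = arr[r0:r1, c0:c1].reshape(-1, 3).astype(np.float64)

    if covariance == "per_class":
        inverses = [c.S_inv for c in registry.classes]
    elif covariance == "pooled_image":
        pooled = regularize_covariance(
            channel_covariance(PixelSample(pixels.clip(0, 255))), shrinkage
        )
        pooled_inv = np.linalg.inv(pooled.S)
        inverses = [pooled_inv] * registry.K
    else:
        raise ValueError(f"unknown covariance mode {covariance!r}")

    D = np.empty((registry.K, pixels.shape[0]))
    for k, (ref, S_inv) in enumerate(zip(registry.classes, inverses)):
        if representative == "centroid":
            D[k] = mahalanobis_distances(pixels, ref.means, S_inv)
        elif representative == "nearest_reference":
            D[k] = _nearest_reference_distances(pixels, ref, S_inv)
        else:
            raise ValueError(f"unknown representative mode {representative!r}")

    roi_labels = np.argmin(D, axis=0).astype(np.int32)  # ties -> lowest index
    labels = np.full((H, W), UNPROCESSED, dtype=np.int32)
    labels[r0:r1, c0:c1] = roi_labels.reshape(r1 - r0, c1 - c0)
    label_image = LabelImage(labels, registry, roi=roi)

    stack = None
    if keep_distances:
        grid = np.full((registry.K, H, W), np.inf)
        grid[:, r0:r1, c0:c1] = D.reshape(registry.K, r1 - r0, c1 - c0)
        stack = DistanceStack(grid, registry)
    return label_image, stack


# ---------------------------------------------------------------------------
# Reference annotation files
#
# JSON: {"classes": [{"name": ..., "roles": [...], "pixels": [[R,G,B], ...]},
#        ...]}  (class order is file order)
# CSV:  columns class,role,R,G,B — one row per pixel, role a '|'-joined flag
#       list repeated on each row of the class.
# ---------------------------------------------------------------------------


def _validate_class_entry(name: str, roles, pixels) -> None:
    for role in roles:
        if role not in VALID_ROLES:
            raise RegistryError(
                f"class {name!r}: unknown role {role!r} (valid: {VALID_ROLES})"
            )
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 4:
        raise RegistryError(
            f"class {name!r}: needs at least 4 RGB reference pixels, "
            f"got shape {arr.shape}"
        )
    if arr.min() < 0 or arr.max() > 255:
        raise RegistryError(f"class {name!r}: pixel values outside [0, 255]")


def _registry_from_entries(entries, shrinkage: float) -> ClassRegistry:
    names = [e[0] for e in entries]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise RegistryError(f"duplicate class name(s): {sorted(dupes)}")
    if len(entries) < 2:
        raise RegistryError(f"a reference file needs at least 2 classes, got {len(entries)}")
    classes = []
    for name, roles, pixels in entries:
        _validate_class_entry(name, roles, pixels)
        classes.append(
            fit_reference_class(
                name, PixelSample(np.asarray(pixels)), shrinkage=shrinkage, roles=tuple(roles)
            )
        )
    return ClassRegistry(classes)


def load_reference_file(path, shrinkage: float = 0.1) -> ClassRegistry:
    """Load a JSON or CSV reference-pixel annotation file and fit a registry."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries: list[tuple[str, tuple[str, ...], list]] = []
    if path.suffix.lower() == ".csv":
        by_name: dict[str, tuple[tuple[str, ...], list]] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                name = row["class"]
                roles = tuple(r for r in row.get("role", "").split("|") if r)
                rgb = [float(row["R"]), float(row["G"]), float(row["B"])]
                if name not in by_name:
                    by_name[name] = (roles, [])
                by_name[name][1].append(rgb)
        entries = [(n, roles, px) for n, (roles, px) in by_name.items()]
    else:
        with open(path) as fh:
            doc = json.load(fh)
        for cls in doc.get("classes", []):
            entries.append(
                (cls["name"], tuple(cls.get("roles", [])), cls["pixels"])
            )
    return _registry_from_entries(entries, shrinkage)


def save_reference_file(registry: ClassRegistry, path) -> None:
    """Write a registry's reference pixels back out (canonical formatting)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["class", "role", "R", "G", "B"])
            for cls in registry.classes:
                role = "|".join(cls.roles)
                for px in cls.sample.pixels:
                    writer.writerow([cls.name, role, *(int(v) for v in px)])
    else:
        doc = {
            "classes": [
                {
                    "name": cls.name,
                    "roles": list(cls.roles),
                    "pixels": [[int(v) for v in px] for px in cls.sample.pixels],
                }
                for cls in registry.classes
            ]
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")
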