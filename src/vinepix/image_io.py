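"""Image reading/writing and indexed label-map files.

``read_image`` normalizes everything to 8-bit RGB: alpha channels are
dropped, grayscale is promoted by channel replication, and 16-bit data is
rescaled with ``value * 255 / 65535`` rounded half-up.  Label images are
written as indexed PNGs with a deterministic palette plus a JSON sidecar
mapping index to class name, so ``read(write(x)) == x``.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from PIL import Image

from .classifier import UNPROCESSED, ClassRegistry, LabelImage

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg", ".tif", ".tiff")

#: PNG index used for out-of-ROI ("unprocessed") pixels.
SENTINEL_INDEX = 255

#: Deterministic, visually distinct display palette, cycled over class indices.
LABEL_COLORS = (
    (230, 25, 75), (60, 180, 75), (255, 225, 25), (0, 130, 200),
    (245, 130, 48), (145, 30, 180), (70, 240, 240), (240, 50, 230),
    (210, 245, 60), (250, 190, 212), (0, 128, 128), (220, 190, 255),
    (170, 110, 40), (255, 250, 200), (128, 0, 0), (170, 255, 195),
    (128, 128, 0), (255, 215, 180), (0, 0, 128), (128, 128, 128),
)


class ImageFormatError(ValueError):
    """Raised for unreadable or unsupported image files."""


def read_image(path) -> np.ndarray:
    """Read PNG/TIFF/JPEG as an (H, W, 3) uint8 RGB array."""
    path = Path(path)
    if path.suffix.lower() not in IMAGE_SUFFIXES:
        raise ImageFormatError(f"{path}: unsupported image format {path.suffix!r}")
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise ImageFormatError(f"{path}: could not read image ({exc})") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ImageFormatError(f"{path}: unsupported image layout {arr.shape}")
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return np.floor(arr.astype(np.float64) * 255.0 / 65535.0 + 0.5).astype(np.uint8)
    raise ImageFormatError(f"{path}: unsupported pixel dtype {arr.dtype}")


def write_image(image: np.ndarray, path) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_label_image(label_image: LabelImage, path) -> None:
    """Write an indexed PNG plus a JSON sidecar with the class-name mapping."""
    path = Path(path)
    K = label_image.registry.K
    if K > SENTINEL_INDEX:
        raise ValueError(f"cannot encode {K} classes in an 8-bit indexed PNG")
    data = label_image.labels.astype(np.int32).copy()
    data[data == UNPROCESSED] = SENTINEL_INDEX
    img = Image.fromarray(data.astype(np.uint8), mode="P")
    palette = [0] * (256 * 3)
    for k in range(K):
        color = LABEL_COLORS[k % len(LABEL_COLORS)]
        palette[3 * k : 3 * k + 3] = color
    img.putpalette(palette)
    img.save(path)
    sidecar = {
        "classes": list(label_image.registry.names),
        "sentinel": SENTINEL_INDEX,
        "roi": list(label_image.roi) if label_image.roi else None,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=2)
        fh.write("\n")


def read_label_array(path) -> tuple[np.ndarray, list[str], tuple | None]:
    """Read an indexed label PNG; returns (labels, class names, roi)."""
    path = Path(path)
    arr = np.asarray(Image.open(path)).astype(np.int32)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing label sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    arr[arr == sidecar.get("sentinel", SENTINEL_INDEX)] = UNPROCESSED
    roi = tuple(sidecar["roi"]) if sidecar.get("roi") else None
    return arr, list(sidecar["classes"]), roi


def read_label_image(path, registry: ClassRegistry) -> LabelImage:
    """Read a label PNG into a LabelImage bound to ``registry``."""
    labels, names, roi = read_label_array(path)
    if tuple(names) != registry.names:
        raise ValueError(
            f"label file {path} classes {names} do not match registry {list(registry.names)}"
        )
    return LabelImage(labels, registry, roi=roi)
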