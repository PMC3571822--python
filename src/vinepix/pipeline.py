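"""The batch pipeline: read, classify, clean, count, save — per image.

Images are processed in filename-sorted order for reproducible logs; a
failure on one image is logged and skipped rather than aborting the batch.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from .classifier import ClassRegistry, classify_image, load_reference_file
from .config import PipelineConfig
from .image_io import IMAGE_SUFFIXES, read_image, write_label_image
from .postprocess import clean_grape_class
from .quantify import ClassCounts, count_pixels, write_results

logger = logging.getLogger("vinepix")


def resize_rgb(image: np.ndarray, width: int, height: int) -> np.ndarray:
    """Bilinear resize to (height, width), back to uint8."""
    out = _sk_resize(
        image.astype(np.float64),
        (height, width),
        order=1,
        preserve_range=True,
        anti_aliasing=False,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def list_input_images(images: str | Path) -> list[Path]:
    path = Path(images)
    if path.is_file():
        return [path]
    files = sorted(
        p for p in path.glob("*") if p.suffix.lower() in IMAGE_SUFFIXES
    )
    if not files:
        raise FileNotFoundError(f"no input images found under {path}")
    return files


def process_image(
    path: Path, registry: ClassRegistry, config: PipelineConfig
) -> tuple[ClassCounts, "LabelImage"]:
    image = read_image(path)
    if config.resize_to is not None:
        image = resize_rgb(image, config.resize_to[0], config.resize_to[1])
    roi = tuple(config.roi) if config.roi else None
    label_image, stack = classify_image(
        image,
        registry,
        roi=roi,
        keep_distances=config.clean_grape,
        covariance=config.covariance,
        representative=config.representative,
        shrinkage=config.shrinkage,
    )
    if config.clean_grape and registry.grape_index is not None:
        label_image = clean_grape_class(
            label_image, stack, config.morph, config.lower_fraction
        )
    counts = count_pixels(label_image, image_id=path.stem)
    return counts, label_image


def run_pipeline(config: PipelineConfig) -> list[ClassCounts]:
    """Run the whole per-image pipeline and write labels + a results CSV."""
    registry = load_reference_file(config.reference_file, shrinkage=config.shrinkage)
    files = list_input_images(config.images)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    all_counts: list[ClassCounts] = []
    for path in files:
        t0 = time.perf_counter()
        try:
            counts, label_image = process_image(path, registry, config)
        except Exception as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            continue
        write_label_image(label_image, out_dir / f"{path.stem}_labels.png")
        all_counts.append(counts)
        logger.info(
            "%s: %s (%.2fs)",
            path.name,
            {k: v for k, v in counts.counts.items() if v},
            time.perf_counter() - t0,
        )
    write_results(all_counts, out_dir / "class_counts.csv")
    return all_counts
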