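"""Optional dataset adapters for external gland-segmentation layouts.

These readers cover the two common public colorectal gland datasets
(never required by the test-suite, which runs entirely on synthetic
tiles):

* CRAG layout: ``<root>/{train,valid}/Images/*.png`` with instance
  label PNGs of the same stem under ``Annotation/``.
* GlaS layout: flat directory of ``*.bmp`` images with ``*_anno.bmp``
  instance maps; test images are named ``testA_*`` / ``testB_*`` which
  defines the A (60 images) / B (20 images) subgroups.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .core_io import (ImageTile, InstanceLabelMap, read_image,
                      relabel_contiguous)

__all__ = ["load_paired_directory", "load_crag", "load_glas"]


def _read_any_label(path: Path) -> InstanceLabelMap:
    arr = np.asarray(Image.open(path).convert("I"))
    return InstanceLabelMap(relabel_contiguous(arr.astype(np.int64)))


def load_paired_directory(image_dir: str | Path, label_dir: str | Path,
                          exts=(".png", ".bmp", ".tif", ".tiff")
                          ) -> list[tuple[ImageTile, InstanceLabelMap]]:
    """Pair images with equally-named label maps in another directory."""
    image_dir, label_dir = Path(image_dir), Path(label_dir)
    pairs = []
    for img_path in sorted(p for p in image_dir.iterdir()
                           if p.suffix.lower() in exts):
        for ext in exts:
            lab_path = label_dir / (img_path.stem + ext)
            if lab_path.exists():
                break
        else:
            raise FileNotFoundError(f"no label map for {img_path.name}")
        pairs.append((read_image(img_path), _read_any_label(lab_path)))
    if not pairs:
        raise FileNotFoundError(f"no images found in {image_dir}")
    return pairs


def load_crag(root: str | Path, split: str = "train"
              ) -> list[tuple[ImageTile, InstanceLabelMap]]:
    root = Path(root) / split
    return load_paired_directory(root / "Images", root / "Annotation")


def load_glas(root: str | Path, split: str = "train"
              ) -> list[tuple[ImageTile, InstanceLabelMap]]:
    """split: 'train', 'testA' or 'testB'."""
    root = Path(root)
    prefix = {"train": "train", "testA": "testA", "testB": "testB"}[split]
    pairs = []
    for img_path in sorted(root.glob(f"{prefix}_*.bmp")):
        if img_path.stem.endswith("_anno"):
            continue
        lab_path = root / f"{img_path.stem}_anno.bmp"
        if not lab_path.exists():
            raise FileNotFoundError(lab_path)
        pairs.append((read_image(img_path), _read_any_label(lab_path)))
    if not pairs:
        raise FileNotFoundError(f"no {split} images under {root}")
    return pairs
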