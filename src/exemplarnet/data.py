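"""Image-folder loading and bilinear resizing.

Datasets follow the ``root/{train,test}/<class-name>/*.png`` layout. Class
names are the sorted subdirectory names; label indices follow that order.
Images are decoded with Pillow, converted to RGB (grayscale inputs are
channel-replicated), bilinearly resized, and scaled to [0, 1] float32.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import DataError

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}


def load_image(path, side: int) -> np.ndarray:
    """One image as HWC float32 in [0, 1], bilinearly resized to ``side``."""
    with Image.open(path) as im:
        im = im.convert("RGB")
        if im.size != (side, side):
            im = im.resize((side, side), Image.BILINEAR)
        return np.asarray(im, dtype=np.float32) / 255.0


def resize_image(image: np.ndarray, side: int) -> np.ndarray:
    """Bilinear resize of an HWC float array (values preserved, not re-quantized)."""
    img = np.asarray(image, dtype=np.float32)
    if img.shape[0] == side and img.shape[1] == side:
        return img
    channels = [
        np.asarray(Image.fromarray(img[:, :, c], mode="F").resize((side, side),
                                                                  Image.BILINEAR))
        for c in range(img.shape[2])
    ]
    return np.stack(channels, axis=-1).astype(np.float32)


def list_image_folder(root) -> tuple[list[Path], list[str], list[str]]:
    """Sorted (paths, labels, class_names) for one split directory."""
    root = Path(root)
    if not root.is_dir():
        raise DataError(f"image folder {root} does not exist")
    class_names = sorted(d.name for d in root.iterdir() if d.is_dir())
    if not class_names:
        raise DataError(f"image folder {root} has no class subdirectories")
    paths, labels = [], []
    for name in class_names:
        files = sorted(p for p in (root / name).iterdir()
                       if p.suffix.lower() in IMAGE_EXTENSIONS)
        if not files:
            raise DataError(f"class folder {root / name} contains no images")
        paths.extend(files)
        labels.extend([name] * len(files))
    return paths, labels, class_names


def load_image_folder(root, side: int):
    """Load a split directory into (X, y, class_names, paths).

    X is (N, C, S, S) float32 NCHW; y holds integer label indices into
    ``class_names``. Unreadable files are skipped with a warning; if every file
    is unreadable a :class:`DataError` is raised.
    """
    paths, labels, class_names = list_image_folder(root)
    images, kept_labels, kept_paths = [], [], []
    skipped = 0
    for p, lab in zip(paths, labels):
        try:
            images.append(load_image(p, side).transpose(2, 0, 1))
        except (OSError, ValueError) as e:
            warnings.warn(f"skipping unreadable image {p}: {e}")
            skipped += 1
            continue
        kept_labels.append(lab)
        kept_paths.append(p)
    if not images:
        raise DataError(f"no readable images under {root} ({skipped} skipped)")
    if skipped:
        warnings.warn(f"{skipped} unreadable image(s) skipped under {root}")
    name_to_idx = {n: i for i, n in enumerate(class_names)}
    y = np.array([name_to_idx[l] for l in kept_labels], dtype=np.int64)
    return np.stack(images), y, class_names, kept_paths
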