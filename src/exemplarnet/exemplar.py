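"""Exemplar (patch-based) deep feature extraction.

A 224x224 image is divided into nine overlapping 112x112 patches (stride 56:
top-left offsets {0, 56, 112} in both axes, row-major). GAP features are
extracted from the full image and from every patch with the same pretrained
backbone, then concatenated — block t of the output holds the features of
input t (t = 1 is the full image, t = k + 1 is patch k), giving a
10 x 1280 = 12,800-dimensional descriptor at the default width.

Geometry generalises proportionally: for an input side S the patch side is
S / 2 and the stride S / 4, so the 3 x 3 overlapping grid (corner pixels
covered once, the central square four times) is preserved at any scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .architecture import LiteNeXt
from .data import list_image_folder, load_image, resize_image
from .errors import DataError, FormatError, InputError

BLOCK_NAMES = ("image",) + tuple(f"patch{k}" for k in range(1, 10))
LABEL_COLUMN = "label"
SAMPLE_COLUMN = "sample_id"


@dataclass
class PatchSet:
    """Nine overlapping patches of one image, with their 0-based top-left corners."""

    patches: list[np.ndarray]
    offsets: list[tuple[int, int]]
    source_side: int


@dataclass
class ExemplarFeature:
    """One concatenated descriptor; block t (1-based) spans values
    [(t-1) * gap_length, t * gap_length)."""

    values: np.ndarray
    gap_length: int

    def block(self, t: int) -> np.ndarray:
        """Feature block t in 1..10 (1 = full image, k + 1 = patch k)."""
        g = self.gap_length
        return self.values[(t - 1) * g: t * g]


@dataclass
class FeatureMatrix:
    """N x (10 * gap_length) matrix with labels, sample ids and column names."""

    X: np.ndarray
    y: np.ndarray                      # class names (strings), length N
    sample_ids: list[str]
    columns: list[str]

    @property
    def feature_block_map(self) -> list[str]:
        """Source block (image / patch1..9) of every column."""
        return [c.rsplit("_", 1)[0] for c in self.columns]


def divide_patches(image: np.ndarray, patch_side: int | None = None,
                   stride: int | None = None) -> PatchSet:
    """Divide an HWC image into the 3x3 grid of overlapping patches.

    Defaults scale with the image: ``patch_side = side // 2`` and
    ``stride = side // 4`` (112 and 56 for a 224 input). The image side must
    equal ``patch_side + 2 * stride`` so that offsets {0, stride, 2 * stride}
    tile it exactly.
    """
    img = np.asarray(image)
    if img.ndim != 3:
        raise InputError(f"expected an HWC image, got shape {img.shape}")
    side = img.shape[0]
    if img.shape[1] != side:
        raise InputError(f"expected a square image, got shape {img.shape}")
    patch_side = side // 2 if patch_side is None else patch_side
    stride = side // 4 if stride is None else stride
    expected = patch_side + 2 * stride
    if side != expected:
        raise InputError(
            f"image side {side} incompatible with patch_side={patch_side}, "
            f"stride={stride}: expected side {expected}")
    starts = (0, stride, 2 * stride)
    patches, offsets = [], []
    for r in starts:
        for c in starts:
            patches.append(img[r:r + patch_side, c:c + patch_side, :])
            offsets.append((r, c))
    return PatchSet(patches=patches, offsets=offsets, source_side=side)


def _to_nchw(images: list[np.ndarray]) -> np.ndarray:
    return np.stack([np.asarray(im, dtype=np.float32).transpose(2, 0, 1)
                     for im in images])


def extract_exemplar_feature(model: LiteNeXt, image: np.ndarray,
                             patch_mode: str = "resize") -> ExemplarFeature:
    """Concatenated GAP features of the full image and its nine patches.

    ``patch_mode='resize'`` (default) bilinearly upscales each patch to the
    network input side before the forward pass; ``'native'`` runs the patches
    at their own resolution through the fully convolutional trunk (GAP still
    yields one value per channel), which requires the patch side to be a
    multiple of 4 and large enough to survive the three downsamples.
    """
    if patch_mode not in ("resize", "native"):
        raise InputError(f"unknown patch_mode {patch_mode!r}")
    side = model.spec.input_side
    img = resize_image(np.asarray(image, dtype=np.float32), side)
    patchset = divide_patches(img)
    gap_length = model.spec.filters[4]
    if patch_mode == "resize":
        inputs = [img] + [resize_image(p, side) for p in patchset.patches]
        feats = model.features_batch(_to_nchw(inputs))
    else:
        full = model.features_batch(_to_nchw([img]))
        patch_feats = model.features_batch(_to_nchw(patchset.patches))
        feats = np.vstack([full, patch_feats])
    return ExemplarFeature(values=feats.reshape(-1).astype(np.float32),
                           gap_length=gap_length)


def _columns(gap_length: int) -> list[str]:
    return [f"{b}_{r:04d}" for b in BLOCK_NAMES for r in range(1, gap_length + 1)]


def build_feature_matrix(model: LiteNeXt, folder, patch_mode: str = "resize",
                         ) -> FeatureMatrix:
    """One exemplar-feature row per image of a labeled split directory.

    Rows follow deterministic sorted-path order (class directories sorted, files
    sorted within each class). Unreadable images are skipped with a warning; an
    entirely unreadable folder raises :class:`DataError`.
    """
    folder = Path(folder)
    paths, labels, _ = list_image_folder(folder)
    side = model.spec.input_side
    rows, kept_labels, sample_ids = [], [], []
    skipped = 0
    for p, lab in zip(paths, labels):
        try:
            img = load_image(p, side)
        except (OSError, ValueError) as e:
            warnings.warn(f"skipping unreadable image {p}: {e}")
            skipped += 1
            continue
        rows.append(extract_exemplar_feature(model, img, patch_mode).values)
        kept_labels.append(lab)
        sample_ids.append(str(p.relative_to(folder)))
    if not rows:
        raise DataError(f"no readable images under {folder} ({skipped} skipped)")
    if skipped:
        warnings.warn(f"{skipped} unreadable image(s) skipped under {folder}")
    gap_length = model.spec.filters[4]
    return FeatureMatrix(X=np.vstack(rows), y=np.array(kept_labels, dtype=object),
                         sample_ids=sample_ids, columns=_columns(gap_length))


def save_features(fm: FeatureMatrix, path) -> None:
    """Labeled tabular CSV: sample_id, one column per feature (named by its
    source block), and a final class-name label column."""
    df = pd.DataFrame(fm.X.astype(np.float32), columns=fm.columns)
    df.insert(0, SAMPLE_COLUMN, fm.sample_ids)
    df[LABEL_COLUMN] = fm.y
    df.to_csv(path, index=False)


def load_features(path) -> FeatureMatrix:
    try:
        df = pd.read_csv(path)
    except (OSError, ValueError) as e:
        raise FormatError(f"cannot read feature file {path}: {e}") from e
    if df.columns[0] != SAMPLE_COLUMN or df.columns[-1] != LABEL_COLUMN:
        raise FormatError(
            f"feature file {path} must start with '{SAMPLE_COLUMN}' and end "
            f"with '{LABEL_COLUMN}' columns")
    feature_cols = list(df.columns[1:-1])
    n_per_block = len(feature_cols) / len(BLOCK_NAMES)
    if n_per_block != int(n_per_block) or n_per_block < 1:
        raise FormatError(
            f"feature file {path} has {len(feature_cols)} feature columns, "
            f"not a multiple of the {len(BLOCK_NAMES)} source blocks")
    try:
        X = df[feature_cols].to_numpy(dtype=np.float32)
    except ValueError as e:
        raise FormatError(f"non-numeric feature values in {path}: {e}") from e
    return FeatureMatrix(X=X, y=df[LABEL_COLUMN].to_numpy(dtype=object),
                         sample_ids=df[SAMPLE_COLUMN].astype(str).tolist(),
                         columns=feature_cols)
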