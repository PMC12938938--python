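"""Seeded synthetic data with the multi-scale structure the pipeline assumes.

Two generators:

* :func:`generate_image_dataset` writes an image-folder dataset whose class
  signal lives at two spatial scales — a smooth global cosine template (class
  specific frequency/phase across the whole image) and a high-frequency
  checkerboard motif confined to one class-specific cell of the 3x3 overlapping
  patch grid. With the global amplitude at zero the discriminative signal is
  *local only*, so patch-level features must carry information that full-image
  GAP features dilute; this is the premise the exemplar pipeline exploits.
* :func:`generate_feature_fixture` draws a labeled tabular matrix with a known
  informative column subset (class-dependent means, unit noise), used to probe
  the feature selector's recovery behaviour.

Generation is pure given (spec, seed): the same spec writes byte-identical
files. Checkerboards and cosines are chosen so the class signal survives
downscaling to small test-time image sides.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ConfigurationError
from .exemplar import FeatureMatrix, _columns


@dataclass
class SyntheticImageSpec:
    n_classes: int = 3
    train_per_class: int = 40
    test_per_class: int = 15
    image_side: int = 224
    global_amplitude: float = 0.35    # low-frequency class template strength
    motif_amplitude: float = 0.5      # local checkerboard strength
    motif_cell: int = 4               # checkerboard cell size in pixels
    noise_sigma: float = 0.05         # i.i.d. pixel noise
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if self.global_amplitude < 0 or self.motif_amplitude < 0:
            raise ConfigurationError("amplitudes must be >= 0")
        if self.image_side % 4:
            raise ConfigurationError("image_side must be a multiple of 4")


def _global_template(side: int, cls: int) -> np.ndarray:
    """Smooth class-specific cosine surface in [-1, 1]."""
    r, c = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    theta = 2.0 * np.pi * cls / 7.0
    freq = 1.0 + 0.5 * cls
    phase = 0.9 * cls
    u = (r * np.cos(theta) + c * np.sin(theta)) / side
    return np.cos(2.0 * np.pi * freq * u + phase)


def _motif(side: int, cls: int, cell: int) -> np.ndarray:
    """Class-specific checkerboard texture in {-1, +1} (cell size varies by class)."""
    cell = cell + (cls % 3)
    r, c = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    if cls % 2:
        board = ((r // cell + c // cell) % 2)
    else:
        board = (((r + c) // cell) % 2)
    return board * 2.0 - 1.0


def motif_region(cls: int) -> int:
    """Index (0..8, row-major) of the patch-grid cell carrying class ``cls``'s motif."""
    return (2 * cls + 1) % 9


def _render(spec: SyntheticImageSpec, cls: int, rng: np.random.Generator,
            ) -> np.ndarray:
    s = spec.image_side
    stride, ps = s // 4, s // 2
    img = 0.5 + spec.global_amplitude * 0.5 * _global_template(s, cls)
    region = motif_region(cls)
    r0, c0 = (region // 3) * stride, (region % 3) * stride
    # motif fills the central half of its 112-equivalent patch region
    q = ps // 4
    mr, mc = r0 + q, c0 + q
    mside = ps // 2
    img = img.copy()
    img[mr:mr + mside, mc:mc + mside] += (
        spec.motif_amplitude * 0.5 * _motif(mside, cls, spec.motif_cell))
    img = img[:, :, None] + rng.normal(0.0, spec.noise_sigma, size=(s, s, 3))
    return np.clip(img, 0.0, 1.0)


def generate_image_dataset(spec: SyntheticImageSpec, out_dir) -> Path:
    """Write ``train/<class>/*.png`` and ``test/<class>/*.png`` plus a
    ``manifest.csv`` recording the spec and per-file labels; returns the root."""
    spec.validate()
    root = Path(out_dir)
    rng = np.random.default_rng(spec.seed)
    manifest_rows = []
    for split, count in (("train", spec.train_per_class), ("test", spec.test_per_class)):
        for cls in range(spec.n_classes):
            cname = f"class{cls}"
            d = root / split / cname
            d.mkdir(parents=True, exist_ok=True)
            for i in range(count):
                arr = _render(spec, cls, rng)
                path = d / f"{split}_{cname}_{i:04d}.png"
                Image.fromarray((arr * 255).round().astype(np.uint8)).save(path)
                manifest_rows.append({
                    "file": str(path.relative_to(root)),
                    "split": split,
                    "class": cname,
                    "motif_region": motif_region(cls),
                    "seed": spec.seed,
                })
    with open(root / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(manifest_rows[0]))
        writer.writeheader()
        writer.writerows(manifest_rows)
    return root


@dataclass
class FeatureFixtureSpec:
    n_samples: int = 300              # balanced across classes
    n_features: int = 1500
    n_informative: int = 120
    n_classes: int = 3
    effect_size: float = 1.5          # class-mean separation in noise-SD units
    seed: int = 0

    def validate(self) -> None:
        if self.n_informative > self.n_features:
            raise ConfigurationError("n_informative cannot exceed n_features")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")


def generate_feature_fixture(spec: FeatureFixtureSpec,
                             ) -> tuple[FeatureMatrix, np.ndarray]:
    """Balanced labeled matrix: informative columns get class-dependent means
    (adjacent classes separated by ``effect_size`` noise SDs, randomly signed
    per column), remaining columns are pure N(0, 1) noise.

    Returns the matrix and the 0-based indices of the informative columns
    (scattered uniformly over the feature axis).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, d, k = spec.n_samples, spec.n_features, spec.n_classes
    per = n // k
    y_int = np.repeat(np.arange(k), per)
    if y_int.size < n:
        y_int = np.concatenate([y_int, np.arange(n - y_int.size)])
    X = rng.normal(size=(n, d))
    informative = np.sort(rng.choice(d, size=spec.n_informative, replace=False))
    signs = rng.choice([-1.0, 1.0], size=spec.n_informative)
    centered = (y_int - (k - 1) / 2.0)[:, None]
    X[:, informative] += spec.effect_size * centered * signs[None, :]
    y = np.array([f"class{c}" for c in y_int], dtype=object)
    gap = d // 10 if d % 10 == 0 else None
    columns = (_columns(gap) if gap else
               [f"feat_{j:04d}" for j in range(1, d + 1)])
    fm = FeatureMatrix(X=X.astype(np.float32), y=y,
                       sample_ids=[f"sample_{i:04d}" for i in range(n)],
                       columns=columns)
    return fm, informative
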