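"""Dataset I/O and paired augmentations.

Images are 2-D grayscale arrays in [0, 1] (PNG 8/16-bit or single-slice
NIfTI), masks are integer label maps (0 = background, 1 = organ, 2 = lesion),
and every sample id has a free-text annotation in a CSV / JSON-Lines table.
Masks and images are row-major with the origin at the top-left and
pixel-center alignment; NIfTI affines are passed through untouched.

The augmentation menu is fixed to the perturbations the trainer uses:
identity, 90-degree rotation, horizontal flip, Gaussian noise and brightness
shift.  Spatial kinds are label-preserving bijections of the grid, so
applying the same transform to an image and its mask keeps them aligned; the
same spatial transforms are available on autodiff tensors so that prediction
maps can be transported through T for consistency training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .autodiff import Tensor

SPATIAL_KINDS = ("identity", "rotation90", "horizontal-flip")
INTENSITY_KINDS = ("gaussian-noise", "brightness")

#: Text used in place of the real annotation when text guidance is disabled
#: (the "-NT" configuration: non-informative constant input).
NO_TEXT_CONSTANT = "no finding"


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ImageBatch:
    """Normalized image tensor (batch, 1, H, W) with sample identifiers."""

    pixels: np.ndarray
    ids: list[str]

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 4 or self.pixels.shape[1] != 1:
            raise ValueError(f"ImageBatch expects (B,1,H,W), got {self.pixels.shape}")
        if not np.isfinite(self.pixels).all():
            raise ValueError("ImageBatch contains NaN/Inf")

    def validate_depth(self, depth: int) -> None:
        h, w = self.pixels.shape[2:]
        if h % (1 << depth) or w % (1 << depth):
            raise ValueError(f"spatial dims {(h, w)} not divisible by 2^{depth}")


@dataclass
class MaskBatch:
    """Integer label map (batch, H, W) with values in {0..num_classes-1}."""

    labels: np.ndarray
    num_classes: int = 3

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"MaskBatch expects (B,H,W), got {self.labels.shape}")
        if self.labels.min() < 0 or self.labels.max() >= self.num_classes:
            raise ValueError("mask labels outside class range")


@dataclass
class TextAnnotation:
    """A tokenized text string (ids are filled in by the text encoder)."""

    text: str
    token_ids: np.ndarray | None = None
    length: int = 0


@dataclass
class Sample:
    """One dataset item; `mask` is None for the unlabeled pool."""

    id: str
    image: np.ndarray            # (H, W) float in [0, 1]
    text: str
    mask: np.ndarray | None = None


@dataclass
class AugmentTransform:
    """A deterministic perturbation T.

    kind: identity | rotation90 | horizontal-flip | gaussian-noise | brightness
    params: {"k": int} for rotation90, {"sd": float} for gaussian-noise,
            {"delta": float} for brightness.
    """

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in SPATIAL_KINDS + INTENSITY_KINDS:
            raise ValueError(f"unknown transform kind: {self.kind!r}")

    @property
    def is_spatial(self) -> bool:
        return self.kind in SPATIAL_KINDS


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_image(path: Path) -> np.ndarray:
    """Read a grayscale image into float [0, 1] (PNG 8/16-bit, or 2-D NIfTI)."""
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        arr = np.asanyarray(nib.load(str(path)).dataobj).squeeze()
        arr = arr.astype(np.float64)
        lo, hi = arr.min(), arr.max()
        return ((arr - lo) / (hi - lo) if hi > lo else arr * 0.0).astype(np.float32)
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr[..., 0]
    scale = 65535.0 if arr.dtype == np.uint16 or (arr.dtype == np.int32 and arr.max() > 255) else 255.0
    return (arr.astype(np.float32) / scale).clip(0.0, 1.0)


def write_image(path: Path, image: np.ndarray) -> None:
    """Write a float [0, 1] image as 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    Image.fromarray((arr * 65535.0 + 0.5).astype(np.uint16)).save(path)


def read_mask(path: Path) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        return np.asanyarray(nib.load(str(path)).dataobj).squeeze().astype(np.int64)
    return np.asarray(Image.open(path)).astype(np.int64)


def write_mask(path: Path, labels: np.ndarray) -> None:
    Image.fromarray(np.asarray(labels, dtype=np.uint8)).save(path)


def read_text_table(path: Path) -> dict[str, str]:
    """Read an id -> text table (CSV with columns id,text; or JSON Lines)."""
    path = Path(path)
    if path.suffix in (".jsonl", ".json"):
        table = {}
        for line in path.read_text().splitlines():
            if line.strip():
                row = json.loads(line)
                table[str(row["id"])] = str(row["text"])
        return table
    df = pd.read_csv(path, dtype={"id": str})
    return dict(zip(df["id"], df["text"]))


def write_text_table(path: Path, table: dict[str, str]) -> None:
    pd.DataFrame({"id": list(table), "text": list(table.values())}).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# Dataset loading
# ---------------------------------------------------------------------------

_IMAGE_EXTS = (".png", ".nii", ".nii.gz")


def _stem(p: Path) -> str:
    name = p.name
    for ext in (".nii.gz", ".nii", ".png"):
        if name.endswith(ext):
            return name[: -len(ext)]
    return p.stem


def load_dataset(image_dir: Path, mask_dir: Path | None, text_table: Path,
                 labeled_fraction: float | None = None,
                 no_text: bool = False) -> tuple[list[Sample], list[Sample]]:
    """Load (labeled, unlabeled) sample lists.

    A sample is labeled iff a mask file with its id exists in `mask_dir`.
    `labeled_fraction`, if given, deterministically demotes trailing labeled
    samples (sorted by id) to the unlabeled pool until at most that fraction
    of all samples remains labeled.  With `no_text`, every annotation is
    replaced by the constant ``"no finding"`` string (text-disabled ablation).
    """
    image_dir = Path(image_dir)
    paths = sorted([p for p in image_dir.iterdir()
                    if any(p.name.endswith(e) for e in _IMAGE_EXTS)],
                   key=lambda p: p.name)
    if not paths:
        raise FileNotFoundError(f"no images under {image_dir}")
    table = read_text_table(text_table)
    mask_dir = Path(mask_dir) if mask_dir is not None else None

    labeled: list[Sample] = []
    unlabeled: list[Sample] = []
    for p in paths:
        sid = _stem(p)
        if sid not in table:
            raise KeyError(f"text table has no row for sample id {sid!r}")
        image = read_image(p)
        text = NO_TEXT_CONSTANT if no_text else table[sid]
        mask = None
        if mask_dir is not None and mask_dir.exists():
            for ext in (".png", ".nii", ".nii.gz"):
                mp = mask_dir / (sid + ext)
                if mp.exists():
                    mask = read_mask(mp)
                    break
        if mask is not None:
            if mask.shape != image.shape:
                raise ValueError(
                    f"mask/image shape mismatch for {sid!r}: "
                    f"{mask.shape} vs {image.shape}")
            labeled.append(Sample(sid, image, text, mask))
        else:
            unlabeled.append(Sample(sid, image, text))

    if labeled_fraction is not None:
        n_total = len(labeled) + len(unlabeled)
        n_keep = int(round(labeled_fraction * n_total))
        for s in labeled[n_keep:]:
            unlabeled.append(Sample(s.id, s.image, s.text))
        labeled = labeled[:n_keep]
        unlabeled.sort(key=lambda s: s.id)
    return labeled, unlabeled


def to_batch(samples: list[Sample]) -> tuple[ImageBatch, MaskBatch | None, list[str]]:
    """Stack samples into batch containers (masks only if all are labeled)."""
    imgs = np.stack([s.image for s in samples])[:, None]
    batch = ImageBatch(imgs, [s.id for s in samples])
    masks = None
    if all(s.mask is not None for s in samples):
        masks = MaskBatch(np.stack([s.mask for s in samples]))
    return batch, masks, [s.text for s in samples]


# ---------------------------------------------------------------------------
# Augmentations
# ---------------------------------------------------------------------------

def apply_transform(t: AugmentTransform, img: ImageBatch,
                    mask: MaskBatch | None = None
                    ) -> tuple[ImageBatch, MaskBatch | None]:
    """Apply T to an image batch (and, for spatial kinds, its mask)."""
    px = img.pixels
    labels = mask.labels if mask is not None else None
    if t.kind == "identity":
        out, lab = px, labels
    elif t.kind == "rotation90":
        if px.shape[2] != px.shape[3]:
            raise ValueError("rotation90 requires a square grid")
        k = int(t.params.get("k", 1))
        out = np.rot90(px, k=k, axes=(2, 3)).copy()
        lab = np.rot90(labels, k=k, axes=(1, 2)).copy() if labels is not None else None
    elif t.kind == "horizontal-flip":
        out = px[:, :, :, ::-1].copy()
        lab = labels[:, :, ::-1].copy() if labels is not None else None
    elif t.kind == "gaussian-noise":
        sd = float(t.params.get("sd", 0.05))
        rng = np.random.default_rng(t.seed)
        out = np.clip(px + rng.normal(0.0, sd, px.shape).astype(np.float32), 0.0, 1.0)
        lab = labels
    elif t.kind == "brightness":
        delta = float(t.params.get("delta", 0.1))
        out = np.clip(px + delta, 0.0, 1.0)
        lab = labels
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(f"unknown transform kind: {t.kind!r}")
    new_img = ImageBatch(out, list(img.ids))
    new_mask = MaskBatch(lab, mask.num_classes) if lab is not None else None
    return new_img, new_mask


def apply_spatial_to_tensor(t: AugmentTransform, x: Tensor) -> Tensor:
    """Apply a *spatial* transform to an autodiff tensor (B, C, H, W).

    Used to transport prediction maps through T inside the consistency loss,
    keeping gradients intact.  Intensity kinds act on inputs only and are
    identity here.
    """
    if t.kind == "rotation90":
        return x.rot90(int(t.params.get("k", 1)), axes=(-2, -1))
    if t.kind == "horizontal-flip":
        return x.flip(-1)
    return x


def random_spatial_transform(rng: np.random.Generator) -> AugmentTransform:
    """Draw a random label-preserving spatial perturbation."""
    choice = int(rng.integers(0, 4))
    if choice == 3:
        return AugmentTransform("horizontal-flip")
    return AugmentTransform("rotation90", {"k": choice + 1})


# ---------------------------------------------------------------------------
# Prediction output
# ---------------------------------------------------------------------------

def write_prediction(probs: np.ndarray, path: Path, fmt: str = "png",
                     affine: np.ndarray | None = None) -> None:
    """Write the argmax label map of a (K, H, W) probability array.

    PNG stores literal label values; NIfTI preserves the given affine
    (identity if absent).  Reading the file back yields the identical map.
    """
    labels = np.argmax(probs, axis=0).astype(np.uint8)
    path = Path(path)
    if fmt == "png":
        write_mask(path, labels)
    elif fmt == "nifti":
        aff = np.eye(4) if affine is None else affine
        nib.save(nib.Nifti1Image(labels.astype(np.int16), aff), str(path))
    else:
        raise ValueError(f"unsupported prediction format: {fmt!r}")
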