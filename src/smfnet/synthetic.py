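"""Synthetic multimodal phantoms: a low-contrast elliptical "organ" holding a
smaller "lesion" blob, plus a templated text string describing lesion count
and location.

The phantom emulates the structure of contrast-poor abdominal CT slices where
a small tumour sits inside a larger organ, with a one-line report per image.
The text has a causal, checkable relation to the mask: the location word is
derived from the lesion centroid's ninth of the organ bounding box
(upper/middle/lower x left/center/right), so a model that reads the text has
a genuine signal about where the lesion is.  That makes text ablations
measurable and gives the multimodal fusion path something to exploit.

Default geometry: 64x64 grid, organ semi-axes ~(20, 12) px, lesion radius
3-6 px, lesion/organ contrast 0.15, pixel noise sd 0.05.  A proportionally
scaled 32x32 variant (`tiny_spec`) backs the CPU-scale training checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data_io import Sample, write_image, write_mask, write_text_table

BACKGROUND_LEVEL = 0.40
ORGAN_LEVEL = 0.50          # fixed low organ/background contrast of 0.10

VERTICAL_WORDS = ("upper", "middle", "lower")
HORIZONTAL_WORDS = ("left", "center", "right")

COUNT_WORDS = {0: "no", 1: "one", 2: "two", 3: "three", 4: "four", 5: "five"}


@dataclass
class Lesion:
    center: tuple[float, float]      # (row, col)
    radius: float
    intensity_offset: float = 1.0    # scaled by PhantomSpec.contrast


@dataclass
class PhantomSpec:
    """Parameters of one phantom sample."""

    grid: tuple[int, int] = (64, 64)
    organ_center: tuple[float, float] = (32.0, 32.0)
    organ_axes: tuple[float, float] = (20.0, 12.0)   # (semi-major, semi-minor)
    organ_angle: float = 0.0                         # radians
    lesions: list[Lesion] = field(default_factory=list)
    noise_sd: float = 0.05
    contrast: float = 0.15
    seed: int = 0

    def validate(self, depth: int = 4) -> None:
        h, w = self.grid
        if h % (1 << depth) or w % (1 << depth):
            raise ValueError(f"grid {self.grid} not divisible by 2^{depth}")
        if not 0.0 < self.contrast <= 1.0:
            raise ValueError("contrast must be in (0, 1]")
        for les in self.lesions:
            if les.radius <= 0:
                raise ValueError("lesion radius must be positive")

    def to_jsonable(self) -> dict:
        return asdict(self)


def tiny_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """32x32 phantom with geometry scaled from the 64x64 default."""
    spec = PhantomSpec(grid=(32, 32), organ_center=(16.0, 16.0),
                       organ_axes=(10.0, 6.0), seed=seed)
    for k, v in overrides.items():
        setattr(spec, k, v)
    return spec


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _ellipse_mask(grid, center, axes, angle) -> np.ndarray:
    h, w = grid
    rr, cc = np.mgrid[0:h, 0:w]
    dy = rr - center[0]
    dx = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dy * ca + dx * sa
    v = -dy * sa + dx * ca
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _disk_mask(grid, center, radius) -> np.ndarray:
    h, w = grid
    rr, cc = np.mgrid[0:h, 0:w]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def rasterize_mask(spec: PhantomSpec) -> np.ndarray:
    """Label map: 1 on organ-minus-lesion pixels, 2 on lesion pixels."""
    organ = _ellipse_mask(spec.grid, spec.organ_center, spec.organ_axes,
                          spec.organ_angle)
    labels = organ.astype(np.int64)
    for les in spec.lesions:
        disk = _disk_mask(spec.grid, les.center, les.radius)
        if not disk.any() or (disk & ~organ).any():
            raise ValueError(f"lesion at {les.center} not inside the organ")
        labels[disk] = 2
    return labels


# ---------------------------------------------------------------------------
# Text template
# ---------------------------------------------------------------------------

def location_words(labels: np.ndarray) -> tuple[str, str] | None:
    """Recompute the lesion's ninth of the organ bounding box from a mask.

    Returns (vertical, horizontal) words, or None if no lesion pixels exist.
    """
    lesion = labels == 2
    if not lesion.any():
        return None
    organ = labels >= 1
    rows = np.flatnonzero(organ.any(axis=1))
    cols = np.flatnonzero(organ.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    cy, cx = np.argwhere(lesion).mean(axis=0)
    vi = min(int((cy - r0) / (r1 - r0) * 3), 2)
    hi = min(int((cx - c0) / (c1 - c0) * 3), 2)
    return VERTICAL_WORDS[vi], HORIZONTAL_WORDS[hi]


def render_text_from_spec(spec: PhantomSpec, labels: np.ndarray) -> str:
    """Template: '{count} lesion(s) in the {vertical} {horizontal} of the organ'."""
    n = len(spec.lesions)
    if n == 0:
        return "no lesion in the organ"
    loc = location_words(labels)
    count = COUNT_WORDS.get(n, str(n))
    noun = "lesion" if n == 1 else "lesions"
    return f"{count} {noun} in the {loc[0]} {loc[1]} of the organ"


# ---------------------------------------------------------------------------
# Sample and corpus generation
# ---------------------------------------------------------------------------

def generate_sample(spec: PhantomSpec) -> Sample:
    """Deterministically render (image, mask, text) for one phantom spec."""
    spec.validate()
    labels = rasterize_mask(spec)
    image = np.full(spec.grid, BACKGROUND_LEVEL, dtype=np.float64)
    image[labels >= 1] = ORGAN_LEVEL
    for les in spec.lesions:
        disk = _disk_mask(spec.grid, les.center, les.radius)
        image[disk] = ORGAN_LEVEL + spec.contrast * les.intensity_offset
    rng = np.random.default_rng(spec.seed)
    image = np.clip(image + rng.normal(0.0, spec.noise_sd, spec.grid), 0.0, 1.0)
    text = render_text_from_spec(spec, labels)
    return Sample(id=f"phantom_{spec.seed:06d}", image=image.astype(np.float32),
                  text=text, mask=labels)


def random_spec(base: PhantomSpec, rng: np.random.Generator,
                n_lesions: int = 1) -> PhantomSpec:
    """Jitter organ pose and place lesions uniformly inside the organ."""
    h, w = base.grid
    scale = h / 64.0
    center = (base.organ_center[0] + rng.uniform(-2, 2) * scale,
              base.organ_center[1] + rng.uniform(-2, 2) * scale)
    axes = (base.organ_axes[0] * rng.uniform(0.9, 1.1),
            base.organ_axes[1] * rng.uniform(0.9, 1.1))
    angle = rng.uniform(-0.3, 0.3)
    lesions: list[Lesion] = []
    for _ in range(n_lesions):
        radius = rng.uniform(3.0, 6.0) * scale
        # rejection-sample a lesion disk fully inside the organ
        for _attempt in range(200):
            t = rng.uniform(0, 2 * np.pi)
            r = np.sqrt(rng.uniform(0, 1))
            u = r * max(axes[0] - radius - 1, 1.0) * np.cos(t)
            v = r * max(axes[1] - radius - 1, 1.0) * np.sin(t)
            ca, sa = np.cos(angle), np.sin(angle)
            cand = (center[0] + u * ca - v * sa, center[1] + u * sa + v * ca)
            organ = _ellipse_mask(base.grid, center, axes, angle)
            disk = _disk_mask(base.grid, cand, radius)
            if disk.any() and not (disk & ~organ).any():
                lesions.append(Lesion(center=cand, radius=radius))
                break
        else:
            raise RuntimeError("could not place lesion inside organ")
    return PhantomSpec(grid=base.grid, organ_center=center, organ_axes=axes,
                       organ_angle=angle, lesions=lesions,
                       noise_sd=base.noise_sd, contrast=base.contrast,
                       seed=int(rng.integers(0, 2 ** 31 - 1)))


def generate_samples(n: int, base_spec: PhantomSpec, seed: int,
                     n_lesions: int = 1) -> list[Sample]:
    """Draw n random phantoms; fully deterministic in (base_spec, seed)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        spec = random_spec(base_spec, rng, n_lesions=n_lesions)
        s = generate_sample(spec)
        out.append(Sample(id=f"phantom_{seed}_{i:04d}", image=s.image,
                          text=s.text, mask=s.mask))
    return out


def generate_corpus(n_labeled: int, n_unlabeled: int, base_spec: PhantomSpec,
                    seed: int, out_dir: Path, n_lesions: int = 1) -> dict:
    """Write a phantom corpus in the on-disk layout `load_dataset` reads.

    Layout: images/{id}.png, masks/{id}.png (labeled only), text.csv,
    manifest.json.  Per-sample randomness derives from the corpus seed, so
    identical calls produce byte-identical corpora.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    table: dict[str, str] = {}
    manifest: dict = {"seed": seed, "n_labeled": n_labeled,
                      "n_unlabeled": n_unlabeled, "samples": []}
    for i in range(n_labeled + n_unlabeled):
        labeled = i < n_labeled
        spec = random_spec(base_spec, rng, n_lesions=n_lesions)
        s = generate_sample(spec)
        sid = f"{'lab' if labeled else 'unl'}_{i:04d}"
        write_image(out_dir / "images" / f"{sid}.png", s.image)
        if labeled:
            write_mask(out_dir / "masks" / f"{sid}.png", s.mask)
        table[sid] = s.text
        manifest["samples"].append({"id": sid, "labeled": labeled,
                                    "spec": spec.to_jsonable()})
    write_text_table(out_dir / "text.csv", table)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
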