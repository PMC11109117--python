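"""Deterministic generator of synthetic foot-ulcer scenes with exact ground truth.

Scenes are foot-shaped skin regions on a dark backdrop, with lesion blobs of
the six subcategories painted inside. Each subcategory carries a distinct mean
colour so that small models can learn the classes from colour statistics alone:

======  ============  ------------------
code    subcategory   mean RGB (uint8)
======  ============  ------------------
1       Ulcer1        (214, 118, 118)  pink-red
2       Ulcer2        (152,  32,  46)  deep red
3       Infection1    (202, 192,  92)  yellow
4       Infection2    (128, 142,  40)  olive-green
5       Gangrene1     (112,  72,  40)  brown
6       Gangrene2     ( 36,  28,  28)  near-black
(0)     skin          (226, 184, 150)
(0)     backdrop      ( 70,  80,  95)
======  ============  ------------------

The minimum pairwise Euclidean distance between the six lesion means (and
between each lesion mean and the skin/backdrop colours) is ~57 RGB units,
far above the additive pixel-noise scale (sigma = 6). Level-2 subcategories
are darker than their level-1 counterparts and are drawn with a larger radius
prior, encoding depth and extent in both appearance and size.

All randomness flows from a single ``numpy`` generator keyed by the scene
seed; identical specs reproduce bit-identical images and label maps.
Overlapping blobs are resolved by list order: the later blob overwrites the
earlier one, both in the image and in the label map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from scoredfu.errors import ValidationError
from scoredfu.types import (
    LesionAreas,
    Severity,
    Subcategory,
    SEVERITY_ORDER,
    validate_labelmap,
)
from scoredfu.segmentation import areas_from_labelmap

PALETTES: dict[Subcategory, tuple[int, int, int]] = {
    Subcategory.ULCER1: (214, 118, 118),
    Subcategory.ULCER2: (152, 32, 46),
    Subcategory.INFECTION1: (202, 192, 92),
    Subcategory.INFECTION2: (128, 142, 40),
    Subcategory.GANGRENE1: (112, 72, 40),
    Subcategory.GANGRENE2: (36, 28, 28),
}
SKIN_RGB = (226, 184, 150)
BACKDROP_RGB = (70, 80, 95)
PIXEL_NOISE_SIGMA = 6.0
MIN_IMAGE_DIM = 64


@dataclass(frozen=True)
class BlobSpec:
    """One lesion blob: subcategory, centre (row, col), radius, irregularity.

    ``irregularity`` in [0, 1] modulates the blob boundary with smooth angular
    harmonics; 0 gives an exact rasterized disc. The blob's maximal radial
    extent is ``radius * (1 + irregularity)``.
    """

    subcategory: Subcategory
    center: tuple[int, int]
    radius: float
    irregularity: float = 0.0

    def __post_init__(self):
        if self.radius < 2:
            raise ValidationError(f"blob radius must be >= 2, got {self.radius}")
        if not 0.0 <= self.irregularity <= 1.0:
            raise ValidationError(
                f"irregularity must be in [0, 1], got {self.irregularity}"
            )
        object.__setattr__(self, "subcategory", Subcategory(self.subcategory))

    @property
    def max_extent(self) -> float:
        return self.radius * (1.0 + self.irregularity)


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic scene (dims, blobs, background, seed)."""

    image_height: int
    image_width: int
    blobs: tuple[BlobSpec, ...] = ()
    background_style: str = "skin"
    seed: int = 0

    def __post_init__(self):
        if self.image_height < MIN_IMAGE_DIM or self.image_width < MIN_IMAGE_DIM:
            raise ValidationError(
                f"image dims must be >= {MIN_IMAGE_DIM}, got "
                f"{self.image_height}x{self.image_width}"
            )
        if self.background_style not in ("skin", "skin_textured"):
            raise ValidationError(
                f"unknown background_style {self.background_style!r}"
            )
        object.__setattr__(self, "blobs", tuple(self.blobs))
        for b in self.blobs:
            r, c = b.center
            m = b.max_extent
            if r - m < 0 or c - m < 0 or r + m >= self.image_height or c + m >= self.image_width:
                raise ValidationError(
                    f"blob at {b.center} with extent {m:.1f} exceeds "
                    f"{self.image_height}x{self.image_width} image bounds"
                )


@dataclass(frozen=True)
class GroundTruth:
    """Pixel-exact ground truth for a generated scene."""

    label_map: np.ndarray
    severity_label: Severity
    areas: LesionAreas


def _blob_mask(h: int, w: int, blob: BlobSpec, rng: np.random.Generator) -> np.ndarray:
    """Rasterize one blob; irregular boundary via 3 random angular harmonics."""
    cy, cx = blob.center
    rr, cc = np.ogrid[:h, :w]
    dy = rr - cy
    dx = cc - cx
    dist = np.hypot(dy, dx)
    if blob.irregularity == 0.0:
        return dist <= blob.radius
    # smooth radial perturbation, normalized so |f| <= 1
    n_harm = 3
    amps = rng.uniform(0.3, 1.0, n_harm)
    phases = rng.uniform(0, 2 * np.pi, n_harm)
    ks = rng.integers(2, 6, n_harm)
    theta = np.arctan2(dy, dx)
    f = np.zeros((h, w))
    for a, p, k in zip(amps, phases, ks):
        f += a * np.sin(k * theta + p)
    f /= np.sum(amps)
    r_theta = blob.radius * (1.0 + blob.irregularity * f)
    return dist <= r_theta


def foot_mask(h: int, w: int) -> np.ndarray:
    """Elliptical foot-like region used as the skin area of every scene."""
    rr, cc = np.ogrid[:h, :w]
    cy, cx = h / 2.0, w / 2.0
    return ((rr - cy) / (0.46 * h)) ** 2 + ((cc - cx) / (0.40 * w)) ** 2 <= 1.0


def severity_from_areas(areas: LesionAreas) -> Severity:
    """Most severe family with nonzero realized area; normal if none.

    Using realized areas (after overlap resolution) rather than the raw blob
    list keeps the invariant that a scene is labelled normal exactly when all
    six areas are zero, even if a blob is fully occluded by a later one.
    """
    if areas.gangrene > 0:
        return Severity.GANGRENE
    if areas.ulcer > 0:
        return Severity.ULCER
    if areas.infection > 0:
        return Severity.INFECTION
    return Severity.NORMAL


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene to an RGB uint8 image plus exact ground truth.

    Deterministic: the same spec (including seed) reproduces bit-identical
    output. Later blobs overwrite earlier ones where they overlap.
    """
    h, w = spec.image_height, spec.image_width
    rng = np.random.default_rng(spec.seed)

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = BACKDROP_RGB
    fm = foot_mask(h, w)
    img[fm] = SKIN_RGB

    if spec.background_style == "skin_textured":
        # low-frequency multiplicative shading over the skin region
        yy, xx = np.mgrid[:h, :w]
        phase = rng.uniform(0, 2 * np.pi, 2)
        tex = 1.0 + 0.06 * np.sin(2 * np.pi * yy / h * 3 + phase[0]) \
                  + 0.06 * np.sin(2 * np.pi * xx / w * 3 + phase[1])
        img[fm] *= tex[fm][:, None]

    labels = np.zeros((h, w), dtype=np.uint8)
    for blob in spec.blobs:
        mask = _blob_mask(h, w, blob, rng)
        shade = rng.uniform(0.92, 1.08)  # per-blob brightness jitter
        img[mask] = np.asarray(PALETTES[blob.subcategory], dtype=np.float64) * shade
        labels[mask] = int(blob.subcategory)

    img += rng.normal(0.0, PIXEL_NOISE_SIGMA, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    areas = areas_from_labelmap(labels)
    truth = GroundTruth(
        label_map=validate_labelmap(labels),
        severity_label=severity_from_areas(areas),
        areas=areas,
    )
    return img, truth


# ---------------------------------------------------------------------------
# dataset generation

# radius priors as fractions of min(image dims): level 2 larger than level 1
_RADIUS_FRAC = {1: (0.08, 0.14), 2: (0.12, 0.20)}

_FAMILY_SUBCATS = {
    Severity.INFECTION: (Subcategory.INFECTION1, Subcategory.INFECTION2),
    Severity.ULCER: (Subcategory.ULCER1, Subcategory.ULCER2),
    Severity.GANGRENE: (Subcategory.GANGRENE1, Subcategory.GANGRENE2),
}


def proportional_counts(n: int, proportions) -> list[int]:
    """Largest-remainder apportionment of n items over proportions."""
    p = np.asarray(proportions, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"proportions sum to {p.sum()}, expected 1")
    if (p < 0).any():
        raise ValidationError("proportions must be non-negative")
    exact = n * p
    counts = np.floor(exact).astype(int)
    rem = exact - counts
    short = n - counts.sum()
    if short > 0:
        for idx in np.argsort(-rem, kind="stable")[:short]:
            counts[idx] += 1
    return counts.tolist()


def _random_blob(
    rng: np.random.Generator,
    subcat: Subcategory,
    h: int,
    w: int,
) -> BlobSpec:
    s = min(h, w)
    lo, hi = _RADIUS_FRAC[subcat.level]
    radius = rng.uniform(lo * s, hi * s)
    irregularity = rng.uniform(0.15, 0.35)
    extent = radius * (1.0 + irregularity)
    # keep the blob inside the foot ellipse (and therefore inside bounds)
    margin_y = 0.46 * h - extent
    margin_x = 0.40 * w - extent
    cy = int(np.rint(h / 2 + rng.uniform(-0.6, 0.6) * margin_y))
    cx = int(np.rint(w / 2 + rng.uniform(-0.6, 0.6) * margin_x))
    return BlobSpec(subcategory=subcat, center=(cy, cx), radius=radius,
                    irregularity=irregularity)


def _scene_spec_for_label(
    label: Severity, h: int, w: int, seed: int, rng: np.random.Generator
) -> SceneSpec:
    """Draw a random scene layout whose realized severity equals ``label``.

    Lower-ranked lesion families may co-occur (an ulcer scene can carry an
    infection blob); the dominant family's blob is appended last so overlap
    cannot occlude it.
    """
    blobs: list[BlobSpec] = []
    if label != Severity.NORMAL:
        for fam in (Severity.INFECTION, Severity.ULCER, Severity.GANGRENE):
            if fam.rank > label.rank:
                continue
            if fam == label:
                n_blobs = int(rng.integers(1, 3))
            elif rng.uniform() < 0.3:  # optional lower-severity companion
                n_blobs = 1
            else:
                continue
            for _ in range(n_blobs):
                subcat = _FAMILY_SUBCATS[fam][int(rng.integers(0, 2))]
                blobs.append(_random_blob(rng, subcat, h, w))
    style = "skin_textured" if rng.uniform() < 0.5 else "skin"
    return SceneSpec(image_height=h, image_width=w, blobs=tuple(blobs),
                     background_style=style, seed=seed)


def generate_dataset(
    n: int,
    class_mix=(0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    image_size: int = 64,
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Generate ``n`` scenes with per-severity counts ``round(n * class_mix)``.

    ``class_mix`` orders the four severities (normal, infection, ulcer,
    gangrene). Counts follow largest-remainder rounding so they always sum
    to ``n``. Scenes are shuffled; everything is reproducible under ``seed``.

    Occasionally a drawn layout's realized severity differs from its target
    (a companion blob fully occluded); such layouts are redrawn so the
    returned labels match the requested mix exactly.
    """
    if n <= 0:
        raise ValidationError(f"n must be > 0, got {n}")
    counts = proportional_counts(n, class_mix)
    rng = np.random.default_rng(seed)
    out: list[tuple[np.ndarray, GroundTruth]] = []
    for label, count in zip(SEVERITY_ORDER, counts):
        for _ in range(count):
            for _attempt in range(20):
                scene_seed = int(rng.integers(0, 2**31 - 1))
                spec = _scene_spec_for_label(label, image_size, image_size,
                                             scene_seed, rng)
                img, truth = generate_scene(spec)
                if truth.severity_label == label:
                    break
            else:  # pragma: no cover - vanishingly unlikely
                raise RuntimeError(f"could not realize severity {label}")
            out.append((img, truth))
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def palette_separation() -> float:
    """Minimum pairwise Euclidean RGB distance among the six lesion means."""
    cols = np.array([PALETTES[s] for s in Subcategory], dtype=float)
    d = np.linalg.norm(cols[:, None, :] - cols[None, :, :], axis=-1)
    return float(d[np.triu_indices(len(cols), k=1)].min())
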