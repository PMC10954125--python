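"""Seeded generator of dermoscopy-like labeled lesion images.

Real dermoscopy archives (e.g. the eight-diagnosis ISIC 2019 collection)
cannot be redistributed with a package, so every downstream stage is
exercised on synthetic images that reproduce the features the pipeline
actually consumes: a darker, radially perturbed elliptical lesion on a
textured skin background, multiplicative speckle noise with unit-mean
noise factor, optional thin dark hair strokes, and a class-imbalance
profile chosen by the caller.  Class identity is encoded by
systematically different lesion intensity and texture parameters so that
classes are learnable by construction.

All randomness flows through one explicit integer seed per call; the
same seed yields bit-identical images and masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .exceptions import DomainError

#: The eight diagnosis labels of the ISIC 2019 vocabulary, in the fixed order
#: used for class indices throughout the package.
CLASS_NAMES: tuple[str, ...] = ("AK", "BCC", "BK", "DF", "MEL", "MN", "SCC", "VASC")

#: Published per-class image counts of the imbalanced archive the generator
#: can mimic (before any rebalancing).
ISIC2019_CLASS_COUNTS: dict[str, int] = {
    "AK": 440,
    "BCC": 600,
    "BK": 800,
    "DF": 230,
    "MEL": 818,
    "MN": 1510,
    "SCC": 245,
    "VASC": 200,
}


@dataclass(frozen=True)
class LesionSpec:
    """Full parameterization of one synthetic lesion image.

    Parameters
    ----------
    class_id : str
        Label of the image (any string; the canonical vocabulary is
        :data:`CLASS_NAMES`).
    image_size : (int, int)
        Output height and width in pixels.
    ellipse_center : (float, float)
        Lesion center, (row, col) in pixels.
    axes : (float, float)
        Ellipse semi-axes in pixels (before radial perturbation).
    rotation : float
        Ellipse rotation in radians.
    lesion_intensity_mean, background_mean : float
        Mean grey levels (0-255 scale); lesions must be darker than skin.
    border_irregularity : float
        Amplitude of the radial boundary perturbation, as a fraction of
        the local ellipse radius (0 = exact ellipse).
    texture_amplitude : float
        Peak amplitude (grey levels) of the smooth background texture.
    hair_count : int
        Number of dark hair-like strokes drawn over the image.
    speckle_var : float
        Variance of the unit-mean multiplicative noise factor.
    seed : int
        Seed for every random element of this image.
    """

    class_id: str
    image_size: tuple[int, int] = (128, 128)
    ellipse_center: tuple[float, float] = (64.0, 64.0)
    axes: tuple[float, float] = (30.0, 22.0)
    rotation: float = 0.0
    lesion_intensity_mean: float = 90.0
    background_mean: float = 200.0
    border_irregularity: float = 0.15
    texture_amplitude: float = 8.0
    hair_count: int = 0
    speckle_var: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.lesion_intensity_mean >= self.background_mean:
            raise DomainError("lesion must be darker than the background")
        if self.speckle_var < 0:
            raise DomainError("speckle variance must be non-negative")
        if self.border_irregularity < 0:
            raise DomainError("border irregularity must be non-negative")
        h, w = self.image_size
        cy, cx = self.ellipse_center
        reach = max(self.axes) * (1.0 + self.border_irregularity)
        if not (reach <= cy <= h - 1 - reach and reach <= cx <= w - 1 - reach):
            raise DomainError("perturbed ellipse does not fit inside the frame")


@dataclass
class SyntheticDataset:
    """A generated image collection with labels, masks and per-image specs."""

    images: list[np.ndarray]
    labels: list[str]
    manifest: list[LesionSpec]
    masks: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.images)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lab in self.labels:
            counts[lab] = counts.get(lab, 0) + 1
        return counts


def add_speckle(image: np.ndarray, variance: float, seed: int) -> np.ndarray:
    """Apply unit-mean multiplicative speckle noise to a grey image.

    The degraded image is ``A0 = A * n`` with the noise factor ``n`` drawn
    i.i.d. per pixel from a Gamma distribution with mean 1 and the stated
    variance (shape ``1/variance``), which keeps the factor positive.
    The output is clipped to the 0-255 intensity scale.
    """
    if variance < 0:
        raise DomainError("speckle variance must be non-negative")
    image = np.asarray(image, dtype=np.float64)
    if variance == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    shape = 1.0 / variance
    factor = rng.gamma(shape, scale=variance, size=image.shape)
    return np.clip(image * factor, 0.0, 255.0)


def _boundary_perturbation(rng: np.random.Generator, n_harmonics: int = 3):
    """A smooth periodic radial perturbation profile with peak |value| = 1.

    Sum of low-order sinusoids (harmonics 2..n+1) with random phases and
    decaying amplitudes; harmonic 1 is excluded so the perturbation does
    not simply translate the lesion.
    """
    orders = np.arange(2, 2 + n_harmonics)
    amps = rng.uniform(0.3, 1.0, size=n_harmonics) / orders
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_harmonics)

    def profile(phi: np.ndarray) -> np.ndarray:
        out = np.zeros_like(phi, dtype=np.float64)
        for m, a, p in zip(orders, amps, phases):
            out += a * np.sin(m * phi + p)
        return out / peak

    # peak over a dense grid so max |profile| == 1
    grid = np.linspace(0.0, 2.0 * np.pi, 2048, endpoint=False)
    raw = np.zeros_like(grid)
    for m, a, p in zip(orders, amps, phases):
        raw += a * np.sin(m * grid + p)
    peak = max(np.max(np.abs(raw)), 1e-12)
    return profile


def lesion_membership(
    yy: np.ndarray,
    xx: np.ndarray,
    spec: LesionSpec,
    profile,
) -> np.ndarray:
    """Boolean lesion membership for pixel coordinates.

    A pixel belongs to the lesion when its normalized elliptical radius
    ``rho = sqrt((u/a)^2 + (v/b)^2)`` (u, v = coordinates in the rotated
    ellipse frame) satisfies ``rho <= 1 + irregularity * P(phi)`` with
    ``phi`` the polar angle in that frame and ``P`` the unit-amplitude
    perturbation profile.
    """
    cy, cx = spec.ellipse_center
    a, b = spec.axes
    c, s = np.cos(spec.rotation), np.sin(spec.rotation)
    dy = yy - cy
    dx = xx - cx
    u = c * dx + s * dy
    v = -s * dx + c * dy
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    phi = np.arctan2(v, u)
    limit = 1.0 + spec.border_irregularity * profile(phi)
    return rho <= limit


def _draw_hairs(img: np.ndarray, rng: np.random.Generator, count: int) -> None:
    """Overlay thin dark quadratic Bezier strokes in place."""
    h, w = img.shape
    for _ in range(count):
        pts = rng.uniform([0, 0], [h - 1, w - 1], size=(3, 2))
        t = np.linspace(0.0, 1.0, 4 * (h + w))[:, None]
        curve = ((1 - t) ** 2) * pts[0] + 2 * (1 - t) * t * pts[1] + (t**2) * pts[2]
        rr = np.clip(np.round(curve[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.round(curve[:, 1]).astype(int), 0, w - 1)
        shade = rng.uniform(20.0, 45.0)
        img[rr, cc] = np.minimum(img[rr, cc], shade)


def generate_lesion_image(spec: LesionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one synthetic dermoscopy image and its exact lesion mask.

    Returns
    -------
    image : ndarray, shape (H, W, 3)
        RGB image, float values on the 0-255 scale.
    mask : ndarray of bool, shape (H, W)
        The exact boolean lesion membership used during rendering
        (before hair strokes and speckle are overlaid).
    """
    spec.validate()
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)

    profile = _boundary_perturbation(rng)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    mask = lesion_membership(yy, xx, spec, profile)

    # smooth low-frequency textures for background and lesion interior
    def texture(amplitude: float, sigma: float) -> np.ndarray:
        fld = gaussian_filter(rng.standard_normal((h, w)), sigma=sigma)
        peak = max(np.max(np.abs(fld)), 1e-12)
        return fld * (amplitude / peak)

    gray = spec.background_mean + texture(spec.texture_amplitude, sigma=8.0)
    lesion = spec.lesion_intensity_mean + texture(0.6 * spec.texture_amplitude, sigma=4.0)
    gray[mask] = lesion[mask]

    if spec.hair_count:
        _draw_hairs(gray, rng, spec.hair_count)

    gray = add_speckle(gray, spec.speckle_var, seed=int(rng.integers(0, 2**31)))

    # mild warm tint so the RGB image is not strictly channel-equal
    rgb = np.stack([gray, gray * 0.96, gray * 0.92], axis=-1)
    return np.clip(rgb, 0.0, 255.0), mask


def _class_style(index: int, n_classes: int) -> dict:
    """Systematic per-class rendering parameters.

    Lesion mean intensity is spread evenly over 40-170 grey levels so
    every class stays clearly darker than the 220-level background (a
    visible lesion under unit-mean speckle) while classes remain
    separated; irregularity and texture cycle so shape cues differ too.
    """
    frac = index / max(1, n_classes - 1) if n_classes > 1 else 0.5
    return {
        "lesion_intensity_mean": 40.0 + 130.0 * frac,
        "background_mean": 220.0,
        "border_irregularity": 0.08 + 0.06 * (index % 4),
        "texture_amplitude": 6.0 + 1.5 * (index % 3),
    }


def generate_dataset(
    class_counts: Mapping[str, int],
    image_size: int | tuple[int, int] = 128,
    seed: int = 0,
    speckle_var: float = 0.05,
    hair_fraction: float = 0.15,
) -> SyntheticDataset:
    """Generate a labeled dataset with exactly the requested class counts.

    Parameters
    ----------
    class_counts : mapping label -> int
        Requested images per class (e.g. the archive's imbalance profile
        :data:`ISIC2019_CLASS_COUNTS`); order of iteration fixes class
        style assignment.
    image_size : int or (int, int)
        Pixel size of the generated images.
    seed : int
        Master seed; per-image seeds are derived from it.
    speckle_var : float
        Multiplicative noise variance applied to every image.
    hair_fraction : float
        Fraction of images receiving 1-3 hair strokes.
    """
    if not class_counts:
        raise DomainError("class_counts must name at least one class")
    if any(c < 0 for c in class_counts.values()):
        raise DomainError("class counts must be non-negative")
    total = sum(class_counts.values())
    if total == 0:
        raise DomainError("requested dataset is empty")

    if isinstance(image_size, int):
        image_size = (image_size, image_size)
    h, w = image_size

    ss = np.random.SeedSequence(seed)
    child_seeds = (ss.generate_state(2 * total, dtype=np.uint64) % (2**31)).astype(np.int64)

    images: list[np.ndarray] = []
    labels: list[str] = []
    manifest: list[LesionSpec] = []
    gt_masks: list[np.ndarray] = []

    classes = list(class_counts)
    i = 0
    for ci, name in enumerate(classes):
        style = _class_style(ci, len(classes))
        for _ in range(class_counts[name]):
            s = int(child_seeds[i])
            i += 1
            rng = np.random.default_rng(int(child_seeds[total + i - 1]))
            irregularity = style["border_irregularity"]
            max_reach_frac = 0.38 / (1.0 + irregularity)
            a = rng.uniform(0.22, max_reach_frac) * min(h, w)
            b = a * rng.uniform(0.6, 1.0)
            reach = a * (1.0 + irregularity)
            cy = rng.uniform(reach, h - 1 - reach)
            cx = rng.uniform(reach, w - 1 - reach)
            spec = LesionSpec(
                class_id=name,
                image_size=(h, w),
                ellipse_center=(cy, cx),
                axes=(a, b),
                rotation=rng.uniform(0.0, np.pi),
                lesion_intensity_mean=style["lesion_intensity_mean"] + rng.uniform(-8, 8),
                background_mean=style["background_mean"],
                border_irregularity=irregularity,
                texture_amplitude=style["texture_amplitude"],
                hair_count=int(rng.integers(1, 4)) if rng.random() < hair_fraction else 0,
                speckle_var=speckle_var,
                seed=s,
            )
            img, mask = generate_lesion_image(spec)
            images.append(img)
            labels.append(name)
            manifest.append(spec)
            gt_masks.append(mask)

    return SyntheticDataset(images=images, labels=labels, manifest=manifest, masks=gt_masks)


def save_dataset(dataset: SyntheticDataset, outdir: str | Path) -> Path:
    """Write images as PNG plus a ``manifest.csv`` (image_path,label,split).

    The split column is left empty at generation time.  Returns the
    manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, lab) in enumerate(zip(dataset.images, dataset.labels)):
        rel = f"img_{i:05d}_{lab}.png"
        Image.fromarray(np.round(img).astype(np.uint8)).save(outdir / rel)
        rows.append((rel, lab, ""))
    manifest_path = outdir / "manifest.csv"
    with open(manifest_path, "w") as fh:
        fh.write("image_path,label,split\n")
        for rel, lab, split in rows:
            fh.write(f"{rel},{lab},{split}\n")
    return manifest_path
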