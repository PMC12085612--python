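"""Synthetic cranial CT phantoms with labeled hemorrhage lesions.

Generates 2-D grayscale slices that mimic the gross geometry of an axial
head CT: a bright elliptical skull ring, textured brain parenchyma inside
it, dark background outside, and (optionally) exactly one hyperdense
lesion whose shape and location follow the anatomical prior of one of the
five intracranial-hemorrhage subtypes:

* IVH  -- intraventricular: blob near the center of the brain,
* IPH  -- intraparenchymal: blob in the mid-parenchyma,
* SAH  -- subarachnoid: thin curvilinear streak along the inner skull margin,
* SDH  -- subdural: crescent hugging the inner skull table,
* EDH  -- epidural: biconvex lens at the inner skull table.

Lesions are drawn brighter than parenchyma but dimmer than bone, the way
acute blood appears in a brain-window CT.  The phantoms are deliberately
simple (no Hounsfield physics, one lesion per slice) -- their job is to
make every downstream stage of the pipeline testable end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .dataset import CTSlice, DatasetManifest, SegMask, save_mask, save_slice

#: Fixed class-index <-> subtype-name bijection used across the package.
CLASS_NAMES: tuple[str, ...] = ("EDH", "IPH", "IVH", "SAH", "SDH")
CLASS_INDEX: dict[str, int] = {n: i for i, n in enumerate(CLASS_NAMES)}

#: Sentinel for a lesion-free slice.
NO_LESION = "NONE"

# Grayscale layout of the phantom (8-bit units).
_BACKGROUND_LEVEL = 8.0
_PARENCHYMA_LEVEL = 105.0
_PARENCHYMA_TEXTURE_SD = 12.0
_SKULL_LEVEL = 235.0
_LESION_LEVEL = 185.0  # hyperdense blood: above parenchyma, below bone

#: Synthetic patients group this many consecutive slices of one class.
DEFAULT_SLICES_PER_PATIENT = 30


@dataclass(frozen=True)
class ClassLabel:
    """One hemorrhage subtype, with its fixed index in 0..4."""

    index: int
    name: str

    def __post_init__(self) -> None:
        if self.name not in CLASS_INDEX:
            raise ValueError(f"unknown hemorrhage class {self.name!r}")
        if CLASS_INDEX[self.name] != self.index:
            raise ValueError(
                f"class {self.name!r} has index {CLASS_INDEX[self.name]}, "
                f"not {self.index}"
            )

    @classmethod
    def from_name(cls, name: str) -> "ClassLabel":
        return cls(CLASS_INDEX[name], name)

    @classmethod
    def from_index(cls, index: int) -> "ClassLabel":
        return cls(index, CLASS_NAMES[index])


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice.

    ``lesion_scale`` is the target lesion area as a fraction of the image
    area; the rasterized lesion is kept within a factor of two of it.
    ``image_size`` must be a multiple of 32 so that the five halvings of
    the encoder land on integral sizes.
    """

    image_size: int = 256
    lesion_class: str = NO_LESION
    lesion_scale: float = 0.02
    noise_sd: float = 4.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32 or self.image_size % 32 != 0:
            raise ValueError(
                f"image_size must be >= 32 and a multiple of 32, got {self.image_size}"
            )
        if not (0.0 < self.lesion_scale <= 0.2):
            raise ValueError(
                f"lesion_scale must be in (0, 0.2], got {self.lesion_scale}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.lesion_class != NO_LESION and self.lesion_class not in CLASS_INDEX:
            raise ValueError(f"unknown lesion class {self.lesion_class!r}")


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], radii: tuple[float, float],
    angle: float = 0.0,
) -> np.ndarray:
    """Boolean mask of a filled, optionally rotated ellipse."""
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(np.float64)
    y = yy - center[0]
    x = xx - center[1]
    c, s = math.cos(angle), math.sin(angle)
    u = c * x + s * y
    v = -s * x + c * y
    return (u / radii[1]) ** 2 + (v / radii[0]) ** 2 <= 1.0


def _head_geometry(size: int) -> dict[str, float]:
    s = float(size)
    return {
        "cy": s / 2.0,
        "cx": s / 2.0,
        "outer_ry": 0.46 * s,
        "outer_rx": 0.42 * s,
        "thickness": 0.035 * s,
    }


def _brain_interior(size: int, margin: float = 0.0) -> np.ndarray:
    """Mask of the region inside the inner skull table, shrunk by ``margin`` px."""
    g = _head_geometry(size)
    return _ellipse_mask(
        (size, size),
        (g["cy"], g["cx"]),
        (g["outer_ry"] - g["thickness"] - margin, g["outer_rx"] - g["thickness"] - margin),
    )


def _rim_coords(
    size: int,
    center: tuple[float, float],
    radii: tuple[float, float],
    theta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized elliptical radius and angle (relative to ``theta``)."""
    yy, xx = np.mgrid[:size, :size].astype(np.float64)
    u = (xx - center[1]) / radii[1]
    v = (yy - center[0]) / radii[0]
    rho = np.hypot(u, v)
    ang = np.mod(np.arctan2(v, u) - theta + math.pi, 2 * math.pi) - math.pi
    return rho, ang


def _lesion_mask(
    size: int, class_name: str, target_area: float, rng: np.random.Generator
) -> np.ndarray:
    """Rasterize one lesion following the subtype's location/shape prior.

    A multiplicative size correction is applied (up to three passes) so the
    pixel count stays close to ``target_area`` despite clipping against the
    inner skull table.
    """
    g = _head_geometry(size)
    cy, cx = g["cy"], g["cx"]
    inner_ry = g["outer_ry"] - g["thickness"]
    inner_rx = g["outer_rx"] - g["thickness"]
    interior = _brain_interior(size, margin=1.0)
    theta = rng.uniform(0.0, 2.0 * math.pi)  # orientation of the lesion site
    aspect = rng.uniform(1.1, 1.5)
    scale = 1.0
    mask = np.zeros((size, size), dtype=bool)

    for _ in range(3):
        area = target_area * scale
        if class_name == "IVH":
            # ventricular blood: near the brain center
            off = 0.04 * size
            c = (cy + rng.uniform(-off, off), cx + rng.uniform(-off, off))
            r = math.sqrt(area / math.pi)
            mask = _ellipse_mask(
                (size, size), c, (r * aspect, r / aspect), rng.uniform(0, math.pi)
            )
        elif class_name == "IPH":
            # parenchymal blood: blob in the mid-parenchyma, clear of the rim
            r = math.sqrt(area / math.pi)
            r_eff = min(inner_ry, inner_rx)
            max_rho = max(0.2, 1.0 - (r * aspect + 0.05 * size) / r_eff)
            rho = rng.uniform(0.6 * max_rho, max_rho)
            c = (cy + rho * inner_ry * math.sin(theta), cx + rho * inner_rx * math.cos(theta))
            mask = _ellipse_mask(
                (size, size), c, (r * aspect, r / aspect), rng.uniform(0, math.pi)
            )
        elif class_name == "SAH":
            # subarachnoid blood: thin streak tracking the inner skull margin
            t = max(1.5, 0.02 * size) * scale
            r_mid = 0.90  # fraction of the inner table radius
            span = min(1.7 * math.pi, max(0.4 * math.pi, area / (t * r_mid * min(inner_ry, inner_rx))))
            rho, ang = _rim_coords(size, (cy, cx), (inner_ry, inner_rx), theta)
            half_t = t / (2.0 * min(inner_ry, inner_rx))
            mask = (np.abs(rho - r_mid) <= half_t) & (np.abs(ang) <= span / 2.0)
        elif class_name == "SDH":
            # subdural blood: long crescentic band hugging the inner table,
            # much thicker than an SAH streak and far more extended than a lens
            t = max(2.5, 0.06 * size) * scale
            r_eff = min(inner_ry, inner_rx)
            span = min(1.8 * math.pi, max(0.7 * math.pi, area / (t * 0.97 * r_eff)))
            rho, ang = _rim_coords(size, (cy, cx), (inner_ry, inner_rx), theta)
            w = t / r_eff
            taper = 1.0 - (np.abs(ang) / (span / 2.0)) ** 2  # crescent tapers to its tips
            mask = (
                (rho <= 1.0)
                & (rho >= 1.0 - w * np.maximum(taper, 0.0))
                & (np.abs(ang) <= span / 2.0)
            )
        elif class_name == "EDH":
            # epidural blood: lens formed by two intersecting discs at the table
            r_lens = math.sqrt(area / 0.8946)  # lens area for center gap 1.2 R
            d = 1.2 * r_lens
            bcy = cy + (inner_ry - 0.2 * r_lens) * math.sin(theta)
            bcx = cx + (inner_rx - 0.2 * r_lens) * math.cos(theta)
            ny, nx = math.sin(theta), math.cos(theta)
            c1 = (bcy - 0.5 * d * ny, bcx - 0.5 * d * nx)
            c2 = (bcy + 0.5 * d * ny, bcx + 0.5 * d * nx)
            disc1 = _ellipse_mask((size, size), c1, (r_lens, r_lens))
            disc2 = _ellipse_mask((size, size), c2, (r_lens, r_lens))
            mask = disc1 & disc2
        else:  # pragma: no cover - guarded by PhantomSpec validation
            raise ValueError(f"unknown lesion class {class_name!r}")

        mask &= interior
        count = int(mask.sum())
        if count == 0:
            scale *= 2.0
            continue
        ratio = target_area / count
        if 0.7 <= ratio <= 1.4:
            break
        scale *= min(2.0, max(0.5, ratio))
    return mask


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[CTSlice, SegMask, ClassLabel | None]:
    """Generate one labeled cranial phantom.

    Returns the 8-bit slice, its per-pixel label mask (0 background,
    class index + 1 for lesion pixels) and the lesion's class label
    (``None`` for a lesion-free slice).  Deterministic in ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    size = spec.image_size

    g = _head_geometry(size)
    outer = _ellipse_mask((size, size), (g["cy"], g["cx"]), (g["outer_ry"], g["outer_rx"]))
    inner = _brain_interior(size)
    skull = outer & ~inner

    img = np.full((size, size), _BACKGROUND_LEVEL, dtype=np.float64)
    # smooth parenchymal texture: low-pass filtered white noise
    texture = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=size / 48.0)
    sd = texture.std()
    if sd > 0:
        texture *= _PARENCHYMA_TEXTURE_SD / sd
    img[inner] = _PARENCHYMA_LEVEL + texture[inner]
    img[skull] = _SKULL_LEVEL

    labels = np.zeros((size, size), dtype=np.uint8)
    label: ClassLabel | None = None
    if spec.lesion_class != NO_LESION:
        label = ClassLabel.from_name(spec.lesion_class)
        target_area = spec.lesion_scale * size * size
        lesion = _lesion_mask(size, spec.lesion_class, target_area, rng)
        img[lesion] = _LESION_LEVEL + 0.3 * texture[lesion]
        labels[lesion] = label.index + 1

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    ct = CTSlice(pixels=pixels, patient_id="", slice_index=0)
    mask = SegMask(labels=labels)
    return ct, mask, label


def generate_dataset(
    per_class_counts: dict[str, int],
    out_dir: str | Path,
    spec_defaults: PhantomSpec = PhantomSpec(),
    seed: int = 0,
    slices_per_patient: int = DEFAULT_SLICES_PER_PATIENT,
) -> DatasetManifest:
    """Write a labeled phantom dataset to ``out_dir`` and return its manifest.

    ``per_class_counts`` maps subtype name to the number of slices to
    generate.  Synthetic "patients" group ``slices_per_patient``
    consecutive slices of one class, which makes patient-wise splitting
    meaningful.  The whole dataset is a pure function of
    ``(per_class_counts, spec_defaults, seed)``.
    """
    if slices_per_patient < 1:
        raise ValueError("slices_per_patient must be >= 1")
    for name, count in per_class_counts.items():
        if name != NO_LESION and name not in CLASS_INDEX:
            raise ValueError(f"unknown class {name!r}")
        if count < 0:
            raise ValueError(f"negative count for class {name!r}")

    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    mask_dir = out_dir / "masks"
    img_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)

    seed_rng = np.random.default_rng(seed)
    rows = []
    for name in sorted(per_class_counts):  # fixed order for determinism
        count = per_class_counts[name]
        for i in range(count):
            slice_seed = int(seed_rng.integers(0, 2**31 - 1))
            spec = replace(spec_defaults, lesion_class=name, rng_seed=slice_seed)
            ct, mask, _ = generate_phantom(spec)
            patient_id = f"synth-{name.lower()}-{i // slices_per_patient:03d}"
            stem = f"{name.lower()}_{i:04d}"
            img_path = img_dir / f"{stem}.png"
            mask_path = mask_dir / f"{stem}_mask.png"
            save_slice(ct, img_path)
            save_mask(mask, mask_path)
            rows.append(
                {
                    "image_path": str(img_path),
                    "mask_path": str(mask_path),
                    "class_name": name,
                    "patient_id": patient_id,
                    "split": "unassigned",
                }
            )
    frame = pd.DataFrame(
        rows, columns=["image_path", "mask_path", "class_name", "patient_id", "split"]
    )
    return DatasetManifest(frame)
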