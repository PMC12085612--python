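"""Slice, mask and manifest I/O plus the patient-wise train/test split.

Working formats: 8-bit grayscale PNG/JPEG for slices, paletted PNG with
literal label integers for masks (lossless and trivially countable), a
UTF-8 CSV manifest with columns ``image_path, mask_path, class_name,
patient_id, split``, and read-only NIfTI volumes sliced axially.
Coordinate convention throughout: row-major, origin top-left, 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

MANIFEST_COLUMNS = ["image_path", "mask_path", "class_name", "patient_id", "split"]

#: label value -> class name for mask legends (0 is background)
DEFAULT_LEGEND = {0: "background", 1: "EDH", 2: "IPH", 3: "IVH", 4: "SAH", 5: "SDH"}


@dataclass
class CTSlice:
    """One grayscale CT slice with its identity.

    ``pixels`` is a 2-D uint8 array (values in [0, 255]).
    """

    pixels: np.ndarray
    patient_id: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"slice pixels must be 2-D, got shape {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class SegMask:
    """Per-pixel integer label map; 0 is background, 1-5 hemorrhage classes."""

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"mask labels must be 2-D, got shape {self.labels.shape}")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() > 5):
            raise ValueError("mask labels must lie in {0,...,5}")
        self.labels = self.labels.astype(np.uint8)


class DatasetManifest:
    """Tabular index of a dataset: one row per slice.

    Thin wrapper over a pandas DataFrame with the fixed column set plus
    any extra columns (e.g. a ``synthetic`` flag added by balancing).
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def rows(self, split: str | None = None) -> pd.DataFrame:
        if split is None:
            return self.frame
        return self.frame[self.frame["split"] == split]

    def class_counts(self, split: str | None = None) -> dict[str, int]:
        return self.rows(split)["class_name"].value_counts().to_dict()

    def save(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        return cls(pd.read_csv(path, keep_default_na=False))


# ---------------------------------------------------------------------------
# slice and mask I/O
# ---------------------------------------------------------------------------

def load_slice(
    path: str | Path,
    slice_index: int = 0,
    patient_id: str = "",
) -> CTSlice:
    """Load one grayscale slice from PNG/JPEG or an axial NIfTI volume.

    Color images are converted by the luma transform; NIfTI volumes are
    min-max rescaled to [0, 255] per slice.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise OSError(f"unreadable or empty image file: {path}")
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj)
        if vol.ndim != 3:
            raise OSError(f"expected a 3-D NIfTI volume, got shape {vol.shape}")
        if not (0 <= slice_index < vol.shape[2]):
            raise IndexError(f"slice {slice_index} out of range for {vol.shape}")
        plane = np.asarray(vol[:, :, slice_index], dtype=np.float64)
        lo, hi = plane.min(), plane.max()
        if hi > lo:
            plane = (plane - lo) / (hi - lo) * 255.0
        else:
            plane = np.zeros_like(plane)
        pixels = np.rint(plane).astype(np.uint8)
    else:
        with Image.open(path) as im:
            pixels = np.asarray(im.convert("L"))
    return CTSlice(pixels=pixels, patient_id=patient_id, slice_index=slice_index)


def save_slice(ct: CTSlice, path: str | Path) -> None:
    """Write a slice as 8-bit grayscale PNG (lossless)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(ct.pixels, mode="L").save(path)


_MASK_PALETTE = [
    0, 0, 0,        # 0 background
    255, 0, 0,      # 1 EDH
    0, 255, 0,      # 2 IPH
    0, 0, 255,      # 3 IVH
    255, 255, 0,    # 4 SAH
    255, 0, 255,    # 5 SDH
]


def save_mask(mask: SegMask, path: str | Path) -> None:
    """Write a mask as paletted PNG whose palette indices are the labels."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    im = Image.fromarray(mask.labels, mode="P")
    im.putpalette(_MASK_PALETTE + [0, 0, 0] * (256 - len(_MASK_PALETTE) // 3))
    im.save(path)


def load_mask(path: str | Path) -> SegMask:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise OSError(f"unreadable or empty mask file: {path}")
    with Image.open(path) as im:
        if im.mode not in ("P", "L"):
            raise OSError(f"mask must be paletted or grayscale PNG, got mode {im.mode}")
        labels = np.asarray(im)
    return SegMask(labels=labels)


# ---------------------------------------------------------------------------
# patient-wise splitting
# ---------------------------------------------------------------------------

def split_patientwise(
    manifest: DatasetManifest,
    test_fraction: float = 0.2,
    seed: int = 0,
    per_class_test_counts: dict[str, int] | None = None,
) -> DatasetManifest:
    """Assign ``train``/``test`` per patient, stratified per class.

    All slices of a patient share a split, so no subject leaks across it.
    Per class, the number of test *slices* approximates
    ``test_fraction`` of that class's slices as closely as patient
    granularity allows (or matches ``per_class_test_counts`` if given).
    A class whose slices all belong to one patient cannot be split; it is
    assigned wholly to train with a warning.
    """
    if not (0.0 <= test_fraction <= 1.0):
        raise ValueError("test_fraction must lie in [0, 1]")
    frame = manifest.frame.copy()
    if (frame["patient_id"] == "").any():
        raise ValueError("every manifest row needs a patient_id")

    rng = np.random.default_rng(seed)
    frame["split"] = "train"
    for class_name, group in frame.groupby("class_name", sort=True):
        n_slices = len(group)
        target = (
            per_class_test_counts.get(class_name, 0)
            if per_class_test_counts is not None
            else test_fraction * n_slices
        )
        if target <= 0:
            continue
        patients = group.groupby("patient_id").size()
        if len(patients) == 1 and target < n_slices:
            warnings.warn(
                f"class {class_name!r} has a single patient; assigning it to train",
                stacklevel=2,
            )
            continue
        order = patients.index.to_numpy()
        rng.shuffle(order)
        # greedy: add whole patients while that moves the count toward target
        test_patients, count = [], 0
        for pid in order:
            size = int(patients[pid])
            if abs(count + size - target) < abs(count - target):
                test_patients.append(pid)
                count += size
        if not test_patients:
            # a requested split must hold out something: take the
            # smallest patient even if it overshoots the target
            smallest = min(order, key=lambda pid: int(patients[pid]))
            test_patients.append(smallest)
        frame.loc[
            (frame["class_name"] == class_name)
            & frame["patient_id"].isin(test_patients),
            "split",
        ] = "test"
    return DatasetManifest(frame)
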