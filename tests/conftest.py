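"""Shared fixtures: tiny phantom datasets and surrogate manifests.

All fixture data is generated programmatically at test time; nothing is
stored in the repository.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ihsnet.dataset import CTSlice, DatasetManifest, SegMask, save_mask, save_slice
from ihsnet.phantom import CLASS_INDEX, CLASS_NAMES, PhantomSpec, generate_dataset

#: Reference per-class bookkeeping of the working dataset: total slices,
#: training slices before oversampling, SMOTE targets, test slices.
ACTUAL_COUNTS = {"IVH": 24, "IPH": 73, "SAH": 18, "SDH": 56, "EDH": 173}
BEFORE_SMOTE = {"IVH": 18, "IPH": 58, "SAH": 14, "SDH": 45, "EDH": 138}
SMOTE_TARGETS = {"IVH": 385, "IPH": 400, "SAH": 403, "SDH": 364, "EDH": 408}
TEST_COUNTS = {"IVH": 6, "IPH": 15, "SAH": 4, "SDH": 11, "EDH": 35}


def make_surrogate_dataset(
    root,
    counts: dict[str, int],
    size: int = 16,
    seed: int = 0,
    patient_block: int = 1,
) -> DatasetManifest:
    """Write small random grayscale slices + blob masks and a manifest.

    Surrogates stand in for CT slices in bookkeeping tests where image
    content is irrelevant; ``patient_block`` consecutive slices of one
    class share a synthetic patient id.
    """
    rng = np.random.default_rng(seed)
    img_dir = root / "images"
    mask_dir = root / "masks"
    rows = []
    for name in sorted(counts):
        label = CLASS_INDEX[name] + 1
        for i in range(counts[name]):
            pixels = rng.integers(0, 256, size=(size, size), dtype=np.uint8)
            labels = np.zeros((size, size), dtype=np.uint8)
            r, c = rng.integers(0, size - 4, size=2)
            labels[r : r + 4, c : c + 4] = label
            stem = f"{name.lower()}_{i:04d}"
            img_path = img_dir / f"{stem}.png"
            mask_path = mask_dir / f"{stem}.png"
            save_slice(CTSlice(pixels=pixels), img_path)
            save_mask(SegMask(labels=labels), mask_path)
            rows.append(
                {
                    "image_path": str(img_path),
                    "mask_path": str(mask_path),
                    "class_name": name,
                    "patient_id": f"{name.lower()}-p{i // patient_block:03d}",
                    "split": "unassigned",
                }
            )
    return DatasetManifest(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def tiny_phantom_manifest(tmp_path_factory):
    """Eight 32x32 phantoms (plus one lesion-free class is not needed):
    enough rows to exercise training bookkeeping quickly."""
    root = tmp_path_factory.mktemp("tiny_phantoms")
    spec = PhantomSpec(image_size=32, lesion_scale=0.06, noise_sd=2.0)
    counts = {"IVH": 2, "EDH": 2, "SDH": 2, "SAH": 1, "IPH": 1}
    manifest = generate_dataset(
        counts, root, spec_defaults=spec, seed=11, slices_per_patient=1
    )
    frame = manifest.frame.copy()
    frame["split"] = "train"
    return DatasetManifest(frame)


@pytest.fixture(scope="session")
def seed0_phantom():
    from ihsnet.phantom import generate_phantom

    spec = PhantomSpec(image_size=64, lesion_class="IPH", lesion_scale=0.05, rng_seed=0)
    return generate_phantom(spec)
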