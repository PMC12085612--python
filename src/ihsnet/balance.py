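"""SMOTE oversampling of minority hemorrhage classes.

Classical SMOTE: for each synthetic sample, pick a minority-class vector
x_i, one of its k nearest neighbors x_j (Euclidean distance in the
flattened-image feature space), and a uniform u in [0, 1]; the synthetic
sample is x_i + u * (x_j - x_i).  Balancing runs on the *training* split
only, on the preprocessed grayscale images; test rows are never touched
and never serve as parents.

Segmentation masks for synthetic images are built by interpolating the
two parents' binary lesion masks with the same u and thresholding at
0.5 -- one defensible rule for a step the source method leaves
unspecified; it is isolated behind ``SmoteConfig.mask_rule``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .dataset import CTSlice, DatasetManifest, SegMask, load_mask, load_slice, save_mask, save_slice
from .phantom import CLASS_INDEX


@dataclass(frozen=True)
class SmoteConfig:
    """SMOTE settings: neighborhood size, per-class target counts, seed.

    Targets must not fall below current counts (oversampling only).
    ``mask_rule`` selects how synthetic masks are derived: only
    ``"interpolate-threshold"`` is currently defined.
    """

    k_neighbors: int = 5
    target_counts: dict[str, int] = field(default_factory=dict)
    rng_seed: int = 0
    mask_rule: str = "interpolate-threshold"

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.mask_rule != "interpolate-threshold":
            raise ValueError(f"unknown mask rule {self.mask_rule!r}")


def smote_sample(
    vectors: np.ndarray,
    n_new: int,
    k: int = 5,
    seed: int = 0,
    return_parents: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Generate ``n_new`` synthetic vectors by SMOTE interpolation.

    Each synthetic s satisfies s = x_i + u * (x_j - x_i) with x_j one of
    the k nearest neighbors of x_i and u ~ U[0, 1].  Deterministic given
    ``seed``.  With ``return_parents`` the parent indices (i, j) and the
    interpolation weights u are returned as well.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2:
        raise ValueError("vectors must be a 2-D (n_samples, n_features) array")
    n = vectors.shape[0]
    if n_new < 0:
        raise ValueError("n_new must be >= 0")
    if n <= k:
        raise ValueError(f"need more than k={k} vectors, got {n}")
    if n_new == 0:
        empty = np.empty((0, vectors.shape[1]))
        if return_parents:
            return empty, np.empty(0, int), np.empty(0, int), np.empty(0)
        return empty

    # k+1 because each vector is its own nearest neighbor
    nn = NearestNeighbors(n_neighbors=k + 1).fit(vectors)
    neighbors = nn.kneighbors(vectors, return_distance=False)[:, 1:]

    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=n_new)
    j = neighbors[i, rng.integers(0, k, size=n_new)]
    u = rng.uniform(0.0, 1.0, size=n_new)
    synthetic = vectors[i] + u[:, None] * (vectors[j] - vectors[i])
    if return_parents:
        return synthetic, i, j, u
    return synthetic


def balance_training_set(
    manifest: DatasetManifest,
    cfg: SmoteConfig,
    out_dir: str | Path,
) -> DatasetManifest:
    """Oversample minority classes of the training split to the target
    counts, writing synthetic slices/masks under ``out_dir``.

    Synthetic rows are flagged with ``synthetic=True`` in an extra
    manifest column; test rows pass through untouched.
    """
    frame = manifest.frame.copy()
    if "synthetic" not in frame.columns:
        frame["synthetic"] = False
    if not (frame["split"] == "train").any():
        raise ValueError("manifest has no training split assigned")

    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    mask_dir = out_dir / "masks"

    new_rows = []
    for class_name in sorted(cfg.target_counts):
        if class_name not in CLASS_INDEX:
            raise ValueError(f"unknown class {class_name!r}")
        target = cfg.target_counts[class_name]
        train_rows = frame[
            (frame["class_name"] == class_name) & (frame["split"] == "train")
        ]
        current = len(train_rows)
        if target < current:
            raise ValueError(
                f"target {target} for class {class_name} below current count {current}"
            )
        n_new = target - current
        if n_new == 0:
            continue

        images, masks, shape = [], [], None
        for _, row in train_rows.iterrows():
            ct = load_slice(row["image_path"])
            shape = ct.pixels.shape
            images.append(ct.pixels.astype(np.float64).ravel())
            masks.append((load_mask(row["mask_path"]).labels > 0).astype(np.float64).ravel())
        vectors = np.stack(images)
        mask_vectors = np.stack(masks)

        class_seed = (cfg.rng_seed + CLASS_INDEX[class_name] * 7919) % 2**31
        synthetic, pi, pj, u = smote_sample(
            vectors, n_new, k=cfg.k_neighbors, seed=class_seed, return_parents=True
        )
        label_value = CLASS_INDEX[class_name] + 1
        for s in range(n_new):
            pixels = np.clip(np.rint(synthetic[s]), 0, 255).astype(np.uint8).reshape(shape)
            soft = mask_vectors[pi[s]] + u[s] * (mask_vectors[pj[s]] - mask_vectors[pi[s]])
            labels = np.where(soft.reshape(shape) > 0.5, label_value, 0).astype(np.uint8)
            stem = f"smote_{class_name.lower()}_{s:04d}"
            img_path = img_dir / f"{stem}.png"
            mask_path = mask_dir / f"{stem}_mask.png"
            save_slice(CTSlice(pixels=pixels), img_path)
            save_mask(SegMask(labels=labels), mask_path)
            new_rows.append(
                {
                    "image_path": str(img_path),
                    "mask_path": str(mask_path),
                    "class_name": class_name,
                    "patient_id": f"smote-{class_name.lower()}",
                    "split": "train",
                    "synthetic": True,
                }
            )
    if new_rows:
        frame = pd.concat([frame, pd.DataFrame(new_rows)], ignore_index=True)
    return DatasetManifest(frame)
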