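"""SMOTE interpolation contract and training-set balancing."""

import numpy as np
import pytest

from ihsnet.balance import SmoteConfig, balance_training_set, smote_sample
from ihsnet.dataset import load_mask, load_slice, split_patientwise

from conftest import make_surrogate_dataset


def _is_convex_combination(s, vectors, neighbors, atol=1e-8):
    """Brute-force search for (i, j, u) with s = x_i + u (x_j - x_i)."""
    for i, x_i in enumerate(vectors):
        for j in neighbors[i]:
            d = vectors[j] - x_i
            denom = float(d @ d)
            if denom == 0.0:
                if np.allclose(s, x_i, atol=atol):
                    return True
                continue
            u = float((s - x_i) @ d) / denom
            if -1e-9 <= u <= 1 + 1e-9 and np.allclose(s, x_i + u * d, atol=atol):
                return True
    return False


class TestSmoteSample:
    def test_zero_requested_returns_empty(self):
        out = smote_sample(np.random.default_rng(0).random((10, 4)), 0, k=3, seed=1)
        assert out.shape == (0, 4)

    def test_every_sample_is_verified_convex_combination(self):
        from sklearn.neighbors import NearestNeighbors

        rng = np.random.default_rng(2)
        vectors = rng.random((12, 5))
        k = 4
        out = smote_sample(vectors, 30, k=k, seed=7)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(vectors)
        neighbors = nn.kneighbors(vectors, return_distance=False)[:, 1:]
        assert out.shape == (30, 5)
        for s in out:
            assert _is_convex_combination(s, vectors, neighbors)

    def test_duplicate_vectors_interpolate_to_themselves(self):
        v = np.tile(np.array([[2.0, -1.0, 3.0]]), (2, 1))
        out = smote_sample(v, 5, k=1, seed=3)
        assert np.allclose(out, v[0])

    def test_deterministic_given_seed(self):
        vectors = np.random.default_rng(4).random((8, 3))
        a = smote_sample(vectors, 10, k=2, seed=42)
        b = smote_sample(vectors, 10, k=2, seed=42)
        assert np.array_equal(a, b)

    def test_too_few_vectors_or_negative_count_rejected(self):
        vectors = np.random.default_rng(5).random((3, 2))
        with pytest.raises(ValueError):
            smote_sample(vectors, 1, k=3, seed=0)
        with pytest.raises(ValueError):
            smote_sample(np.random.default_rng(6).random((9, 2)), -1, k=3, seed=0)


class TestBalanceTrainingSet:
    @pytest.fixture()
    def split_manifest(self, tmp_path):
        manifest = make_surrogate_dataset(
            tmp_path, {"IVH": 10, "EDH": 14}, size=16, patient_block=2
        )
        return split_patientwise(manifest, test_fraction=0.2, seed=1)

    def test_counts_reach_targets_and_test_rows_untouched(self, split_manifest, tmp_path):
        targets = {
            "IVH": len(split_manifest.rows("train").query("class_name=='IVH'")) + 5,
            "EDH": len(split_manifest.rows("train").query("class_name=='EDH'")) + 3,
        }
        n_test = len(split_manifest.rows("test"))
        cfg = SmoteConfig(k_neighbors=3, target_counts=targets, rng_seed=0)
        out = balance_training_set(split_manifest, cfg, tmp_path / "smote")
        assert out.class_counts("train") == targets
        assert len(out.rows("test")) == n_test
        synth = out.frame[out.frame["synthetic"] == True]  # noqa: E712
        assert len(synth) == 8
        assert (synth["split"] == "train").all()

    def test_synthetic_pixels_in_byte_range_with_valid_masks(self, split_manifest, tmp_path):
        targets = {"IVH": len(split_manifest.rows("train").query("class_name=='IVH'")) + 4}
        cfg = SmoteConfig(k_neighbors=2, target_counts=targets, rng_seed=5)
        out = balance_training_set(split_manifest, cfg, tmp_path / "smote2")
        for _, row in out.frame[out.frame["synthetic"] == True].iterrows():  # noqa: E712
            pixels = load_slice(row["image_path"]).pixels
            labels = load_mask(row["mask_path"]).labels
            assert pixels.shape == (16, 16)
            # IVH carries label index 2 -> mask value 3
            assert set(np.unique(labels)) <= {0, 3}

    def test_targets_already_met_is_a_no_op(self, split_manifest, tmp_path):
        current = split_manifest.class_counts("train")
        cfg = SmoteConfig(k_neighbors=2, target_counts=current, rng_seed=0)
        out = balance_training_set(split_manifest, cfg, tmp_path / "noop")
        assert len(out) == len(split_manifest)

    def test_target_below_current_rejected(self, split_manifest, tmp_path):
        cfg = SmoteConfig(k_neighbors=2, target_counts={"EDH": 1}, rng_seed=0)
        with pytest.raises(ValueError):
            balance_training_set(split_manifest, cfg, tmp_path / "bad")

    def test_synthetic_parents_come_from_train_only(self, split_manifest, tmp_path):
        # synthetic pixel vectors must lie in the convex hull of the
        # training images of their class (elementwise between min/max)
        targets = {"IVH": len(split_manifest.rows("train").query("class_name=='IVH'")) + 6}
        cfg = SmoteConfig(k_neighbors=3, target_counts=targets, rng_seed=2)
        out = balance_training_set(split_manifest, cfg, tmp_path / "hull")
        train_imgs = np.stack(
            [
                load_slice(p).pixels.astype(float)
                for p in split_manifest.rows("train").query("class_name=='IVH'")["image_path"]
            ]
        )
        lo, hi = train_imgs.min(axis=0), train_imgs.max(axis=0)
        for _, row in out.frame[out.frame["synthetic"] == True].iterrows():  # noqa: E712
            pixels = load_slice(row["image_path"]).pixels.astype(float)
            assert (pixels >= lo - 1).all() and (pixels <= hi + 1).all()
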