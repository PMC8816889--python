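"""Slice extraction, patient-exclusive splits, flip augmentation."""

import numpy as np
import pytest

from lofisim.dataset import (
    SliceRecord,
    assign_split,
    augment_flip,
    extract_slices,
    records_to_frame,
    split_by_patient,
)
from lofisim.volume import LabelMap, Volume


def _volume_with_lesion_pixels(pixels_per_slice, spacing=(1.6, 1.6, 5.0), n_slices=6):
    shape = (24, 24, n_slices)
    data = np.ones(shape)
    mask = np.ones(shape, dtype=bool)
    labels = np.zeros(shape, dtype=np.int32)
    for z, n in pixels_per_slice.items():
        flat = labels[:, :, z].ravel()
        flat[:n] = 1
        labels[:, :, z] = flat.reshape(24, 24)
        plane = data[:, :, z].ravel()
        plane[:n] = 2.0
        data[:, :, z] = plane.reshape(24, 24)
    return Volume(data, spacing, mask), LabelMap(labels, spacing)


def test_single_lesion_pixel_labels_slice_positive():
    vol, labels = _volume_with_lesion_pixels({2: 1})
    records = extract_slices(vol, labels, "P1", arm="simLF")
    rec = records[2]
    assert rec.label == 1
    assert rec.lesion_area_cm2 == pytest.approx(0.0256)  # 1.6 mm x 1.6 mm pixel


def test_lesion_free_slice_is_negative_with_zero_covariates():
    vol, labels = _volume_with_lesion_pixels({2: 5})
    rec = extract_slices(vol, labels, "P1")[0]
    assert (rec.label, rec.lesion_area_cm2, rec.lesion_contrast) == (0, 0.0, 0.0)


def test_positive_record_count_matches_lesion_extent(lesion_phantom):
    _, vol, labels, _ = lesion_phantom
    records = extract_slices(vol, labels, "P1")
    assert sum(r.label for r in records) == 5  # lesion spans 5 slices


def test_contrast_covariate_sign_is_positive_for_hyperintense(lesion_phantom):
    _, vol, labels, _ = lesion_phantom
    pos = [r for r in extract_slices(vol, labels, "P1") if r.label]
    assert all(r.lesion_contrast > 0 for r in pos)


def test_area_bookkeeping_consistent_with_3d_volume(lesion_phantom):
    _, vol, labels, _ = lesion_phantom
    records = extract_slices(vol, labels, "P1")
    per_slice_volume = sum(r.lesion_area_cm2 for r in records) * vol.slice_thickness_mm / 10.0
    voxel_cm3 = np.prod(vol.spacing_mm) / 1000.0
    true_volume = (labels.labels > 0).sum() * voxel_cm3
    assert per_slice_volume == pytest.approx(true_volume, abs=voxel_cm3)


def test_misaligned_shapes_rejected():
    vol, _ = _volume_with_lesion_pixels({})
    labels = LabelMap(np.zeros((10, 10, 2), dtype=np.int32), vol.spacing_mm)
    with pytest.raises(ValueError):
        extract_slices(vol, labels, "P1")


def test_record_invariant_label_iff_area():
    with pytest.raises(ValueError):
        SliceRecord("P", 0, np.zeros((4, 4)), label=1, lesion_area_cm2=0.0,
                    lesion_contrast=0.0, arm="HF")


class TestSplit:
    def test_20_patients_at_ratio_09_gives_18_2(self):
        ids = [f"P{i}" for i in range(20)]
        m = split_by_patient(ids, 0.9, seed=4)
        assert (len(m.train_patients), len(m.test_patients)) == (18, 2)

    def test_same_seed_reproduces_manifest(self):
        ids = [f"P{i}" for i in range(11)]
        assert split_by_patient(ids, 0.8, 7) == split_by_patient(ids, 0.8, 7)

    def test_two_patients_split_one_one(self):
        m = split_by_patient(["A", "B"], 0.5, 0)
        assert len(m.train_patients) == len(m.test_patients) == 1

    @pytest.mark.parametrize("seed", range(25))
    def test_disjoint_and_covering(self, seed):
        ids = [f"P{i}" for i in range(13)]
        m = split_by_patient(ids, 0.85, seed)
        assert set(m.train_patients) & set(m.test_patients) == set()
        assert set(m.train_patients) | set(m.test_patients) == set(ids)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            split_by_patient(["A"], 0.5, 0)


class TestAugmentFlip:
    def _records(self, split="train"):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(12):
            recs.append(
                SliceRecord(f"P{i}", 0, rng.normal(size=(8, 8)), 0, 0.0, 0.0, "HF", split=split)
            )
        return recs

    def test_flip_is_horizontal_mirror_and_label_preserving(self):
        recs = self._records()
        out = list(augment_flip(recs, seed=5))
        flipped = [o for o, r in zip(out, recs) if not np.array_equal(o.pixels, r.pixels)]
        assert flipped, "with 12 records some flips are expected"
        for o, r in zip(out, recs):
            if not np.array_equal(o.pixels, r.pixels):
                assert np.array_equal(o.pixels, r.pixels[:, ::-1])
            assert (o.label, o.lesion_area_cm2, o.split) == (r.label, r.lesion_area_cm2, r.split)

    def test_seeded_flip_decisions_reproduce(self):
        recs = self._records()
        a = [r.pixels for r in augment_flip(recs, seed=9)]
        b = [r.pixels for r in augment_flip(recs, seed=9)]
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_test_split_records_are_refused(self):
        with pytest.raises(ValueError, match="test"):
            list(augment_flip(self._records(split="test"), seed=0))


def test_assign_split_stamps_every_record():
    vol, labels = _volume_with_lesion_pixels({1: 4})
    recs = extract_slices(vol, labels, "A") + extract_slices(vol, labels, "B")
    manifest = split_by_patient(["A", "B"], 0.5, 0)
    assign_split(recs, manifest)
    frame = records_to_frame(recs)
    assert set(frame.split) == {"train", "test"}
    assert frame.groupby("patient_id").split.nunique().max() == 1
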