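"""Domain types, repetition splits, class balancing and manifest I/O."""

import numpy as np
import pytest

from emgaug import (
    ConfigurationError,
    DatasetIOError,
    LabeledDataset,
    MultichannelSignal,
    RecordingMeta,
    balance_classes,
    read_dataset,
    split_by_repetition,
    write_dataset,
)
from emgaug.windowing import SegmentSet, WindowingConfig, segment

import pandas as pd


def _ds(rep_labels):
    """Tiny dataset with one record per (repetition, gesture) pair."""
    recs = []
    for rep, gesture in rep_labels:
        sig = MultichannelSignal(np.full((20, 2), float(rep)), 100.0)
        recs.append((sig, RecordingMeta("s01", gesture, rep)))
    return LabeledDataset(recs)


class TestSignalTypes:
    def test_signal_validation(self):
        with pytest.raises(ValueError):
            MultichannelSignal(np.array([[np.nan, 1.0]]), 100.0)
        with pytest.raises(ValueError):
            MultichannelSignal(np.ones((5, 2)), -1.0)
        sig = MultichannelSignal(np.ones(7), 10.0)  # 1-D promotes to (7, 1)
        assert sig.channel_count == 1 and sig.n_samples == 7

    def test_meta_origin_lineage_consistency(self):
        with pytest.raises(ValueError):
            RecordingMeta("s", 0, 1, origin="real", lineage=("gn",))
        with pytest.raises(ValueError):
            RecordingMeta("s", 0, 1, origin="augmented")
        meta = RecordingMeta("s", 3, 2).derived(["mw", "gn"])
        assert meta.origin == "augmented" and meta.lineage == ("mw", "gn")
        assert meta.gesture_label == 3 and meta.repetition == 2

    def test_dataset_rejects_mixed_rates_and_ragged_channels(self):
        a = MultichannelSignal(np.ones((5, 2)), 100.0)
        b = MultichannelSignal(np.ones((5, 2)), 200.0)
        c = MultichannelSignal(np.ones((5, 3)), 100.0)
        m = RecordingMeta("s", 0, 1)
        with pytest.raises(DatasetIOError):
            LabeledDataset([(a, m), (b, m)])
        with pytest.raises(DatasetIOError):
            LabeledDataset([(a, m), (c, m)])


class TestSplit:
    def test_repetition_five_goes_to_test_only(self):
        ds = _ds([(r, 0) for r in range(1, 11)])
        train, val, test = split_by_repetition(
            ds, train_reps=set(range(1, 11)) - {4, 5}, val_reps={4}, test_reps={5}
        )
        assert {m.repetition for _, m in test} == {5}
        assert all(m.repetition != 5 for _, m in train)
        assert all(m.repetition != 5 for _, m in val)
        assert len(train) + len(val) + len(test) == len(ds)

    def test_empty_train_set_allowed(self):
        ds = _ds([(1, 0), (2, 0)])
        train, val, test = split_by_repetition(ds, set(), {1}, {2})
        assert len(train) == 0 and len(val) == 1 and len(test) == 1

    def test_overlapping_sets_rejected(self):
        ds = _ds([(1, 0)])
        with pytest.raises(ConfigurationError, match="overlap"):
            split_by_repetition(ds, {1, 2}, {2}, {3})

    def test_uncovered_repetition_named_in_error(self):
        ds = _ds([(1, 0), (2, 0)])
        with pytest.raises(ConfigurationError, match=r"\[2\]"):
            split_by_repetition(ds, {1}, set(), set())
        # a repetition absent from the dataset may appear in a split set
        split_by_repetition(_ds([(1, 0), (2, 0)]), {1}, {2}, {3})


def _segs(label_counts):
    images, rows = [], []
    i = 0
    for lab, count in label_counts.items():
        for _ in range(count):
            images.append(np.full((4, 2), float(i)))
            rows.append((i, 0, "s01", lab, 1, "real"))
            i += 1
    meta = pd.DataFrame(
        rows, columns=["record", "start", "subject", "gesture", "repetition", "origin"]
    )
    return SegmentSet(np.stack(images), meta)


class TestBalance:
    def test_counts_equal_minimum(self):
        out = balance_classes(_segs({0: 5, 1: 3}), rng_seed=0)
        assert out.label_counts() == {0: 3, 1: 3}

    def test_already_balanced_unchanged(self):
        segs = _segs({0: 4, 1: 4})
        out = balance_classes(segs, rng_seed=0)
        assert len(out) == 8
        np.testing.assert_array_equal(out.images, segs.images)

    def test_deterministic_under_seed(self):
        segs = _segs({0: 9, 1: 4, 2: 6})
        a = balance_classes(segs, rng_seed=42)
        b = balance_classes(segs, rng_seed=42)
        np.testing.assert_array_equal(a.images, b.images)
        assert a.meta.equals(b.meta)

    def test_never_increases_any_count(self):
        segs = _segs({0: 7, 1: 2, 2: 5})
        out = balance_classes(segs, rng_seed=3)
        before = segs.label_counts()
        after = out.label_counts()
        assert all(after[k] <= before[k] for k in before)
        assert len(set(after.values())) == 1

    def test_single_label_returned_unchanged(self):
        segs = _segs({0: 5})
        out = balance_classes(segs, rng_seed=0)
        assert len(out) == 5


class TestManifestIO:
    def test_roundtrip_exact(self, tmp_path, small_dataset):
        sub = LabeledDataset(small_dataset.records[:2])
        manifest = write_dataset(sub, tmp_path / "ds")
        back = read_dataset(manifest)
        assert len(back) == 2
        for (s0, m0), (s1, m1) in zip(sub, back):
            np.testing.assert_array_equal(s0.samples, s1.samples)
            assert m0 == m1

    def test_missing_record_file(self, tmp_path, small_dataset):
        sub = LabeledDataset(small_dataset.records[:1])
        manifest = write_dataset(sub, tmp_path / "ds")
        (tmp_path / "ds" / "rec_00000.csv").unlink()
        with pytest.raises(DatasetIOError, match="not found"):
            read_dataset(manifest)

    def test_fs_mismatch_names_both_rates(self, tmp_path, small_dataset):
        import json

        sub = LabeledDataset(small_dataset.records[:1])
        manifest = write_dataset(sub, tmp_path / "ds")
        doc = json.loads(manifest.read_text())
        doc["records"][0]["fs_hz"] = 200.0
        manifest.write_text(json.dumps(doc))
        with pytest.raises(DatasetIOError, match="100.*200|200.*100"):
            read_dataset(manifest)

    def test_empty_manifest_gives_empty_dataset(self, tmp_path):
        p = tmp_path / "manifest.json"
        p.write_text('{"fs_hz": 100.0, "records": []}')
        assert len(read_dataset(p)) == 0

    def test_augmented_lineage_survives_roundtrip(self, tmp_path):
        sig = MultichannelSignal(np.ones((10, 2)), 100.0)
        meta = RecordingMeta("s02", 1, 3).derived(["ss2", "gn"])
        manifest = write_dataset(LabeledDataset([(sig, meta)]), tmp_path / "a")
        back = read_dataset(manifest)
        assert back.records[0][1].lineage == ("ss2", "gn")
        assert back.records[0][1].origin == "augmented"
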