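"""Splits, metric suite, per-donor accuracy, schedules."""

import numpy as np
import pandas as pd
import pytest

from deformcyte.reference import REFERENCE_SPLITS, TOTAL_CELLS, \
    reference_donor_specs
from deformcyte.synthetic import build_manifest
from deformcyte.training import (ClipDataset, TrainConfig, compute_metrics,
                                 cosine_warm_restart_lr, fold_mean_metrics,
                                 macro_sensitivity, make_splits,
                                 per_donor_accuracy)


def manifest_of(counts):
    return pd.DataFrame({
        "donor_id": [f"d{i}" for i in range(len(counts))],
        "class_label": ["adult" if i % 2 else "fetal"
                        for i in range(len(counts))],
        "n_cells": counts,
    })


class TestMakeSplits:
    def test_equal_donors_give_exact_fifths(self):
        m = manifest_of([10] * 5)
        s = make_splits(m, k=5, seed=0)
        per_split = [sum(10 for d in s.donors_in(i)) for i in range(5)]
        assert per_split == [10] * 5

    def test_disjoint_and_complete(self):
        rng = np.random.default_rng(0)
        m = manifest_of(list(rng.integers(50, 300, size=23)))
        s = make_splits(m, k=5, seed=1)
        all_donors = [d for i in range(5) for d in s.donors_in(i)]
        assert sorted(all_donors) == sorted(m.donor_id)
        assert len(all_donors) == len(set(all_donors))

    def test_reference_cohort_balance(self):
        """Greedy balancing on the 164-donor reference cohort keeps every
        split within 20% +/- 2 percentage points of the cells, like the
        published allocation (test split: 20.34%)."""
        manifest = build_manifest(reference_donor_specs())
        s = make_splits(manifest, k=5, seed=0)
        m = manifest.set_index("donor_id")
        for i in range(5):
            frac = m.loc[s.donors_in(i), "n_cells"].sum() / TOTAL_CELLS
            assert 0.18 < frac < 0.22

    def test_stratified_splits_contain_both_classes(self):
        m = manifest_of([30] * 12)
        s = make_splits(m, k=5, seed=3, stratify=True)
        cls = m.set_index("donor_id").class_label
        for i in range(5):
            labels = {cls[d] for d in s.donors_in(i)}
            assert labels == {"adult", "fetal"}

    def test_too_few_donors_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            make_splits(manifest_of([10, 10]), k=5)

    def test_deterministic_given_seed(self):
        m = manifest_of([17, 3, 9, 12, 25, 8, 30, 14])
        a = make_splits(m, k=5, seed=7)
        b = make_splits(m, k=5, seed=7)
        assert a.assignment == b.assignment


class TestComputeMetrics:
    def test_perfect_predictions(self):
        labels = np.array([0, 1] * 5)
        scores = np.eye(2)[labels]
        r = compute_metrics(scores, labels)
        assert r.accuracy == 100.0 and r.f1 == 100.0
        assert r.confusion[0, 1] == 0 and r.confusion[1, 0] == 0
        assert r.sensitivity == 100.0

    def test_hand_computed_confusion(self):
        """Confusion [[8,2],[1,9]] -> accuracy 85%, adult recall 80%,
        fetal recall 90%, macro sensitivity 85%."""
        labels = np.array([0] * 10 + [1] * 10)
        pred = np.array([0] * 8 + [1] * 2 + [1] * 9 + [0] * 1)
        scores = np.eye(2)[pred]
        r = compute_metrics(scores, labels)
        assert np.array_equal(r.confusion, [[8, 2], [1, 9]])
        assert r.accuracy == pytest.approx(85.0)
        assert r.per_class_recall["adult"] == pytest.approx(80.0)
        assert r.per_class_recall["fetal"] == pytest.approx(90.0)
        assert r.sensitivity == pytest.approx(85.0)

    def test_macro_sensitivity_equals_mean_recall_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            labels = rng.integers(0, 2, size=60)
            if len(np.unique(labels)) < 2:
                continue
            pred = rng.integers(0, 2, size=60)
            # brute-force per-class counts
            want = np.mean([
                np.sum((labels == c) & (pred == c)) / np.sum(labels == c)
                for c in (0, 1)])
            assert macro_sensitivity(labels, pred) == pytest.approx(want)

    def test_metric_identities_on_random_confusions(self):
        """accuracy = (TP+TN)/n and F1 = 2PR/(P+R) against direct counts."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            labels = rng.integers(0, 2, size=80)
            pred = rng.integers(0, 2, size=80)
            if len(np.unique(labels)) < 2 or pred.sum() in (0, 80):
                continue
            scores = np.eye(2)[pred]
            r = compute_metrics(scores, labels)
            tp = np.sum((labels == 1) & (pred == 1))
            tn = np.sum((labels == 0) & (pred == 0))
            fp = np.sum((labels == 0) & (pred == 1))
            fn = np.sum((labels == 1) & (pred == 0))
            assert r.accuracy == pytest.approx(100 * (tp + tn) / 80)
            p_, r_ = tp / (tp + fp), tp / (tp + fn)
            if p_ + r_ > 0:
                assert r.f1 == pytest.approx(100 * 2 * p_ * r_ / (p_ + r_))

    def test_auc_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, size=50)
        s = rng.random(50)
        scores = np.column_stack([1 - s, s])
        r = compute_metrics(scores, labels)
        pos, neg = s[labels == 1], s[labels == 0]
        pairs = [(p > n) + 0.5 * (p == n) for p in pos for n in neg]
        assert r.auc == pytest.approx(100 * np.mean(pairs))

    def test_single_class_auc_undefined(self):
        labels = np.ones(10, dtype=int)
        scores = np.column_stack([np.zeros(10), np.ones(10)])
        r = compute_metrics(scores, labels)
        assert np.isnan(r.auc)
        assert any("AUC undefined" in n for n in r.notes)

    def test_fold_mean_confusion_sums_to_mean_n(self):
        rng = np.random.default_rng(4)
        reports = []
        for _ in range(4):
            labels = rng.integers(0, 2, size=40)
            scores = rng.dirichlet([1, 1], size=40)
            reports.append(compute_metrics(scores, labels))
        agg = fold_mean_metrics(reports)
        assert agg.confusion.sum() == pytest.approx(agg.n)


class TestPerDonorAccuracy:
    def _data(self):
        labels = np.array([0] * 6 + [1] * 6)
        donors = np.array(["a1"] * 3 + ["a2"] * 3 + ["f1"] * 3 + ["f2"] * 3,
                          dtype=object)
        return labels, donors

    def test_all_correct(self):
        labels, donors = self._data()
        scores = [np.eye(2)[labels]] * 4
        table, summary = per_donor_accuracy(scores, labels, donors)
        assert table.grid.shape == (4, 4)
        assert (table.grid == 1.0).all()
        assert (summary[["lowest", "mean", "highest"]] == 1.0).all().all()

    def test_donors_weighted_equally(self):
        """Donor accuracies (0.8, 1.0) average to 0.9 regardless of the
        donors' cell counts."""
        labels = np.array([0] * 5 + [0] * 20)
        donors = np.array(["a1"] * 5 + ["a2"] * 20, dtype=object)
        pred = np.concatenate([[0, 0, 0, 0, 1],        # a1: 0.8
                               np.zeros(20, dtype=int)])  # a2: 1.0
        table, summary = per_donor_accuracy([np.eye(2)[pred]], labels, donors)
        row = summary[summary.class_label == "adult"].iloc[0]
        assert row["mean"] == pytest.approx(0.9)

    def test_grid_completeness(self):
        labels, donors = self._data()
        scores = [np.eye(2)[labels]] * 4
        table, _ = per_donor_accuracy(scores, labels, donors)
        assert table.grid.size == 16
        assert table.n_folds == 4
        assert table.donor_classes == ["adult", "adult", "fetal", "fetal"]


class TestSchedule:
    def test_warm_restart_shape(self):
        cfg = TrainConfig(lr=0.01, restart_period=10, restart_mult=2,
                          lr_min=1e-4)
        assert cosine_warm_restart_lr(0, cfg) == pytest.approx(0.01)
        assert cosine_warm_restart_lr(10, cfg) == pytest.approx(0.01)
        assert cosine_warm_restart_lr(30, cfg) == pytest.approx(0.01)
        assert cosine_warm_restart_lr(9, cfg) < cosine_warm_restart_lr(5, cfg)
        # periods: [0,10), [10,30), [30,70)
        assert cosine_warm_restart_lr(29, cfg) < 1e-3


class TestRunCv:
    def test_four_folds_with_even_epoch_validation(self):
        from deformcyte.slowfast import SlowFastConfig
        from deformcyte.training import run_cv

        rng = np.random.default_rng(0)
        n_donors, per = 10, 6
        ds = ClipDataset(
            clips=(rng.random((n_donors * per, 16, 50, 50)) * 255).astype(np.uint8),
            labels=np.repeat(np.arange(n_donors) % 2, per),
            donor_ids=np.repeat([f"d{i}" for i in range(n_donors)],
                                per).astype(object))
        manifest = pd.DataFrame({
            "donor_id": [f"d{i}" for i in range(n_donors)],
            "class_label": ["fetal" if i % 2 else "adult"
                            for i in range(n_donors)],
            "n_cells": [per] * n_donors})
        splits = make_splits(manifest, k=5, seed=0, stratify=True)
        mcfg = SlowFastConfig(clip_frames=16, spatial_pool=2)
        tcfg = TrainConfig(max_epochs=2, jitter_px=0, temporal_jitter=0)
        models, hists = run_cv(ds, splits, mcfg, tcfg, seed=0)
        assert len(models) == 4 and len(hists) == 4
        assert [h["fold"] for h in hists] == [0, 1, 2, 3]
        assert {h["val_split"] for h in hists} == set(splits.cv_splits)
        for h in hists:
            for epoch, _ in h["val_points"]:
                assert epoch % 2 == 0
        # setup determinism: same seed reproduces the epoch-0 loss exactly
        models2, hists2 = run_cv(ds, splits, mcfg, tcfg, seed=0)
        assert [h["epoch_loss"][0] for h in hists] == \
               [h["epoch_loss"][0] for h in hists2]


class TestClipDataset:
    def test_donor_subset(self):
        ds = ClipDataset(
            clips=np.zeros((6, 4, 8, 8), dtype=np.uint8),
            labels=np.array([0, 0, 1, 1, 0, 1]),
            donor_ids=np.array(["a", "a", "b", "b", "c", "c"], dtype=object))
        sub = ds.donors_subset(["a", "c"])
        assert len(sub) == 4
        assert set(sub.donor_ids) == {"a", "c"}
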