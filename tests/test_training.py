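"""Cross-validation plumbing: fold construction, stratification,
subject independence, training-loop contracts and determinism."""

import numpy as np
import pytest

from radarcough.config import (AugmentationConfig, DatasetSpec, ModelConfig,
                               TrainConfig)
from radarcough.simulate import generate_manifest
from radarcough.training import (Fold, assert_subject_independent,
                                 build_rdm_dataset, make_folds,
                                 summarize_folds, train_one_fold)


@pytest.fixture(scope="module")
def default_manifest():
    return generate_manifest(DatasetSpec())


@pytest.fixture(scope="module")
def tiny_data(tiny_dataset_spec):
    manifest = generate_manifest(tiny_dataset_spec)
    # reuse frames cropped short to keep the training tests fast
    data = build_rdm_dataset(manifest, tiny_dataset_spec,
                             frame_slice=slice(0, 12))
    return manifest, data


# make session fixtures visible at module scope
@pytest.fixture(scope="module")
def tiny_dataset_spec():
    return DatasetSpec(num_subjects=5, bed_cough=2, bed_noncough=2,
                       sitting_cough=2, sitting_noncough=2, snr_db=20.0,
                       master_seed=11)


class TestMakeFolds:
    def test_default_partition_properties(self, default_manifest):
        plan = make_folds(default_manifest.subjects(), default_manifest,
                          k=5, n_test=3, rng=0)
        assert len(plan.folds) == 5
        groups = [set(f.test_subjects) for f in plan.folds]
        assert all(len(g) == 3 for g in groups)
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                assert not (a & b)
        assert set.union(*groups) == set(default_manifest.subjects())

    def test_subject_independence_every_fold(self, default_manifest):
        plan = make_folds(default_manifest.subjects(), default_manifest,
                          k=5, n_test=3, rng=1)
        for fold in plan.folds:
            assert_subject_independent(fold, default_manifest)

    def test_train_val_ratio_and_stratification(self, default_manifest):
        plan = make_folds(default_manifest.subjects(), default_manifest,
                          k=5, n_test=3, rng=2)
        labels = {r.sample_id: r.label for r in default_manifest.records}
        for fold in plan.folds:
            n_train, n_val = len(fold.train_ids), len(fold.val_ids)
            assert n_val / (n_train + n_val) == pytest.approx(0.2, abs=0.01)
            train_ratio = np.mean([labels[i] for i in fold.train_ids])
            val_ratio = np.mean([labels[i] for i in fold.val_ids])
            # stratified by label: class ratio preserved within one sample
            assert abs(train_ratio - val_ratio) < 1.5 / n_val

    def test_wrong_group_arithmetic_rejected(self, default_manifest):
        with pytest.raises(ValueError, match="k\\*n_test"):
            make_folds(default_manifest.subjects(), default_manifest,
                       k=4, n_test=3, rng=0)

    def test_deterministic_given_rng(self, default_manifest):
        a = make_folds(default_manifest.subjects(), default_manifest, rng=7)
        b = make_folds(default_manifest.subjects(), default_manifest, rng=7)
        for fa, fb in zip(a.folds, b.folds):
            assert fa == fb


class TestBuildDataset:
    def test_shapes_and_labels(self, tiny_data, tiny_dataset_spec):
        manifest, data = tiny_data
        assert set(data) == {r.sample_id for r in manifest.records}
        labels = {r.sample_id: r.label for r in manifest.records}
        for sid, (arr, label) in data.items():
            assert arr.shape == (12, 1, 48, 125)
            assert arr.dtype == np.float32
            assert label == labels[sid]


class TestTrainOneFold:
    @pytest.fixture(scope="class")
    def fold(self, tiny_data):
        manifest, _ = tiny_data
        plan = make_folds(manifest.subjects(), manifest, k=5, n_test=1, rng=0)
        return plan.folds[0]

    @pytest.fixture(scope="class")
    def fast_cfgs(self):
        model_cfg = ModelConfig(spatial_backbone="resnet18", base_channels=2,
                                feature_dim=16, ffn_hidden_dim=32)
        train_cfg = TrainConfig(learning_rate=1e-3, weight_decay=0.0,
                                batch_size=8, epochs=2, seed=5)
        return model_cfg, train_cfg

    def test_zero_epochs_rejected(self, tiny_data, fold, fast_cfgs):
        _, data = tiny_data
        model_cfg, _ = fast_cfgs
        with pytest.raises(ValueError, match="no checkpoint selected"):
            train_one_fold(fold, data, model_cfg,
                           TrainConfig(epochs=0, seed=0))

    def test_empty_partition_rejected(self, tiny_data, fast_cfgs):
        _, data = tiny_data
        model_cfg, train_cfg = fast_cfgs
        empty = Fold(test_subjects=[], train_ids=list(data)[:4],
                     val_ids=list(data)[4:6], test_ids=[])
        with pytest.raises(ValueError, match="empty"):
            train_one_fold(empty, data, model_cfg, train_cfg)

    def test_identical_seeds_identical_trajectories(self, tiny_data, fold,
                                                    fast_cfgs):
        manifest, data = tiny_data
        model_cfg, train_cfg = fast_cfgs
        aug = AugmentationConfig()
        _, res_a = train_one_fold(fold, data, model_cfg, train_cfg, aug,
                                  manifest=manifest)
        _, res_b = train_one_fold(fold, data, model_cfg, train_cfg, aug,
                                  manifest=manifest)
        assert res_a.val_f1_history == res_b.val_f1_history
        assert res_a.train_loss_history == res_b.train_loss_history
        assert res_a.report.to_dict() == res_b.report.to_dict()

    def test_best_checkpoint_selected_by_val_f1(self, tiny_data, fold,
                                                fast_cfgs):
        _, data = tiny_data
        model_cfg, train_cfg = fast_cfgs
        _, res = train_one_fold(fold, data, model_cfg, train_cfg)
        best = max(range(len(res.val_f1_history)),
                   key=lambda i: (res.val_f1_history[i], i))
        assert res.best_epoch == best


class TestSummaries:
    def test_summary_mean_and_std(self):
        from radarcough.metrics import MetricsReport

        reports = [
            MetricsReport(1, 0, 0, 1, acc, 1, 1, 1, f1, 0.1, 1.0)
            for acc, f1 in [(0.9, 0.8), (1.0, 0.9)]
        ]
        summary = summarize_folds(reports)
        assert summary["accuracy"]["mean"] == pytest.approx(0.95)
        assert summary["f1"]["std"] == pytest.approx(np.std([0.8, 0.9], ddof=1))

    def test_fold_order_invariance(self):
        from radarcough.metrics import MetricsReport

        reports = [
            MetricsReport(1, 0, 0, 1, a, p, r, s, f, b, u)
            for a, p, r, s, f, b, u in [
                (0.9, 0.8, 0.7, 0.95, 0.75, 0.1, 0.9),
                (0.8, 0.7, 0.9, 0.85, 0.79, 0.2, 0.8),
                (1.0, 1.0, 1.0, 1.00, 1.00, 0.0, 1.0),
            ]
        ]
        fwd = summarize_folds(reports)
        rev = summarize_folds(reports[::-1])
        for name, stats in fwd.items():
            assert rev[name]["mean"] == pytest.approx(stats["mean"], abs=1e-12)
            assert rev[name]["std"] == pytest.approx(stats["std"], abs=1e-12)
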