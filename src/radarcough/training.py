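"""Subject-independent cross-validation and the training loop.

Protocol: the subject pool is randomly partitioned into k disjoint test
groups (no subject ever contributes data to both a fold's training and test
partitions).  Within each fold the remaining subjects' recordings are split
80/20 into train/validation, stratified by the binary label.  Training runs
Adam at the configured hyperparameters with augmentation on the training
partition only; after every epoch the validation F1 (threshold 0.5) is
computed and the best-validation-F1 weights (ties broken toward the later
epoch) are restored before the single test-set evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .augment import augment_array
from .config import (AugmentationConfig, DatasetSpec, ModelConfig,
                     PipelineConfig, RadarConfig, TrainConfig)
from .metrics import MetricsReport, aggregate_fold_metric, compute_metrics
from .model import CoughClassifier
from .nn import Adam, softmax, softmax_cross_entropy
from .pipeline import preprocess, standardize
from .simulate import DatasetManifest, cube_for_record


@dataclass
class Fold:
    test_subjects: list[str]
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]


@dataclass
class FoldPlan:
    folds: list[Fold]
    master_seed: int = 0


def make_folds(subject_ids, manifest: DatasetManifest, k: int = 5,
               n_test: int = 3, rng: np.random.Generator | int = 0,
               val_fraction: float = 0.2) -> FoldPlan:
    """Partition subjects into k disjoint test groups and split the rest.

    Raises if ``k * n_test`` does not equal the number of subjects.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    subject_ids = list(subject_ids)
    if k * n_test != len(subject_ids):
        raise ValueError(
            f"k*n_test = {k * n_test} must equal the number of subjects "
            f"({len(subject_ids)})"
        )
    order = list(rng.permutation(subject_ids))
    groups = [sorted(order[i * n_test:(i + 1) * n_test]) for i in range(k)]

    folds = []
    for test_subjects in groups:
        test_ids = [r.sample_id for r in manifest.records
                    if r.subject_id in test_subjects]
        rest = [r for r in manifest.records if r.subject_id not in test_subjects]
        rest_ids = [r.sample_id for r in rest]
        rest_labels = [r.label for r in rest]
        seed = int(rng.integers(0, 2**31 - 1))
        train_ids, val_ids = train_test_split(
            rest_ids, test_size=val_fraction, stratify=rest_labels,
            random_state=seed,
        )
        folds.append(Fold(test_subjects=test_subjects,
                          train_ids=sorted(train_ids),
                          val_ids=sorted(val_ids),
                          test_ids=sorted(test_ids)))
    return FoldPlan(folds=folds)


def assert_subject_independent(fold: Fold, manifest: DatasetManifest):
    """Sanity check run on every fold: test subjects never leak into train/val."""
    by_id = {r.sample_id: r.subject_id for r in manifest.records}
    trainval = {by_id[i] for i in fold.train_ids + fold.val_ids}
    if trainval & set(fold.test_subjects):
        raise AssertionError("subject leakage between train/val and test")


# ---------------------------------------------------------------------------
# dataset materialization
# ---------------------------------------------------------------------------

def build_rdm_dataset(manifest: DatasetManifest, spec: DatasetSpec,
                      radar_cfg: RadarConfig | None = None,
                      pipeline_cfg: PipelineConfig | None = None,
                      frame_slice: slice | None = None) -> dict:
    """Synthesize + preprocess every manifest record into log-RDM arrays.

    Returns ``{sample_id: (float32 (T,1,B,W) array, label)}``.
    ``frame_slice`` optionally keeps a temporal sub-window (sequence-length
    ablations).
    """
    radar_cfg = radar_cfg or RadarConfig()
    pipeline_cfg = pipeline_cfg or PipelineConfig()
    out = {}
    for rec in manifest.records:
        cube = cube_for_record(rec, spec, radar_cfg)
        seq = preprocess(cube, pipeline_cfg, radar_cfg)
        data = seq.data.astype(np.float32)
        if frame_slice is not None:
            data = data[frame_slice]
        out[rec.sample_id] = (data, rec.label)
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    report: MetricsReport
    best_epoch: int
    val_f1_history: list[float] = field(default_factory=list)
    train_loss_history: list[float] = field(default_factory=list)


def _batches(ids, batch_size):
    for i in range(0, len(ids), batch_size):
        yield ids[i:i + batch_size]


def _stack(dataset, ids, augment_cfg=None, rng=None):
    xs, ys = [], []
    for sid in ids:
        data, label = dataset[sid]
        if augment_cfg is not None:
            data = augment_array(data, augment_cfg, rng)
        xs.append(standardize(data).astype(np.float32))
        ys.append(label)
    return np.stack(xs), np.array(ys, dtype=int)


def _predict_proba(model, dataset, ids, batch_size):
    model.eval()
    probs = []
    for chunk in _batches(ids, batch_size):
        x, _ = _stack(dataset, chunk)
        probs.append(softmax(model.forward(x))[:, 1])
    model.train()
    return np.concatenate(probs)


def _f1_at_half(y_true, probs):
    y_pred = (probs >= 0.5).astype(int)
    tp = np.sum((y_true == 1) & (y_pred == 1))
    fp = np.sum((y_true == 0) & (y_pred == 1))
    fn = np.sum((y_true == 1) & (y_pred == 0))
    denom = 2 * tp + fp + fn
    return float(2 * tp / denom) if denom else 0.0


def train_one_fold(fold: Fold, dataset: dict,
                   model_cfg: ModelConfig | None = None,
                   train_cfg: TrainConfig | None = None,
                   augment_cfg: AugmentationConfig | None = None,
                   manifest: DatasetManifest | None = None,
                   verbose: bool = False) -> tuple[CoughClassifier, FoldResult]:
    """Train on one fold and evaluate once on its held-out test subjects.

    ``augment_cfg=None`` disables augmentation; validation and test data are
    never augmented.  Deterministic given ``train_cfg.seed``.
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    if not (fold.train_ids and fold.val_ids and fold.test_ids):
        raise ValueError("empty train/val/test partition")
    if train_cfg.epochs == 0:
        raise ValueError("no checkpoint selected: epochs must be >= 1")
    if manifest is not None:
        assert_subject_independent(fold, manifest)

    frame_shape = dataset[fold.train_ids[0]][0].shape[-2:]
    rng = np.random.default_rng(train_cfg.seed)
    model = CoughClassifier(model_cfg, rng=int(rng.integers(2**31 - 1)),
                            frame_shape=frame_shape)
    optim = Adam(model.parameters(), lr=train_cfg.learning_rate,
                 betas=train_cfg.adam_betas,
                 weight_decay=train_cfg.weight_decay)

    val_labels = np.array([dataset[i][1] for i in fold.val_ids], dtype=int)
    best_f1, best_epoch, best_state = -1.0, -1, None
    val_history, loss_history = [], []

    steps_per_epoch = -(-len(fold.train_ids) // train_cfg.batch_size)
    total_steps = steps_per_epoch * train_cfg.epochs
    warmup = max(1, total_steps // 10)
    step = 0

    for epoch in range(train_cfg.epochs):
        order = list(rng.permutation(fold.train_ids))
        epoch_loss, n_seen = 0.0, 0
        for chunk in _batches(order, train_cfg.batch_size):
            if train_cfg.lr_schedule == "warmup_cosine":
                if step < warmup:
                    optim.lr = train_cfg.learning_rate * (step + 1) / warmup
                else:
                    frac = (step - warmup) / max(1, total_steps - warmup)
                    optim.lr = train_cfg.learning_rate * 0.5 * (
                        1 + np.cos(np.pi * frac))
            step += 1
            x, y = _stack(dataset, chunk,
                          augment_cfg=augment_cfg, rng=rng)
            logits = model.forward(x)
            loss, dlogits, _ = softmax_cross_entropy(logits, y)
            model.zero_grad()
            model.backward(dlogits)
            if train_cfg.max_grad_norm is not None:
                total = np.sqrt(sum(float((p.grad ** 2).sum())
                                    for p in model.parameters()))
                if total > train_cfg.max_grad_norm:
                    scale = train_cfg.max_grad_norm / (total + 1e-12)
                    for p in model.parameters():
                        p.grad *= scale
            optim.step()
            epoch_loss += loss * len(chunk)
            n_seen += len(chunk)
        loss_history.append(epoch_loss / n_seen)

        val_probs = _predict_proba(model, dataset, fold.val_ids,
                                   train_cfg.batch_size)
        val_f1 = _f1_at_half(val_labels, val_probs)
        val_history.append(val_f1)
        if val_f1 >= best_f1:  # ties -> later epoch
            best_f1, best_epoch = val_f1, epoch
            best_state = model.state_dict()
        if verbose:
            print(f"  epoch {epoch + 1}/{train_cfg.epochs}: "
                  f"loss {loss_history[-1]:.4f}  val F1 {val_f1:.3f}")

    model.load_state_dict(best_state)
    test_labels = np.array([dataset[i][1] for i in fold.test_ids], dtype=int)
    test_probs = _predict_proba(model, dataset, fold.test_ids,
                                train_cfg.batch_size)
    report = compute_metrics(test_labels, (test_probs >= 0.5).astype(int),
                             test_probs)
    return model, FoldResult(report=report, best_epoch=best_epoch,
                             val_f1_history=val_history,
                             train_loss_history=loss_history)


METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f1",
                "brier", "auc")


def summarize_folds(reports: list[MetricsReport]) -> dict:
    """Per-metric mean and sample std across folds."""
    summary = {}
    for name in METRIC_NAMES:
        mean, std = aggregate_fold_metric([getattr(r, name) for r in reports])
        summary[name] = {"mean": mean, "std": std}
    return summary


def cross_validate(manifest: DatasetManifest, dataset: dict,
                   model_cfg: ModelConfig | None = None,
                   train_cfg: TrainConfig | None = None,
                   augment_cfg: AugmentationConfig | None = None,
                   k: int = 5, n_test: int = 3,
                   rng: np.random.Generator | int = 0,
                   verbose: bool = False) -> dict:
    """Run the full k-fold protocol and aggregate per-fold metrics.

    Returns ``{"folds": [per-fold metric dicts], "summary": {metric:
    {mean, std}}, "plan": FoldPlan}``.
    """
    plan = make_folds(manifest.subjects(), manifest, k=k, n_test=n_test,
                      rng=rng)
    reports, results = [], []
    for i, fold in enumerate(plan.folds):
        if verbose:
            print(f"fold {i + 1}/{k}: test subjects {fold.test_subjects}")
        _, result = train_one_fold(fold, dataset, model_cfg, train_cfg,
                                   augment_cfg, manifest=manifest,
                                   verbose=verbose)
        reports.append(result.report)
        results.append(result)
    return {
        "folds": [r.to_dict() for r in reports],
        "summary": summarize_folds(reports),
        "plan": plan,
        "results": results,
    }
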