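"""Donor-disjoint evaluation: splits, cross-validated training, metrics.

Cells from one donor are correlated (shared donor-level biology and imaging
conditions), so clips are partitioned at the donor level: a greedy balancer
assigns whole donors to k = 5 splits of approximately equal cell count, one
split is held out as the test set and the remaining four are
cross-validation folds. Each fold's model trains on three splits with SGD
(momentum 0.9, batch 8, cross-entropy, cosine warm-restart schedule),
validates on the fourth every second epoch, and early-stops when validation
macro sensitivity stagnates.

The metric suite reports AUC, macro sensitivity (unweighted mean of
per-class recalls), accuracy, precision and F1, each with a Wald
normal-approximation 95% CI, plus a fold-averaged confusion matrix and
per-donor accuracies. The ramping experiment retrains on nested fractions
of the training data to trace test sensitivity versus dataset size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .slowfast import (SGD, SlowFastConfig, SlowFastModel, build_model,
                       softmax_cross_entropy)

__all__ = [
    "SplitAssignment",
    "ClipDataset",
    "TrainConfig",
    "MetricsReport",
    "AccuracyTable",
    "make_splits",
    "train_model",
    "run_cv",
    "compute_metrics",
    "per_donor_accuracy",
    "run_ramping",
]

CLASS_TO_INDEX = {"adult": 0, "fetal": 1}
INDEX_TO_CLASS = {v: k for k, v in CLASS_TO_INDEX.items()}


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

@dataclass
class SplitAssignment:
    """Donor-level partition into k splits, one designated as test."""

    assignment: dict            # donor_id -> split index in {0..k-1}
    k: int
    test_split: int

    def donors_in(self, split: int) -> list:
        return sorted(d for d, s in self.assignment.items() if s == split)

    @property
    def cv_splits(self) -> list[int]:
        return [s for s in range(self.k) if s != self.test_split]

    def summary(self, manifest: pd.DataFrame) -> pd.DataFrame:
        m = manifest.set_index("donor_id")
        rows = []
        for s in range(self.k):
            donors = self.donors_in(s)
            sub = m.loc[donors]
            rows.append({
                "split": s,
                "role": "test" if s == self.test_split else "cv",
                "n_donors": len(donors),
                "n_cells": int(sub["n_cells"].sum()),
                "n_cells_fetal": int(sub.loc[sub.class_label == "fetal", "n_cells"].sum()),
                "n_cells_adult": int(sub.loc[sub.class_label == "adult", "n_cells"].sum()),
            })
        return pd.DataFrame(rows)


def make_splits(manifest: pd.DataFrame, k: int = 5, seed: int = 0,
                test_split: int | None = None,
                stratify: bool = False) -> SplitAssignment:
    """Greedy donor-level balancing into k splits of similar cell count.

    Donors are shuffled (seeded, which orders ties), stably sorted by
    descending cell count, and each assigned to the currently smallest
    split. Every donor lands in exactly one split. With ``stratify=True``
    the greedy pass runs within each class separately (balancing per-class
    cell totals), so every split holds donors of both classes, as in the
    reference allocation; useful for small cohorts where an unstratified
    split can leave a single-class test set.
    """
    donors = list(manifest[["donor_id", "n_cells", "class_label"]]
                  .itertuples(index=False))
    if len(donors) < k:
        raise ValueError(f"need at least k={k} donors, got {len(donors)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(donors))
    donors = [donors[i] for i in order]
    donors.sort(key=lambda d: -d.n_cells)   # stable: seeded order breaks ties
    assignment = {}
    groups = ([donors] if not stratify else
              [[d for d in donors if d.class_label == c]
               for c in sorted({d.class_label for d in donors})])
    for group in groups:
        totals = [0] * k
        offset = rng.integers(k) if stratify else 0
        for d in group:
            s = min(range(k), key=lambda i: (totals[(i + offset) % k], i))
            s = (s + offset) % k
            assignment[d.donor_id] = s
            totals[s] += d.n_cells
    if test_split is None:
        occupied = {s for s in assignment.values()}
        test_split = max(occupied)      # last non-empty split
    return SplitAssignment(assignment=assignment, k=k, test_split=test_split)


# ---------------------------------------------------------------------------
# Clip dataset
# ---------------------------------------------------------------------------

@dataclass
class ClipDataset:
    """Batched clip arrays with labels and donor ids."""

    clips: np.ndarray           # (n, T, H, W) uint8
    labels: np.ndarray          # (n,) int, 0 = adult, 1 = fetal
    donor_ids: np.ndarray       # (n,) object

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_clips(cls, clips) -> "ClipDataset":
        return cls(
            clips=np.stack([c.pixels for c in clips]),
            labels=np.array([CLASS_TO_INDEX[c.class_label] for c in clips]),
            donor_ids=np.array([c.donor_id for c in clips], dtype=object),
        )

    def subset(self, mask) -> "ClipDataset":
        return ClipDataset(self.clips[mask], self.labels[mask],
                           self.donor_ids[mask])

    def donors_subset(self, donor_ids) -> "ClipDataset":
        wanted = set(donor_ids)
        mask = np.array([d in wanted for d in self.donor_ids])
        return self.subset(mask)

    def save(self, path) -> None:
        np.savez_compressed(path, clips=self.clips, labels=self.labels,
                            donor_ids=self.donor_ids.astype(str))

    @classmethod
    def load(cls, path) -> "ClipDataset":
        with np.load(path, allow_pickle=False) as d:
            return cls(clips=d["clips"], labels=d["labels"],
                       donor_ids=d["donor_ids"].astype(object))


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimisation settings: SGD momentum 0.9, batch 8, cross-entropy,
    cosine warm restarts, validation every 2 epochs, early stopping."""

    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0
    batch_size: int = 8
    max_epochs: int = 250
    eval_every: int = 2
    patience: int = 10          # evaluations without improvement before stop
    restart_period: int = 10    # first cosine warm-restart period, in epochs
    restart_mult: int = 2
    lr_min: float = 1e-4
    jitter_px: int = 4          # train-time random spatial jitter
    temporal_jitter: int = 4    # train-time random leading-frame drop
    horizontal_flip: bool = False  # flow direction is physically meaningful
    vertical_flip: bool = True     # channel is mirror-symmetric across flow
    # intensity jitter is available but off by default: gain jitter injects
    # noise directly into the integrated-contrast size cue
    intensity_gain: float = 0.0    # random gain in [1-g, 1+g]
    intensity_offset: float = 0.0  # random offset in [-o, o] intensity units
    zoom: float = 0.0              # random spatial scale in [1-z, 1+z]
    # mixup interpolates clip pairs with soft labels; with only a handful
    # of donors per class it fills the space between donor exemplars and
    # stops the network carving islands around them
    mixup_alpha: float = 0.0       # Beta(a, a) mixing; 0 disables
    # stochastic weight averaging: average parameters over the evaluation
    # points after swa_start_frac of max_epochs, then refresh batch-norm
    # statistics; flattens the checkpoint-to-checkpoint boundary wobble
    swa: bool = False
    swa_start_frac: float = 0.5


def cosine_warm_restart_lr(epoch: int, cfg: TrainConfig) -> float:
    """Learning rate at an epoch under cosine annealing with warm restarts."""
    period, start = cfg.restart_period, 0
    while epoch >= start + period:
        start += period
        period *= cfg.restart_mult
    t = (epoch - start) / period
    return cfg.lr_min + 0.5 * (cfg.lr - cfg.lr_min) * (1 + math.cos(math.pi * t))


def _augment(batch: np.ndarray, rng, cfg: TrainConfig) -> np.ndarray:
    out = batch
    if cfg.temporal_jitter > 0:
        k = rng.integers(0, cfg.temporal_jitter + 1)
        if k:
            out = np.concatenate(
                [out[:, k:], np.repeat(out[:, -1:], k, axis=1)], axis=1)
    if cfg.jitter_px > 0:
        j = cfg.jitter_px
        dr = int(rng.integers(-j, j + 1))
        dc = int(rng.integers(-j, j + 1))
        if dr or dc:
            # edge-replicated shift: keeps the border statistics of the
            # training clips identical to unshifted evaluation clips
            H, W = out.shape[2:]
            padded = np.pad(out, ((0, 0), (0, 0), (j, j), (j, j)),
                            mode="edge")
            out = padded[:, :, j - dr:j - dr + H, j - dc:j - dc + W]
    if cfg.zoom > 0:
        # scale jitter: breaks memorisation of the few discrete donor sizes
        # seen in training and pushes the model toward scale-invariant
        # shape features (the deformation contrast survives zooming)
        from scipy.ndimage import zoom as _ndzoom

        z = 1.0 + rng.uniform(-cfg.zoom, cfg.zoom)
        H, W = out.shape[2:]
        zoomed = _ndzoom(out.astype(np.float32), (1, 1, z, z), order=1)
        h, w = zoomed.shape[2:]
        if h >= H:
            r0, c0 = (h - H) // 2, (w - W) // 2
            out = zoomed[:, :, r0:r0 + H, c0:c0 + W]
        else:
            pr, pc = H - h, W - w
            out = np.pad(zoomed,
                         ((0, 0), (0, 0),
                          (pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2)),
                         mode="edge")
        out = np.clip(out, 0, 255).astype(np.uint8)
    if cfg.horizontal_flip and rng.random() < 0.5:
        out = out[:, :, :, ::-1]
    if cfg.vertical_flip and rng.random() < 0.5:
        out = out[:, :, ::-1, :]
    if cfg.intensity_gain > 0 or cfg.intensity_offset > 0:
        # donor recordings differ in incidental intensity statistics;
        # jittering gain/offset stops the model keying on them
        a = 1.0 + rng.uniform(-cfg.intensity_gain, cfg.intensity_gain)
        b = rng.uniform(-cfg.intensity_offset, cfg.intensity_offset)
        out = np.clip(out.astype(np.float32) * a + b, 0, 255).astype(np.uint8)
    return out


def macro_sensitivity(labels, predicted) -> float:
    """Unweighted mean of per-class recalls."""
    recalls = []
    for c in np.unique(labels):
        m = labels == c
        recalls.append(float(np.mean(predicted[m] == c)))
    return float(np.mean(recalls))


def train_model(
    model: SlowFastModel,
    train_data: ClipDataset,
    val_data: ClipDataset | None,
    cfg: TrainConfig,
    seed: int = 0,
    verbose: bool = False,
) -> dict:
    """Train with SGD + warm restarts and early stopping on validation
    macro sensitivity, evaluated every ``cfg.eval_every`` epochs.

    Returns a history dict with per-epoch losses, validation points
    (epoch, macro sensitivity), and the stopping epoch. The model is left
    at the parameters of its best validation evaluation.

    Raises ``RuntimeError`` if the loss becomes non-finite (diverged fold).
    """
    if len(train_data) == 0:
        raise ValueError("empty training set")
    if val_data is not None and len(val_data) == 0:
        raise ValueError("empty validation set; check the split assignment")
    rng = np.random.default_rng(seed)
    opt = SGD(model.params(), lr=cfg.lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    history = {"epoch_loss": [], "val_points": [], "stopped_epoch": None}
    best = (-np.inf, None)
    stale = 0
    n = len(train_data)
    swa_sum, swa_count = None, 0
    swa_from = int(cfg.swa_start_frac * cfg.max_epochs)
    for epoch in range(cfg.max_epochs):
        opt.lr = cosine_warm_restart_lr(epoch, cfg)
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            batch = _augment(train_data.clips[idx], rng, cfg)
            targets = train_data.labels[idx]
            if cfg.mixup_alpha > 0 and len(idx) > 1:
                lam = float(rng.beta(cfg.mixup_alpha, cfg.mixup_alpha))
                perm = rng.permutation(len(idx))
                batch = (lam * batch.astype(np.float32)
                         + (1 - lam) * batch[perm].astype(np.float32))
                onehot = np.eye(2, dtype=np.float32)[targets]
                targets = lam * onehot + (1 - lam) * onehot[perm]
            logits = model.forward(batch, train=True)
            loss, dlogits = softmax_cross_entropy(logits, targets)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: non-finite loss")
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history["epoch_loss"].append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch}: loss {history['epoch_loss'][-1]:.4f} "
                  f"lr {opt.lr:.4f}")
        if cfg.swa and epoch + 1 >= swa_from and (epoch + 1) % cfg.eval_every == 0:
            values = [p.value for p in model.params()]
            if swa_sum is None:
                swa_sum = [v.copy() for v in values]
            else:
                for s, v in zip(swa_sum, values):
                    s += v
            swa_count += 1
        if val_data is not None and (epoch + 1) % cfg.eval_every == 0:
            probs = model.predict_proba(val_data.clips)
            sens = macro_sensitivity(val_data.labels, probs.argmax(axis=1))
            history["val_points"].append((epoch + 1, sens))
            if sens > best[0]:
                best = (sens, [p.value.copy() for p in model.params()])
                stale = 0
            else:
                stale += 1
            if stale >= cfg.patience:
                history["stopped_epoch"] = epoch + 1
                break
    if cfg.swa and swa_count > 0:
        for p, s in zip(model.params(), swa_sum):
            p.value[...] = s / swa_count
        # refresh batch-norm running statistics under the averaged weights
        order = rng.permutation(n)
        for i in range(0, n, cfg.batch_size):
            model.forward(train_data.clips[order[i:i + cfg.batch_size]],
                          train=True)
        model._cache = None
        history["swa_checkpoints"] = swa_count
    elif best[1] is not None:
        for p, v in zip(model.params(), best[1]):
            p.value[...] = v
    history["best_val_sensitivity"] = best[0] if np.isfinite(best[0]) else None
    return history


def run_cv(
    dataset: ClipDataset,
    splits: SplitAssignment,
    model_cfg: SlowFastConfig,
    train_cfg: TrainConfig,
    seed: int = 0,
) -> tuple[list[SlowFastModel], list[dict]]:
    """4-fold donor-disjoint cross-validation.

    Each fold trains on three of the non-test splits and validates on the
    fourth; the test split never enters training. Returns the fold models
    and their training histories.
    """
    models, histories = [], []
    for fold, val_split in enumerate(splits.cv_splits):
        train_splits = [s for s in splits.cv_splits if s != val_split]
        train_donors = [d for s in train_splits for d in splits.donors_in(s)]
        val_donors = splits.donors_in(val_split)
        model = build_model(model_cfg, seed=seed + 101 * fold)
        hist = train_model(
            model,
            dataset.donors_subset(train_donors),
            dataset.donors_subset(val_donors),
            train_cfg,
            seed=seed + 101 * fold + 1,
        )
        hist["fold"] = fold
        hist["val_split"] = val_split
        models.append(model)
        histories.append(hist)
    return models, histories


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _wald_ci(p: float, n: int) -> float:
    """Half-width of a 95% normal-approximation CI for a proportion."""
    return 1.96 * math.sqrt(max(p * (1 - p), 0.0) / n) if n else float("nan")


def _auc_ci(auc: float, n_pos: int, n_neg: int) -> float:
    """95% CI half-width for AUC via the Hanley–McNeil variance."""
    if n_pos == 0 or n_neg == 0 or not np.isfinite(auc):
        return float("nan")
    q1 = auc / (2 - auc)
    q2 = 2 * auc ** 2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc ** 2)
           + (n_neg - 1) * (q2 - auc ** 2)) / (n_pos * n_neg)
    return 1.96 * math.sqrt(max(var, 0.0))


@dataclass
class MetricsReport:
    """Summary metrics (in %) with 95% CI half-widths.

    ``sensitivity`` is macro-averaged (unweighted mean of per-class
    recalls); ``precision`` and ``f1`` are for the fetal (positive) class.
    The confusion matrix has rows = true (adult, fetal), columns =
    predicted, in counts (fold-averaged counts when aggregating folds).
    """

    auc: float
    auc_ci: float
    sensitivity: float
    sensitivity_ci: float
    accuracy: float
    accuracy_ci: float
    precision: float
    precision_ci: float
    f1: float
    f1_ci: float
    per_class_recall: dict
    confusion: np.ndarray
    n: float
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("auc", "auc_ci", "sensitivity", "sensitivity_ci", "accuracy",
              "accuracy_ci", "precision", "precision_ci", "f1", "f1_ci", "n")}
        d["per_class_recall"] = self.per_class_recall
        d["confusion"] = self.confusion.tolist()
        return d


def _confusion(labels, predicted, k=2) -> np.ndarray:
    cm = np.zeros((k, k), dtype=float)
    for t, p in zip(labels, predicted):
        cm[t, p] += 1
    return cm


def compute_metrics(scores, labels) -> MetricsReport:
    """Metric suite for one evaluation: AUC, macro sensitivity, accuracy,
    precision, F1 (fetal positive), each with a Wald 95% CI, plus the
    confusion matrix.

    ``scores`` is (n, 2) class probabilities; AUC uses the fetal-class
    score ranking. With a single-class label vector the AUC is undefined
    and reported as NaN with a note.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    predicted = scores.argmax(axis=1)
    cm = _confusion(labels, predicted)
    notes = []
    if len(np.unique(labels)) < 2:
        auc = float("nan")
        notes.append("AUC undefined: single-class label vector")
    else:
        auc = float(roc_auc_score(labels, scores[:, 1]))
    acc = float(np.trace(cm) / n)
    recalls = {
        INDEX_TO_CLASS[c]: (float(cm[c, c] / cm[c].sum()) if cm[c].sum() else
                            float("nan"))
        for c in range(2)
    }
    sens = float(np.nanmean(list(recalls.values())))
    tp, fp = cm[1, 1], cm[0, 1]
    prec = float(tp / (tp + fp)) if (tp + fp) else float("nan")
    rec_pos = recalls["fetal"]
    f1 = (2 * prec * rec_pos / (prec + rec_pos)
          if np.isfinite(prec) and np.isfinite(rec_pos) and (prec + rec_pos)
          else float("nan"))
    n_pos = int((labels == 1).sum())
    n_neg = n - n_pos
    return MetricsReport(
        auc=100 * auc, auc_ci=100 * _auc_ci(auc, n_pos, n_neg),
        sensitivity=100 * sens, sensitivity_ci=100 * _wald_ci(sens, n),
        accuracy=100 * acc, accuracy_ci=100 * _wald_ci(acc, n),
        precision=100 * prec, precision_ci=100 * _wald_ci(prec, n),
        f1=100 * f1, f1_ci=100 * _wald_ci(f1, n),
        per_class_recall={k: 100 * v for k, v in recalls.items()},
        confusion=cm, n=float(n), notes=notes,
    )


def fold_mean_metrics(fold_reports: list[MetricsReport]) -> MetricsReport:
    """Average fold-level metrics and confusion matrices entry-wise."""
    def m(attr):
        return float(np.nanmean([getattr(r, attr) for r in fold_reports]))

    return MetricsReport(
        auc=m("auc"), auc_ci=m("auc_ci"),
        sensitivity=m("sensitivity"), sensitivity_ci=m("sensitivity_ci"),
        accuracy=m("accuracy"), accuracy_ci=m("accuracy_ci"),
        precision=m("precision"), precision_ci=m("precision_ci"),
        f1=m("f1"), f1_ci=m("f1_ci"),
        per_class_recall={
            k: float(np.nanmean([r.per_class_recall[k] for r in fold_reports]))
            for k in fold_reports[0].per_class_recall},
        confusion=np.mean([r.confusion for r in fold_reports], axis=0),
        n=float(np.mean([r.n for r in fold_reports])),
        notes=[x for r in fold_reports for x in r.notes],
    )


# ---------------------------------------------------------------------------
# Per-donor accuracy
# ---------------------------------------------------------------------------

@dataclass
class AccuracyTable:
    """Per-donor per-fold accuracy grid A_{d,f} with donor class labels."""

    grid: np.ndarray            # (n_donors, n_folds) in [0, 1]
    donor_ids: list
    donor_classes: list
    n_folds: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.grid, index=self.donor_ids,
                          columns=[f"fold{f + 1}" for f in range(self.n_folds)])
        df.insert(0, "class_label", self.donor_classes)
        return df


def per_donor_accuracy(fold_scores, labels, donor_ids) -> tuple[AccuracyTable, pd.DataFrame]:
    """Accuracy per donor under each fold model, plus the class summary.

    ``fold_scores`` is a list of (n, 2) score arrays, one per fold, over
    the same clips. The summary reports lowest / mean / highest of the
    donor-averaged accuracies per class, weighting donors equally (a donor
    with few cells counts as much as one with many). Donors with zero
    clips are excluded.
    """
    labels = np.asarray(labels)
    donor_ids = np.asarray(donor_ids, dtype=object)
    donors = sorted(set(donor_ids))
    grid = np.zeros((len(donors), len(fold_scores)))
    classes = []
    for di, d in enumerate(donors):
        m = donor_ids == d
        classes.append(INDEX_TO_CLASS[int(labels[m][0])])
        for f, scores in enumerate(fold_scores):
            pred = np.asarray(scores).argmax(axis=1)[m]
            grid[di, f] = float(np.mean(pred == labels[m]))
    table = AccuracyTable(grid=grid, donor_ids=donors, donor_classes=classes,
                          n_folds=len(fold_scores))
    donor_avg = grid.mean(axis=1)
    rows = []
    for cls in ("adult", "fetal"):
        vals = donor_avg[[c == cls for c in classes]]
        if len(vals):
            rows.append({"class_label": cls, "lowest": float(vals.min()),
                         "mean": float(vals.mean()),
                         "highest": float(vals.max()),
                         "n_donors": int(len(vals))})
    return table, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ramping
# ---------------------------------------------------------------------------

def run_ramping(
    dataset: ClipDataset,
    splits: SplitAssignment,
    model_cfg: SlowFastConfig,
    train_cfg: TrainConfig,
    fractions=tuple((i + 1) / 10 for i in range(10)),
    seed: int = 0,
    val_fraction: float = 0.10,
) -> pd.DataFrame:
    """Test sensitivity as a function of training-set size.

    The test split is held out; ``val_fraction`` of the *total* data is
    allocated (donor-disjointly, from the non-test donors) as a validation
    set for early stopping; one model per fraction is then trained on that
    fraction of the remaining training clips and evaluated on the test
    split with macro sensitivity. Fractions of the total data are also
    reported: with a 20% test split and 10% validation allocation, the
    100% point corresponds to about 70% of all data. Fractions whose
    subsample holds a single class are skipped with a note.
    """
    rng = np.random.default_rng(seed)
    test_donors = splits.donors_in(splits.test_split)
    pool_donors = [d for s in splits.cv_splits for d in splits.donors_in(s)]
    test_data = dataset.donors_subset(test_donors)

    # donor-disjoint validation allocation by greedy cell count
    counts = {d: int(np.sum(dataset.donor_ids == d)) for d in pool_donors}
    order = list(rng.permutation(pool_donors))
    target = val_fraction * len(dataset)
    val_donors, acc = [], 0
    for d in order:
        if acc >= target:
            break
        val_donors.append(d)
        acc += counts[d]
    train_donors = [d for d in pool_donors if d not in set(val_donors)]
    val_data = dataset.donors_subset(val_donors)
    train_pool = dataset.donors_subset(train_donors)

    pool_frac_of_total = len(train_pool) / len(dataset)
    rows = []
    for fi, frac in enumerate(fractions):
        n_take = max(1, int(round(frac * len(train_pool))))
        idx = np.sort(rng.permutation(len(train_pool))[:n_take])
        sub = train_pool.subset(idx)
        if len(np.unique(sub.labels)) < 2:
            rows.append({"fraction_of_training": frac,
                         "fraction_of_total": frac * pool_frac_of_total,
                         "n_clips": len(sub), "macro_sensitivity": float("nan"),
                         "note": "skipped: single-class subsample"})
            continue
        model = build_model(model_cfg, seed=seed + 17 * fi)
        train_model(model, sub, val_data, train_cfg, seed=seed + 17 * fi + 1)
        probs = model.predict_proba(test_data.clips)
        sens = macro_sensitivity(test_data.labels, probs.argmax(axis=1))
        rows.append({"fraction_of_training": frac,
                     "fraction_of_total": frac * pool_frac_of_total,
                     "n_clips": len(sub), "macro_sensitivity": sens,
                     "note": ""})
    return pd.DataFrame(rows)
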