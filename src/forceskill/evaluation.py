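"""Cross-validation, training and metrics for the skill-classification benchmark.

Two fold schemes are supported: a *random* six-fold split that deals each
surgeon's trials round-robin across folds (so every fold sees every
surgeon), and *leave-one-user-out* (LOUO), where each fold holds all trials
of one expert group and one novice — the test surgeons are never seen in
training, measuring generalization to unseen operators.

Training follows a fixed recipe: per epoch, each training trial contributes
one fresh random 300-step crop (zero-padded if shorter), optionally
augmented; binary cross-entropy (Expert = 1) is minimized with Adam; after
every epoch the cross-entropy on a stratified validation subset carved from
the training trials is computed, and the parameters with the minimum
validation loss are kept.  Test trials are evaluated at their original
length with no cropping or augmentation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .augmentation import apply_augmentation, AugmentationConfig
from .force_data import (Cohort, ForceTrace, TrialRecord, ScalerState,
                         clip_negatives, fit_scaler, apply_scaler, crop_or_pad,
                         EXPERT, NOVICE)
from .models import FittedModel, ModelSpec, build_model
from .nn import Adam
from .nn import autograd as ag

TrialKey = tuple[str, int]  # (surgeon_id, trial_index)


@dataclass
class FoldAssignment:
    n_folds: int
    fold_of_trial: dict[TrialKey, int]
    scheme: str  # "random" | "louo"

    def trials_in_fold(self, cohort: Cohort, fold: int) -> list[TrialRecord]:
        return [r for r in cohort.records
                if self.fold_of_trial[(r.surgeon_id, r.trial_index)] == fold]

    def trials_not_in_fold(self, cohort: Cohort, fold: int) -> list[TrialRecord]:
        return [r for r in cohort.records
                if self.fold_of_trial[(r.surgeon_id, r.trial_index)] != fold]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-4
    crop_len: int = 300
    val_fraction: float = 0.15
    seed: int = 0
    select_on_test: bool = False  # monitor the test fold instead of a held-out
    # validation subset; leaks the test fold into model selection, off by default
    scaler_scope: str = "pooled"  # "pooled" | "per_trial"

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.crop_len) < 1:
            raise ValueError("epochs, batch_size and crop_len must be positive")
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must be in (0, 1)")
        if self.scaler_scope not in ("pooled", "per_trial"):
            raise ValueError("scaler_scope must be 'pooled' or 'per_trial'")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


METRIC_NAMES = ("accuracy", "precision", "recall", "f1")


def compute_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, precision, recall and F1 from confusion counts.

    Metrics with an empty denominator are reported as None (undefined),
    never silently as zero.
    """
    if counts.total < 1:
        raise ValueError("need at least one evaluated trial")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    return {
        "accuracy": (tp + tn) / counts.total,
        "precision": tp / (tp + fp) if tp + fp > 0 else None,
        "recall": tp / (tp + fn) if tp + fn > 0 else None,
        "f1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else None,
    }


@dataclass
class MetricReport:
    """Per-fold metrics with cross-fold mean and sample standard deviation."""

    per_fold: list[dict[str, float | None]]
    mean: dict[str, float] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.mean:
            for name in METRIC_NAMES:
                vals = [m[name] for m in self.per_fold]
                defined = [v for v in vals if v is not None]
                if len(defined) < len(vals):
                    warnings.warn(
                        f"metric {name!r} undefined in "
                        f"{len(vals) - len(defined)} fold(s); mean/std skip them")
                self.mean[name] = float(np.mean(defined)) if defined else math.nan
                self.std[name] = (float(np.std(defined, ddof=1))
                                  if len(defined) > 1 else math.nan)


# ---------------------------------------------------------------------------
# fold construction
# ---------------------------------------------------------------------------

def random_split(cohort: Cohort, n_folds: int = 6, seed: int = 0) -> FoldAssignment:
    """Shuffle each surgeon's trials and deal them round-robin across folds.

    Per-surgeon fold counts differ by at most one, so every fold contains a
    near-equal number of trials from every surgeon.
    """
    rng = np.random.default_rng(seed)
    fold_of: dict[TrialKey, int] = {}
    for surgeon in cohort.surgeon_ids:
        trials = cohort.trials_of(surgeon)
        order = rng.permutation(len(trials))
        offset = int(rng.integers(n_folds))  # balance fold sizes across surgeons
        for pos, idx in enumerate(order):
            r = trials[idx]
            fold_of[(r.surgeon_id, r.trial_index)] = (offset + pos) % n_folds
    return FoldAssignment(n_folds=n_folds, fold_of_trial=fold_of, scheme="random")


def louo_split(cohort: Cohort, pairing: list[tuple] | None = None,
               merges: list[list[str]] | None = None) -> FoldAssignment:
    """Leave-one-user-out folds: each fold = one expert group + one novice.

    `merges` lists groups of expert surgeons whose trials travel together
    (needed when experts outnumber novices); after merging, the number of
    expert groups must equal the number of novices.  `pairing` optionally
    overrides the default roster-order pairing as a list of
    (expert_group, novice_id) pairs.
    """
    experts = [s.surgeon_id for s in cohort.roster if s.skill == EXPERT]
    novices = [s.surgeon_id for s in cohort.roster if s.skill == NOVICE]
    groups: list[tuple[str, ...]] = []
    merged: set[str] = set()
    for grp in merges or []:
        unknown = set(grp) - set(experts)
        if unknown:
            raise ValueError(f"merge group references non-expert surgeons: {sorted(unknown)}")
        groups.append(tuple(grp))
        merged.update(grp)
    groups.extend((e,) for e in experts if e not in merged)
    groups.sort(key=lambda g: experts.index(g[0]))
    if len(groups) != len(novices):
        raise ValueError(
            f"cannot pair {len(groups)} expert group(s) with {len(novices)} "
            f"novice(s); pass an explicit `merges` list of expert groups "
            f"(e.g. merge the two experts with the fewest trials)")
    pairs = pairing if pairing is not None else list(zip(groups, novices))
    fold_of: dict[TrialKey, int] = {}
    for k, (grp, novice) in enumerate(pairs):
        grp = (grp,) if isinstance(grp, str) else tuple(grp)
        for sid in grp + (novice,):
            for r in cohort.trials_of(sid):
                fold_of[(r.surgeon_id, r.trial_index)] = k
    if len(fold_of) != len(cohort.records):
        raise ValueError("pairing does not cover every surgeon in the roster")
    return FoldAssignment(n_folds=len(pairs), fold_of_trial=fold_of, scheme="louo")


def default_louo_merges(cohort: Cohort) -> list[list[str]] | None:
    """Merge the experts with the fewest trials until groups match novices."""
    experts = [(s.surgeon_id, s.n_trials) for s in cohort.roster if s.skill == EXPERT]
    n_novices = sum(1 for s in cohort.roster if s.skill == NOVICE)
    surplus = len(experts) - n_novices
    if surplus <= 0:
        return None
    fewest = sorted(experts, key=lambda t: (t[1], t[0]))[:surplus + 1]
    return [[sid for sid, _ in fewest]]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _preprocess(records: list[TrialRecord], scaler: ScalerState | None,
                scope: str) -> list[np.ndarray]:
    out = []
    for r in records:
        t = clip_negatives(r.trace)
        if scope == "per_trial":
            s = fit_scaler([t])
            out.append(apply_scaler(t, s).values)
        else:
            out.append(apply_scaler(t, scaler).values)
    return out


def _stratified_val_indices(labels: np.ndarray, frac: float,
                            rng: np.random.Generator) -> np.ndarray:
    val = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if idx.size == 0:
            continue
        n_val = max(1, int(round(frac * idx.size))) if idx.size > 1 else 0
        val.extend(rng.permutation(idx)[:n_val])
    return np.asarray(sorted(val), dtype=np.intp)


def _to_batch(seqs: list[np.ndarray], transform: str | None,
              aug: AugmentationConfig | None, rng: np.random.Generator):
    """Augment and stack equal-length 1-D crops into a (B, C, T) batch."""
    from .augmentation import rfft_stack
    arrs = []
    for v in seqs:
        if aug is not None and aug.name != "fft":
            v = apply_augmentation(aug.name, v, rng,
                                   apply_prob=aug.apply_prob, **aug.params)[0]
        if transform == "fft":
            arrs.append(rfft_stack(v))
        else:
            arrs.append(v[None, :])
    return np.stack(arrs).astype(np.float32)


def train_one_fold(cohort: Cohort, folds: FoldAssignment, test_fold: int,
                   spec: ModelSpec, cfg: TrainConfig,
                   augmentation: AugmentationConfig | None = None) -> FittedModel:
    """Train one model with `test_fold` held out; returns the parameters
    with minimum validation cross-entropy, with the training-fitted scaler
    attached."""
    test = folds.trials_in_fold(cohort, test_fold)
    train_all = folds.trials_not_in_fold(cohort, test_fold)
    if not test:
        raise ValueError(f"test fold {test_fold} is empty")
    labels = np.array([r.label for r in train_all])
    if len(set(labels.tolist())) < 2:
        raise ValueError("training folds contain a single class; cannot train")

    transform = "fft" if (augmentation is not None and augmentation.name == "fft") else None
    needed_channels = 3 if transform == "fft" else 1
    if spec.in_channels != needed_channels:
        spec = ModelSpec(arch=spec.arch, in_channels=needed_channels,
                         init_seed=spec.init_seed)

    aug_seed = augmentation.seed if augmentation is not None else 0
    ss = np.random.SeedSequence([cfg.seed, test_fold, aug_seed])
    rng_split, rng_crop, rng_aug = [np.random.default_rng(s) for s in ss.spawn(3)]

    # scaler fitted on training-fold trials only (never the test fold)
    scaler = None
    if cfg.scaler_scope == "pooled":
        scaler = fit_scaler([clip_negatives(r.trace) for r in train_all])
    train_seqs = _preprocess(train_all, scaler, cfg.scaler_scope)

    if cfg.select_on_test:
        fit_idx = np.arange(len(train_all))
        val_records, val_seqs = test, _preprocess(test, scaler, cfg.scaler_scope)
    else:
        val_idx = _stratified_val_indices(labels, cfg.val_fraction, rng_split)
        fit_idx = np.setdiff1d(np.arange(len(train_all)), val_idx)
        val_records = [train_all[i] for i in val_idx]
        val_seqs = [train_seqs[i] for i in val_idx]
    val_targets = np.array([[r.label] for r in val_records], dtype=np.float32)

    model = build_model(spec)
    model.scaler = scaler
    model.input_transform = transform
    opt = Adam(model.net.parameters(), lr=cfg.learning_rate)

    best_loss = np.inf
    best_state = model.net.get_state()
    for _epoch in range(cfg.epochs):
        order = rng_crop.permutation(fit_idx)
        for lo in range(0, order.size, cfg.batch_size):
            chunk = order[lo:lo + cfg.batch_size]
            crops, lengths, targets = [], [], []
            for i in chunk:
                tr = ForceTrace(train_seqs[i])
                crops.append(crop_or_pad(tr, cfg.crop_len, rng_crop).values)
                lengths.append(min(tr.T, cfg.crop_len))
                targets.append([train_all[i].label])
            batch = _to_batch(crops, transform, augmentation, rng_aug)
            logits = model.forward_logits(batch, lengths)
            loss = ag.bce_with_logits(logits, np.asarray(targets, dtype=np.float32))
            opt.zero_grad()
            loss.backward()
            opt.step()
        vloss = _validation_loss(model, val_seqs, val_targets)
        if vloss < best_loss:
            best_loss = vloss
            best_state = model.net.get_state()
    model.net.set_state(best_state)
    return model


def _validation_loss(model: FittedModel, seqs: list[np.ndarray],
                     targets: np.ndarray) -> float:
    """Mean BCE on full-length sequences in evaluation mode."""
    from .augmentation import rfft_stack
    model.net.eval()
    try:
        losses = []
        for v, t in zip(seqs, targets):
            x = rfft_stack(v) if model.input_transform == "fft" else v[None, :]
            logits = model.forward_logits(x[None].astype(np.float32))
            losses.append(float(ag.bce_with_logits(
                logits, np.asarray([t], dtype=np.float32)).data))
    finally:
        model.net.train()
    return float(np.mean(losses))


def evaluate_fold(model: FittedModel, test: list[TrialRecord]) -> ConfusionCounts:
    """Confusion counts on test trials at original length (Expert = positive).

    Prediction is Expert when the sigmoid output is >= 0.5.
    """
    from .augmentation import rfft_stack
    tp = tn = fp = fn = 0
    for r in test:
        seq = _preprocess([r], model.scaler,
                          "pooled" if model.scaler is not None else "per_trial")[0]
        x = rfft_stack(seq) if model.input_transform == "fft" else seq[None, :]
        prob = model.forward([x])[0]
        pred = 1 if prob >= 0.5 else 0
        if r.label == 1:
            tp, fn = (tp + 1, fn) if pred == 1 else (tp, fn + 1)
        else:
            tn, fp = (tn + 1, fp) if pred == 0 else (tn, fp + 1)
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


# ---------------------------------------------------------------------------
# benchmark driver
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkResult:
    arch: str
    scheme: str
    report: MetricReport
    per_fold_counts: list[ConfusionCounts]
    best_fold: int
    worst_fold: int


def run_benchmark(cohort: Cohort, archs: list[str], scheme: str,
                  cfg: TrainConfig,
                  augmentation: AugmentationConfig | None = None,
                  n_folds: int = 6,
                  louo_merges: list[list[str]] | None = None,
                  out_dir: str | Path | None = None) -> dict[str, BenchmarkResult]:
    """Run every fold of one CV scheme for each architecture.

    Returns per-architecture reports; optionally writes a JSON report and a
    CSV summary table (rows = method, columns = metric "mean ± std").
    """
    if scheme == "random":
        folds = random_split(cohort, n_folds=n_folds, seed=cfg.seed)
    elif scheme == "louo":
        merges = louo_merges if louo_merges is not None else default_louo_merges(cohort)
        folds = louo_split(cohort, merges=merges)
    else:
        raise ValueError("scheme must be 'random' or 'louo'")

    results: dict[str, BenchmarkResult] = {}
    for arch in archs:
        spec = ModelSpec(arch=arch, init_seed=cfg.seed)
        per_fold_counts, per_fold_metrics, fold_models = [], [], []
        for k in range(folds.n_folds):
            model = train_one_fold(cohort, folds, k, spec, cfg, augmentation)
            counts = evaluate_fold(model, folds.trials_in_fold(cohort, k))
            per_fold_counts.append(counts)
            per_fold_metrics.append(compute_metrics(counts))
            fold_models.append(model)
        report = MetricReport(per_fold=per_fold_metrics)
        accs = [m["accuracy"] for m in per_fold_metrics]
        best = int(np.argmax(accs))
        results[arch] = BenchmarkResult(
            arch=arch, scheme=scheme, report=report,
            per_fold_counts=per_fold_counts,
            best_fold=best, worst_fold=int(np.argmin(accs)))
        if out_dir is not None:
            from .models import save_checkpoint
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            save_checkpoint(fold_models[best], out / f"{arch}_best_fold{best}.npz")
    if out_dir is not None:
        write_report(results, out_dir)
    return results


def write_report(results: dict[str, BenchmarkResult], out_dir: str | Path):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blob = {}
    rows = []
    for arch, res in results.items():
        blob[arch] = {
            "scheme": res.scheme,
            "per_fold_counts": [vars(c) for c in res.per_fold_counts],
            "per_fold_metrics": res.report.per_fold,
            "mean": res.report.mean,
            "std": res.report.std,
            "best_fold": res.best_fold,
            "worst_fold": res.worst_fold,
        }
        row = {"method": arch}
        for m in METRIC_NAMES:
            mu, sd = res.report.mean[m], res.report.std[m]
            row[m] = f"{100 * mu:.2f} ± {100 * sd:.2f}" if np.isfinite(mu) else "undefined"
        rows.append(row)
    with open(out / "report.json", "w") as fh:
        json.dump(blob, fh, indent=1)
    pd.DataFrame(rows).to_csv(out / "summary.csv", index=False)
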