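"""Optimization loop, cross-validation orchestration and external-set
evaluation.

Training minimizes softmax cross-entropy with Adam (default learning
rate 0.01 over 250 epochs, dropout 0.5).  All randomness (shuffling,
dropout) derives from the config seed, so a run is reproducible on a
fixed device.  Case-level leakage between the train and evaluation side
of any split is a hard error, never a warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, LeakageError
from .evaluation import (
    MetricsReport,
    aggregate_folds,
    case_level_predict,
    compute_metrics,
    confusion_counts,
    make_folds,
    roc_auc,
)
from .nn import Adam, softmax_cross_entropy
from .network import ModelConfig, ScatInceptionNet, build_network
from .preprocessing import AugmentationConfig, SliceRecord, augment_dataset, extract_region
from .synthetic_mri import CaseRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "CrossvalResult",
    "train_model",
    "predict_slice_probs",
    "run_crossval",
    "evaluate_external",
]

LABEL_TO_INDEX = {"MET": 0, "GBM": 1}  # GBM logit = channel 1 (positive class)


@dataclass
class TrainConfig:
    epochs: int = 250
    learning_rate: float = 0.01
    optimizer: str = "adam"
    dropout_rate: float = 0.5
    batch_size: int = 16
    seed: int = 0
    region: str = "core"
    device: str = "cpu"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ConfigurationError("only the adam optimizer is supported")
        if self.region not in ("core", "edema", "overall"):
            raise ConfigurationError("region must be core, edema or overall")


@dataclass
class TrainHistory:
    """Per-epoch training loss and held-out slice accuracy."""

    losses: list[float] = field(default_factory=list)
    val_accuracies: list[float] = field(default_factory=list)


@dataclass
class CrossvalResult:
    fold_case_reports: list[MetricsReport]
    fold_slice_reports: list[MetricsReport]
    summary_case: dict
    summary_slice: dict
    histories: list[TrainHistory]
    fold_case_ids: list[list[str]]
    roc_points: list[pd.DataFrame]


def _check_disjoint(train_ids: set[str], eval_ids: set[str], context: str) -> None:
    overlap = train_ids & eval_ids
    if overlap:
        raise LeakageError(
            f"{context}: {len(overlap)} case id(s) on both sides, e.g. "
            f"{sorted(overlap)[:3]}"
        )


def _assemble_batch(records: list[SliceRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Stack slice records into a centered (N, 1, H, W) batch."""
    x = np.stack([r.image - r.pixel_mean for r in records]).astype(np.float32)
    y = np.array([LABEL_TO_INDEX[r.class_label] for r in records], dtype=np.int64)
    return x[:, None, :, :], y


def train_model(
    model: ScatInceptionNet,
    train_slices: list[SliceRecord],
    val_slices: list[SliceRecord] | None,
    cfg: TrainConfig,
) -> tuple[ScatInceptionNet, TrainHistory]:
    """Optimize the model on slice records; reproducible from cfg.seed."""
    if not train_slices:
        raise InputError("empty training set")
    train_ids = {r.case_id for r in train_slices}
    if val_slices:
        _check_disjoint(train_ids, {r.case_id for r in val_slices}, "train/val split")
    model.dropout.rate = cfg.dropout_rate
    model.reseed(cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    optimizer = Adam(model.params(), lr=cfg.learning_rate)
    x_all, y_all = _assemble_batch(train_slices)
    history = TrainHistory()
    n = len(train_slices)
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.forward(x_all[idx])
            loss, dlogits, _ = softmax_cross_entropy(logits, y_all[idx])
            model.zero_grad()
            model.backward(dlogits)
            optimizer.step()
            epoch_loss += loss * len(idx)
            logger.debug("epoch %d batch %d loss %.4f", epoch, start, loss)
        epoch_loss /= n
        history.losses.append(epoch_loss)
        if val_slices:
            probs = predict_slice_probs(model, val_slices)
            preds = ["GBM" if p >= 0.5 else "MET" for p in probs]
            acc = np.mean([p == r.class_label for p, r in zip(preds, val_slices)])
            history.val_accuracies.append(float(acc))
            logger.info(
                "epoch %d/%d loss %.4f val_acc %.3f", epoch + 1, cfg.epochs, epoch_loss, acc
            )
        else:
            history.val_accuracies.append(float("nan"))
            logger.info("epoch %d/%d loss %.4f", epoch + 1, cfg.epochs, epoch_loss)
    model.trained_case_ids |= train_ids
    return model, history


def predict_slice_probs(
    model: ScatInceptionNet, slices: list[SliceRecord], batch_size: int = 64
) -> np.ndarray:
    """Positive-class (GBM) probability per slice, in eval mode."""
    model.eval()
    x, _ = _assemble_batch(slices)
    probs = []
    for start in range(0, len(slices), batch_size):
        logits = model.forward(x[start : start + batch_size])
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs.append((ez / ez.sum(axis=1, keepdims=True))[:, LABEL_TO_INDEX["GBM"]])
    return np.concatenate(probs)


def _evaluate_cases(
    model: ScatInceptionNet, cases: list[CaseRecord], region: str, out_size: int
) -> tuple[MetricsReport, MetricsReport, pd.DataFrame]:
    """Slice- and case-level reports plus per-case scores for ROC."""
    slice_truth, slice_pred, slice_scores = [], [], []
    case_truth, case_pred, case_scores, case_ids = [], [], [], []
    for case in cases:
        records = extract_region(case, region, out_size=out_size)
        probs = predict_slice_probs(model, records)
        slice_truth += [case.class_label] * len(records)
        slice_pred += ["GBM" if p >= 0.5 else "MET" for p in probs]
        slice_scores += list(probs)
        case_truth.append(case.class_label)
        case_pred.append(case_level_predict(probs))
        case_scores.append(float(np.mean(probs)))
        case_ids.append(case.case_id)
    both = len(set(case_truth)) == 2
    slice_auc = roc_auc(slice_scores, slice_truth) if both else None
    case_auc = roc_auc(case_scores, case_truth) if both else None
    slice_report = compute_metrics(
        confusion_counts(slice_truth, slice_pred), auc=slice_auc, level="slice"
    )
    case_report = compute_metrics(
        confusion_counts(case_truth, case_pred), auc=case_auc, level="case"
    )
    scores = pd.DataFrame(
        {"case_id": case_ids, "class_label": case_truth, "score": case_scores}
    )
    return case_report, slice_report, scores


def run_crossval(
    cases: list[CaseRecord],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    k: int = 5,
    augment_cfg: AugmentationConfig | None = None,
    out_dir: Path | None = None,
) -> CrossvalResult:
    """Case-level k-fold cross-validation of the full pipeline.

    Each fold trains a freshly initialized model on the other k-1 folds
    (with augmentation applied to the training side only) and evaluates
    on the held-out fold at both slice and case granularity.
    """
    by_id = {c.case_id: c for c in cases}
    split = make_folds([(c.case_id, c.class_label) for c in cases], k=k, seed=train_cfg.seed)
    out_size = model_cfg.input_size[0]
    fold_case_reports, fold_slice_reports = [], []
    histories, roc_points = [], []
    for fold in range(k):
        train_ids, test_ids = split.train_test(fold)
        _check_disjoint(set(train_ids), set(test_ids), f"fold {fold}")
        train_slices: list[SliceRecord] = []
        for cid in train_ids:
            train_slices += extract_region(by_id[cid], train_cfg.region, out_size=out_size)
        if augment_cfg is not None:
            fold_aug = replace(augment_cfg, seed=augment_cfg.seed + fold)
            train_slices = augment_dataset(train_slices, fold_aug)
        model = build_network(replace(model_cfg, seed=model_cfg.seed + fold))
        fold_cfg = replace(train_cfg, seed=train_cfg.seed + fold)
        model, history = train_model(model, train_slices, None, fold_cfg)
        _check_disjoint(model.trained_case_ids, set(test_ids), f"fold {fold} eval")
        case_report, slice_report, scores = _evaluate_cases(
            model, [by_id[cid] for cid in test_ids], train_cfg.region, out_size
        )
        logger.info(
            "fold %d: case acc %.3f slice acc %.3f",
            fold,
            case_report.accuracy,
            slice_report.accuracy,
        )
        fold_case_reports.append(case_report)
        fold_slice_reports.append(slice_report)
        histories.append(history)
        roc_points.append(scores)
    result = CrossvalResult(
        fold_case_reports=fold_case_reports,
        fold_slice_reports=fold_slice_reports,
        summary_case=aggregate_folds(fold_case_reports),
        summary_slice=aggregate_folds(fold_slice_reports),
        histories=histories,
        fold_case_ids=split.folds,
        roc_points=roc_points,
    )
    if out_dir is not None:
        _write_results(result, model_cfg, train_cfg, Path(out_dir))
    return result


def _report_row(report: MetricsReport) -> dict:
    return {
        "level": report.level,
        "n": report.n,
        "accuracy": report.accuracy,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "auc": report.auc,
    }


def _write_results(
    result: CrossvalResult, model_cfg: ModelConfig, train_cfg: TrainConfig, out_dir: Path
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (cr, sr) in enumerate(
        zip(result.fold_case_reports, result.fold_slice_reports)
    ):
        rows.append({"fold": i, **_report_row(cr)})
        rows.append({"fold": i, **_report_row(sr)})
    pd.DataFrame(rows).to_csv(out_dir / "fold_metrics.csv", index=False)
    payload = {
        "config": {
            "model": {**asdict(model_cfg), "input_size": list(model_cfg.input_size)},
            "training": asdict(train_cfg),
        },
        "summary_case": result.summary_case,
        "summary_slice": result.summary_slice,
        "fold_case_ids": result.fold_case_ids,
        "histories": [
            {"losses": h.losses, "val_accuracies": h.val_accuracies}
            for h in result.histories
        ],
    }
    (out_dir / "results.json").write_text(json.dumps(payload, indent=2))
    pd.concat(
        [df.assign(fold=i) for i, df in enumerate(result.roc_points)],
        ignore_index=True,
    ).to_csv(out_dir / "roc_scores.csv", index=False)


def evaluate_external(
    model: ScatInceptionNet,
    external_cases: list[CaseRecord],
    region: str = "core",
) -> tuple[MetricsReport, MetricsReport]:
    """Evaluate a trained model on an external cohort (no updates).

    Returns ``(case_report, slice_report)``; ``case_report.n`` is the
    number of external cases.  Raises :class:`LeakageError` if any
    external case was seen during training.
    """
    if not external_cases:
        raise InputError("empty external cohort")
    _check_disjoint(
        model.trained_case_ids,
        {c.case_id for c in external_cases},
        "external evaluation",
    )
    out_size = model.cfg.input_size[0]
    case_report, slice_report, _ = _evaluate_cases(model, external_cases, region, out_size)
    return case_report, slice_report
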