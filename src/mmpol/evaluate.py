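"""Patient-grouped cross-validation, ROC/AUC and specimen-level scoring.

The evaluation protocol: pixels are split into k=4 folds patient-by-patient
(every sample of a patient lands in exactly one fold, so no patient appears
in both train and test), a fresh MLP is trained per fold, and pixel-level
ROC/AUC plus the confusion summary at a fixed probability threshold are
reported per fold and as mean +/- sd.  Specimen-level performance takes
the p-th percentile of a sample's pixel scores as that sample's prediction,
for every integer percentile from the 50th to the 99th; a specimen counts
as abnormal if any annotated pixel is abnormal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from sklearn import metrics as skmetrics
from sklearn.preprocessing import StandardScaler

from mmpol.classifier import PixelMLP, TrainConfig, _split_table, train

__all__ = [
    "EvalConfig",
    "EvalReport",
    "derive_seed",
    "patient_folds",
    "roc_auc",
    "confusion_at_threshold",
    "specimen_score",
    "specimen_label",
    "cross_validate",
]

logger = logging.getLogger(__name__)


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, fanned out from one global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation protocol parameters.

    ``threshold`` is the fixed decision boundary for the confusion summary
    (scores >= threshold predict abnormal); ``percentiles`` is the range of
    specimen-score percentiles reported.
    """

    k: int = 4
    threshold: float = 0.43
    percentiles: tuple[int, ...] = tuple(range(50, 100))
    percentile_method: str = "linear"  # or "nearest"
    standardize: bool = False
    seed: int = 0
    max_roc_points: int = 256

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if any(p < 50 or p > 99 for p in self.percentiles):
            raise ValueError("percentiles must lie in [50, 99]")
        if self.percentile_method not in ("linear", "nearest"):
            raise ValueError("percentile_method must be 'linear' or 'nearest'")


def patient_folds(patient_ids: ArrayLike, k: int, seed: int = 0) -> NDArray[np.int_]:
    """Assign each row to one of k folds, grouped by patient.

    Patients are shuffled by the seed and dealt round-robin, so fold
    patient-counts differ by at most one and every row of a patient shares
    a fold.
    """
    patient_ids = np.asarray(patient_ids)
    unique = np.unique(patient_ids)
    if k > unique.size:
        raise ValueError(f"k={k} folds requested but only {unique.size} patients available")
    rng = np.random.default_rng(seed)
    order = rng.permutation(unique.size)
    fold_of = {unique[p]: i % k for i, p in enumerate(order)}
    return np.array([fold_of[p] for p in patient_ids], dtype=int)


def roc_auc(scores: ArrayLike, labels: ArrayLike) -> tuple[NDArray[np.float64], float]:
    """ROC points (FPR, TPR) and AUC with abnormal (1) as positive class.

    The AUC equals the Mann-Whitney probability that a random abnormal
    pixel outscores a random normal one, ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, _ = skmetrics.roc_curve(labels, scores, pos_label=1)
    auc = float(skmetrics.roc_auc_score(labels, scores))
    return np.column_stack([fpr, tpr]), auc


def confusion_at_threshold(
    scores: ArrayLike, labels: ArrayLike, threshold: float
) -> dict[str, float]:
    """Sensitivity, specificity, FPR (type I) and FNR (type II) at a cut.

    A score >= threshold predicts abnormal.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present for a confusion summary")
    pred = scores >= threshold
    pos = labels == 1
    sensitivity = float(pred[pos].mean())
    specificity = float((~pred[~pos]).mean())
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "fpr": 1.0 - specificity,
        "fnr": 1.0 - sensitivity,
    }


def specimen_score(scores: ArrayLike, p: float, method: str = "linear") -> float:
    """p-th percentile of one sample's pixel scores (its specimen score)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot score a specimen with no valid pixels")
    if not 50 <= p <= 99:
        raise ValueError(f"percentile must lie in [50, 99], got {p}")
    return float(np.percentile(scores, p, method=method))


def specimen_label(label_mask: ArrayLike) -> int:
    """1 (abnormal) if any annotated pixel is abnormal, else 0 (normal)."""
    from mmpol.phantom import ABNORMAL, UNLABELED

    mask = np.asarray(label_mask)
    if not (mask != UNLABELED).any():
        raise ValueError("sample has no annotated pixels")
    return int((mask == ABNORMAL).any())


# ---------------------------------------------------------------------------
# report containers


@dataclass
class FoldResult:
    fold: int
    test_patients: list[str]
    n_train: int
    n_test: int
    auc: float
    confusion: dict[str, float]
    roc_points: list[list[float]]
    specimen_auc: dict[int, float | None]
    loss_curve: list[float]


@dataclass
class EvalReport:
    """Cross-validation results for one feature mode."""

    mode: str
    k: int
    threshold: float
    folds: list[FoldResult]
    mean_auc: float
    sd_auc: float
    pooled_auc: float
    pooled_roc_points: list[list[float]]
    specimen_auc_mean: dict[int, float | None]
    specimen_auc_sd: dict[int, float | None]
    train_config: dict
    eval_config: dict

    def fold_aucs(self) -> NDArray[np.float64]:
        return np.array([f.auc for f in self.folds])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "EvalReport":
        payload = json.loads(Path(path).read_text())
        folds = [
            FoldResult(**{**f, "specimen_auc": {int(k): v for k, v in f["specimen_auc"].items()}})
            for f in payload.pop("folds")
        ]
        payload["specimen_auc_mean"] = {
            int(k): v for k, v in payload["specimen_auc_mean"].items()
        }
        payload["specimen_auc_sd"] = {int(k): v for k, v in payload["specimen_auc_sd"].items()}
        return cls(folds=folds, **payload)

    def to_frame(self) -> pd.DataFrame:
        """Flat per-fold metric table (one row per fold x metric)."""
        rows = []
        for f in self.folds:
            rows.append({"fold": f.fold, "metric": "auc", "value": f.auc})
            for k, v in f.confusion.items():
                rows.append({"fold": f.fold, "metric": k, "value": v})
        return pd.DataFrame(rows)


def _downsample_roc(points: NDArray[np.float64], max_points: int) -> list[list[float]]:
    if len(points) <= max_points:
        return points.tolist()
    idx = np.unique(np.linspace(0, len(points) - 1, max_points).round().astype(int))
    return points[idx].tolist()


def _specimen_aucs(
    test: pd.DataFrame,
    scores: NDArray[np.float64],
    percentiles: tuple[int, ...],
    method: str,
) -> dict[int, float | None]:
    """Specimen-level AUC per percentile over the fold's test samples.

    A sample's truth is abnormal iff any of its annotated pixels is; folds
    whose test split holds a single specimen class yield None with a
    logged warning.
    """
    sample_keys = test["patient_id"].astype(str) + "/" + test["sample_id"].astype(str)
    out: dict[int, float | None] = {}
    groups = pd.DataFrame(
        {"key": sample_keys.to_numpy(), "label": test["label"].to_numpy(), "score": scores}
    ).groupby("key", sort=True)
    truths = groups["label"].max().to_numpy()
    if np.unique(truths).size < 2:
        logger.warning(
            "test fold holds a single specimen class; specimen AUC skipped"
        )
        return {int(p): None for p in percentiles}
    for p in percentiles:
        preds = groups["score"].apply(lambda s: specimen_score(s, p, method)).to_numpy()
        _, auc = roc_auc(preds, truths)
        out[int(p)] = auc
    return out


def cross_validate(
    table: pd.DataFrame,
    mode: str,
    train_config: TrainConfig | None = None,
    eval_config: EvalConfig | None = None,
) -> EvalReport:
    """Patient-wise k-fold cross-validation of the pixel MLP.

    ``table`` is a labeled feature table (see
    :func:`mmpol.features.build_feature_table`).  Per fold, the model is
    trained on the other k-1 folds' pixels with a fold-derived seed and
    scored on the held-out fold.  Fully deterministic given the configs.
    """
    train_config = train_config or TrainConfig()
    eval_config = eval_config or EvalConfig()
    patients = table["patient_id"].to_numpy()
    folds = patient_folds(patients, eval_config.k, eval_config.seed)

    fold_results: list[FoldResult] = []
    pooled_scores: list[NDArray] = []
    pooled_labels: list[NDArray] = []
    for f in range(eval_config.k):
        train_rows = table.loc[folds != f]
        test_rows = table.loc[folds == f]
        train_pat = set(train_rows["patient_id"])
        test_pat = set(test_rows["patient_id"])
        # grouped-CV leakage guard, asserted every run
        if train_pat & test_pat:
            raise AssertionError(f"patient leakage in fold {f}: {train_pat & test_pat}")
        cfg = dataclasses.replace(train_config, seed=derive_seed(train_config.seed, f"fold{f}"))
        X_train, y_train = _split_table(train_rows)
        X_test, y_test = _split_table(test_rows)
        if eval_config.standardize:
            scaler = StandardScaler().fit(X_train)
            X_train, X_test = scaler.transform(X_train), scaler.transform(X_test)
        model = PixelMLP(
            hidden_units=cfg.hidden_units,
            learning_rate=cfg.learning_rate,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            random_state=cfg.seed,
        ).fit(X_train, y_train)
        scores = model.predict_proba(X_test)[:, 1]
        points, auc = roc_auc(scores, y_test)
        confusion = confusion_at_threshold(scores, y_test, eval_config.threshold)
        specimen = _specimen_aucs(
            test_rows, scores, eval_config.percentiles, eval_config.percentile_method
        )
        fold_results.append(
            FoldResult(
                fold=f,
                test_patients=sorted(test_pat),
                n_train=len(train_rows),
                n_test=len(test_rows),
                auc=auc,
                confusion=confusion,
                roc_points=_downsample_roc(points, eval_config.max_roc_points),
                specimen_auc=specimen,
                loss_curve=list(model.loss_curve_),
            )
        )
        pooled_scores.append(scores)
        pooled_labels.append(y_test)

    aucs = np.array([fr.auc for fr in fold_results])
    pooled_points, pooled_auc = roc_auc(
        np.concatenate(pooled_scores), np.concatenate(pooled_labels)
    )
    spec_mean: dict[int, float | None] = {}
    spec_sd: dict[int, float | None] = {}
    for p in eval_config.percentiles:
        vals = [fr.specimen_auc[int(p)] for fr in fold_results if fr.specimen_auc[int(p)] is not None]
        spec_mean[int(p)] = float(np.mean(vals)) if vals else None
        spec_sd[int(p)] = float(np.std(vals)) if vals else None

    return EvalReport(
        mode=mode,
        k=eval_config.k,
        threshold=eval_config.threshold,
        folds=fold_results,
        mean_auc=float(aucs.mean()),
        sd_auc=float(aucs.std()),
        pooled_auc=pooled_auc,
        pooled_roc_points=_downsample_roc(pooled_points, eval_config.max_roc_points),
        specimen_auc_mean=spec_mean,
        specimen_auc_sd=spec_sd,
        train_config=asdict_config(train_config),
        eval_config=asdict_config(eval_config),
    )


def asdict_config(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
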