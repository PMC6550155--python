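"""Random-Forest diagnosis and the repeated-split evaluation protocol.

The protocol: k (default 25) independent stratified 70/30 splits — 70% of
each class trains, 30% tests — a Random Forest per repeat, and per-repeat
F1 (positive class = dysgraphic), sensitivity, specificity and false-positive
rate, summarized by their mean and standard deviation, plus Gini feature
importances averaged over the repeats.

Reference hygiene: the "distance to cohort mean" features depend on a cohort
reference spectrum. When evaluation receives a :class:`CohortFeatures` bundle
it rebuilds that reference — and the five distance columns — from each
repeat's *training* split only, so no test information leaks into the
features the forest sees.

Shape: :func:`train` produces a :class:`DiagnosisModel` (the fitted artifact,
with ``predict``); :func:`evaluate` produces an :class:`EvaluationReport`
(the results object, with per-repeat metrics, importances and ``summary()``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .dynamics_features import (DISTANCE_COLUMNS, FEATURE_NAMES, CohortFeatures,
                                CohortReference, FeatureVector, extract_cohort)
from .static_features import StaticConfig
from .dynamics_features import DynamicsConfig
from .trace_model import Recording, truncate

__all__ = [
    "CVConfig",
    "DiagnosisModel",
    "EvaluationReport",
    "f1_score",
    "train",
    "predict",
    "evaluate",
    "feature_importances",
    "robustness_curve",
]

logger = logging.getLogger(__name__)

POSITIVE = "D"
NEGATIVE = "TD"


class UndefinedMetricError(ValueError):
    """A metric is undefined (e.g. no positive ground-truth examples)."""


@dataclasses.dataclass(frozen=True)
class CVConfig:
    """Evaluation-protocol parameters.

    k              : number of repeated splits (or folds in k-fold mode).
    train_fraction : per-class share of data used for training.
    n_trees        : forest size.
    seed           : master seed; splits and forests derive from it.
    feature_subset : optional feature-name list (e.g. a simplified
        two-feature model); None = all features.
    threshold      : forest vote fraction above which the label is positive.
    mode           : "shuffle" = repeated stratified 70/30 splits (the
        protocol used for reporting a mean and std); "kfold" = plain
        stratified k-fold, exposed as an alternative reading.
    """

    k: int = 25
    train_fraction: float = 0.70
    n_trees: int = 100
    seed: int = 0
    feature_subset: tuple[str, ...] | None = None
    threshold: float = 0.5
    mode: str = "shuffle"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.mode not in ("shuffle", "kfold"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.feature_subset is not None:
            unknown = set(self.feature_subset) - set(FEATURE_NAMES)
            if unknown:
                raise ValueError(f"unknown features in subset: {sorted(unknown)}")

    def hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]


def f1_score(tp: int, fp: int, fn: int) -> float:
    """Harmonic mean of precision and recall from confusion counts.

    Precision is 0 when nothing was predicted positive; F1 is 0 when both
    precision and recall are 0. Raises when there is no positive truth at
    all (recall undefined).
    """
    if tp + fn == 0:
        raise UndefinedMetricError("no positive ground-truth examples: recall undefined")
    recall = tp / (tp + fn)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _clean_matrix(train_df: pd.DataFrame, test_df: pd.DataFrame | None,
                  cfg: CVConfig) -> tuple[pd.DataFrame, pd.DataFrame | None, dict]:
    """Select features, drop all-missing columns, drop incomplete rows."""
    cols = list(cfg.feature_subset) if cfg.feature_subset else list(train_df.columns)
    train_df = train_df[cols]
    dead = [c for c in cols if train_df[c].isna().all()]
    keep = [c for c in cols if c not in dead]
    train_df = train_df[keep]
    train_rows = train_df.dropna()
    info = {
        "dropped_columns": dead,
        "dropped_train_rows": len(train_df) - len(train_rows),
    }
    test_rows = None
    if test_df is not None:
        test_df = test_df[keep]
        test_rows = test_df.dropna()
        info["dropped_test_rows"] = len(test_df) - len(test_rows)
    for key in ("dropped_train_rows", "dropped_test_rows"):
        if info.get(key):
            logger.info("excluded %d row(s) with missing features (%s)", info[key], key)
    return train_rows, test_rows, info


@dataclasses.dataclass
class DiagnosisModel:
    """A trained diagnosis artifact.

    Bundles the forest, the exact feature-name order it expects, the cohort
    reference its distance features were computed against, and provenance
    (config hash, training-set fingerprint). ``predict`` refuses inputs whose
    feature names do not match.
    """

    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    reference: CohortReference | None
    config: CVConfig
    config_hash: str
    training_fingerprint: str

    def predict(self, fv: "FeatureVector | pd.Series | pd.DataFrame") -> dict:
        if isinstance(fv, FeatureVector):
            row = fv.to_series()
        elif isinstance(fv, pd.DataFrame):
            if len(fv) != 1:
                raise ValueError("predict takes a single recording's features")
            row = fv.iloc[0]
        else:
            row = fv
        missing = [c for c in self.feature_names if c not in row.index]
        if missing:
            raise ValueError(f"feature vector lacks required features: {missing}")
        vec = row[list(self.feature_names)].astype(float)
        if vec.isna().any():
            raise ValueError(
                f"missing values in required features: {list(vec.index[vec.isna()])}")
        proba = self.forest.predict_proba(vec.to_frame().T.to_numpy())[0]
        score = float(proba[list(self.forest.classes_).index(POSITIVE)])
        label = POSITIVE if score >= self.config.threshold else NEGATIVE
        return {"label": label, "score": score}

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "DiagnosisModel":
        return joblib.load(path)


def train(features: pd.DataFrame, labels: Sequence[str], cfg: CVConfig | None = None,
          reference: CohortReference | None = None) -> DiagnosisModel:
    """Fit a Random Forest on a feature table.

    Rows with missing required features are excluded (logged); training
    requires both classes to be present. Deterministic given the seed.
    """
    cfg = cfg or CVConfig()
    labels = pd.Series(list(labels), index=features.index)
    clean, _, _ = _clean_matrix(features, None, cfg)
    y = labels.loc[clean.index]
    if y.nunique() < 2:
        raise ValueError(f"training needs both classes; got only {sorted(y.unique())}")
    forest = RandomForestClassifier(n_estimators=cfg.n_trees, random_state=cfg.seed,
                                    n_jobs=1)
    forest.fit(clean.to_numpy(), y.to_numpy())
    fingerprint = hashlib.sha256(
        ("|".join(sorted(clean.index.astype(str)))).encode()).hexdigest()[:12]
    return DiagnosisModel(forest=forest, feature_names=tuple(clean.columns),
                          reference=reference, config=cfg, config_hash=cfg.hash(),
                          training_fingerprint=fingerprint)


def predict(model: DiagnosisModel, fv) -> dict:
    """Label one feature vector with a trained model: {label, score}."""
    return model.predict(fv)


@dataclasses.dataclass
class EvaluationReport:
    """Results of a repeated-split evaluation.

    per_repeat holds one row per split (f1, sensitivity, specificity,
    false_positive_rate); importances holds per-repeat Gini importances
    (rows = repeats, columns = features, each row sums to 1); confusion
    totals accumulate over repeats.
    """

    per_repeat: pd.DataFrame
    importances: pd.DataFrame
    confusion: dict[str, int]
    feature_names: tuple[str, ...]
    config: CVConfig
    dropped: dict

    @property
    def mean(self) -> pd.Series:
        return self.per_repeat.mean()

    @property
    def std(self) -> pd.Series:
        return self.per_repeat.std(ddof=0)

    def metrics_from_confusion(self) -> dict[str, float]:
        c = self.confusion
        return {
            "f1": f1_score(c["tp"], c["fp"], c["fn"]),
            "sensitivity": c["tp"] / (c["tp"] + c["fn"]),
            "specificity": c["tn"] / (c["tn"] + c["fp"]),
            "false_positive_rate": c["fp"] / (c["fp"] + c["tn"]),
        }

    def ranked_importances(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "mean_importance": self.importances.mean(),
            "std_importance": self.importances.std(ddof=0),
        }).sort_values("mean_importance", ascending=False)
        out.index.name = "feature"
        return out

    def summary(self) -> str:
        m, s = self.mean, self.std
        lines = [
            "Repeated stratified split evaluation",
            "=" * 52,
            f"repeats (k):          {len(self.per_repeat)}",
            f"train fraction:       {self.config.train_fraction:.2f} per class",
            f"features used:        {len(self.feature_names)}",
            f"F1 score:             {100 * m['f1']:.2f}% (std {100 * s['f1']:.2f}%)",
            f"sensitivity:          {100 * m['sensitivity']:.2f}% (std {100 * s['sensitivity']:.2f}%)",
            f"specificity:          {100 * m['specificity']:.2f}% (std {100 * s['specificity']:.2f}%)",
            f"false positive rate:  {100 * m['false_positive_rate']:.2f}% "
            f"(std {100 * s['false_positive_rate']:.2f}%)",
            "",
            "Top features by mean Gini importance",
            "-" * 52,
        ]
        top = self.ranked_importances().head(8)
        for rank, (name, row) in enumerate(top.iterrows(), start=1):
            lines.append(f"{rank:2d}. {name:<28s} {100 * row.mean_importance:6.2f}% "
                         f"(std {100 * row.std_importance:.2f}%)")
        return "\n".join(lines)


def _splits(y: np.ndarray, cfg: CVConfig):
    if cfg.mode == "kfold":
        return StratifiedKFold(n_splits=cfg.k, shuffle=True,
                               random_state=cfg.seed).split(np.zeros(len(y)), y)
    return StratifiedShuffleSplit(n_splits=cfg.k, train_size=cfg.train_fraction,
                                  random_state=cfg.seed).split(np.zeros(len(y)), y)


def evaluate(data: "CohortFeatures | pd.DataFrame",
             labels: Sequence[str] | None = None,
             cfg: CVConfig | None = None) -> EvaluationReport:
    """Run the repeated-split protocol.

    ``data`` is either a :class:`CohortFeatures` bundle (distance features
    recomputed per training split; labels taken from it) or a plain feature
    table with ``labels`` given (distance columns used as-is).
    """
    cfg = cfg or CVConfig()
    if isinstance(data, CohortFeatures):
        cohort, table = data, data.features
        y = data.labels
    else:
        cohort, table = None, data
        if labels is None:
            raise ValueError("labels are required with a plain feature table")
        y = pd.Series(list(labels), index=table.index)
    counts = y.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError(f"each class needs >= 2 members to split; got {counts.to_dict()}")

    rows, imp_rows = [], []
    confusion = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    dropped_total: dict = {"dropped_train_rows": 0, "dropped_test_rows": 0,
                           "dropped_columns": []}
    feature_names: tuple[str, ...] = ()
    for r, (tr_idx, te_idx) in enumerate(_splits(y.to_numpy(), cfg)):
        if cohort is not None:
            ref = cohort.reference(tr_idx)
            train_df = cohort.with_distances(ref, tr_idx)
            test_df = cohort.with_distances(ref, te_idx)
        else:
            train_df, test_df = table.iloc[tr_idx], table.iloc[te_idx]
        train_clean, test_clean, info = _clean_matrix(train_df, test_df, cfg)
        dropped_total["dropped_train_rows"] += info["dropped_train_rows"]
        dropped_total["dropped_test_rows"] += info.get("dropped_test_rows", 0)
        dropped_total["dropped_columns"] = sorted(
            set(dropped_total["dropped_columns"]) | set(info["dropped_columns"]))
        y_tr = y.loc[train_clean.index]
        y_te = y.loc[test_clean.index]
        if y_tr.nunique() < 2:
            raise ValueError(f"repeat {r}: training split lost a class after "
                             "missing-feature filtering")
        forest = RandomForestClassifier(n_estimators=cfg.n_trees,
                                        random_state=cfg.seed + r, n_jobs=1)
        forest.fit(train_clean.to_numpy(), y_tr.to_numpy())
        feature_names = tuple(train_clean.columns)
        pos_col = list(forest.classes_).index(POSITIVE)
        score = forest.predict_proba(test_clean.to_numpy())[:, pos_col]
        pred = np.where(score >= cfg.threshold, POSITIVE, NEGATIVE)
        truth = y_te.to_numpy()
        tp = int(np.sum((pred == POSITIVE) & (truth == POSITIVE)))
        fp = int(np.sum((pred == POSITIVE) & (truth == NEGATIVE)))
        fn = int(np.sum((pred == NEGATIVE) & (truth == POSITIVE)))
        tn = int(np.sum((pred == NEGATIVE) & (truth == NEGATIVE)))
        for key, val in zip(("tp", "fp", "fn", "tn"), (tp, fp, fn, tn)):
            confusion[key] += val
        rows.append({
            "f1": f1_score(tp, fp, fn),
            "sensitivity": tp / (tp + fn),
            "specificity": tn / (tn + fp) if tn + fp > 0 else np.nan,
            "false_positive_rate": fp / (fp + tn) if fp + tn > 0 else np.nan,
        })
        imp_rows.append(pd.Series(forest.feature_importances_, index=feature_names))
    return EvaluationReport(
        per_repeat=pd.DataFrame(rows),
        importances=pd.DataFrame(imp_rows).reset_index(drop=True),
        confusion=confusion, feature_names=feature_names, config=cfg,
        dropped=dropped_total)


def feature_importances(report: EvaluationReport) -> pd.DataFrame:
    """Features ranked by mean Gini importance (with std) over the repeats."""
    return report.ranked_importances()


def robustness_curve(recordings: Sequence[Recording], durations: Sequence[float],
                     static_cfg: StaticConfig | None = None,
                     dyn_cfg: DynamicsConfig | None = None,
                     cv_cfg: CVConfig | None = None) -> pd.DataFrame:
    """Mean/std F1 as a function of the test duration used.

    For each duration, every recording is truncated to its first ``d``
    seconds, the full cohort extraction is re-run (so spectral packet sizes
    re-adapt and the cohort reference is rebuilt per training split), and the
    repeated-split protocol is evaluated. Returns one row per duration.
    """
    cv_cfg = cv_cfg or CVConfig()
    rows = []
    for d in durations:
        if d <= 0:
            raise ValueError("durations must be positive")
        truncated = [truncate(rec, d) for rec in recordings]
        cohort = extract_cohort(truncated, static_cfg, dyn_cfg)
        report = evaluate(cohort, cfg=cv_cfg)
        rows.append({"duration_s": float(d),
                     "f1_mean": float(report.mean["f1"]),
                     "f1_std": float(report.std["f1"]),
                     "n_features": len(report.feature_names)})
    return pd.DataFrame(rows)
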