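"""Probability fusion: assemble single-modal anomaly probabilities into the
four stacking patterns and fit tree-ensemble meta-learners.

The meta-learners are a random forest and a gradient-boosted tree ensemble.
Hyperparameters are chosen by exhaustive grid search maximizing F1 on the
development features at a 0.5 probability cut (ties resolve to the first
configuration in documented grid order), then the winner is refit on the
stacking training features.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier

from cardiostack.stats import binary_metrics

__all__ = [
    "STACKING_PATTERNS",
    "LEARNERS",
    "StackingPattern",
    "StackerSpec",
    "FittedStacker",
    "make_prediction_table",
    "assemble_features",
    "fit_stacker",
    "stacker_importances",
]


@dataclass(frozen=True)
class StackingPattern:
    name: str
    sources: tuple[str, ...]

    @property
    def n_features(self) -> int:
        return len(self.sources)


# Enabled source sets per published pattern table.
STACKING_PATTERNS: dict[str, StackingPattern] = {
    "PCG3ch+ECG2pt": StackingPattern(
        "PCG3ch+ECG2pt", ("PCG-2RSB", "PCG-ERB", "PCG-APX", "ECG-limb", "ECG-precordial")
    ),
    "PCG3ch+ECG1pt": StackingPattern(
        "PCG3ch+ECG1pt", ("PCG-2RSB", "PCG-ERB", "PCG-APX", "ECG-all12")
    ),
    "PCG3ch": StackingPattern("PCG3ch", ("PCG-2RSB", "PCG-ERB", "PCG-APX")),
    "ECG2pt": StackingPattern("ECG2pt", ("ECG-limb", "ECG-precordial")),
}

LEARNERS = ("RF", "GBT")

DEFAULT_GRIDS: dict[str, list[dict]] = {
    "RF": [
        {"n_estimators": n, "max_depth": d}
        for n, d in itertools.product((100, 300), (3, 5, None))
    ],
    "GBT": [
        {"n_estimators": n, "max_depth": d, "learning_rate": lr}
        for n, d, lr in itertools.product((100, 300), (2, 3), (0.1, 0.3))
    ],
}


@dataclass
class StackerSpec:
    learner: str = "RF"
    grid: list[dict] = field(default_factory=list)
    seed: int = 0
    threshold: float = 0.5  # probability cut for F1 during tuning

    def __post_init__(self) -> None:
        if self.learner not in LEARNERS:
            raise ValueError(f"unknown learner {self.learner!r}; expected one of {LEARNERS}")
        if not self.grid:
            self.grid = [dict(g) for g in DEFAULT_GRIDS[self.learner]]


def make_prediction_table(rows: list[tuple[str, str, float]]) -> pd.DataFrame:
    """PredictionTable: one row per (patient, source) anomaly probability."""
    table = pd.DataFrame(rows, columns=["patient_id", "source", "probability"])
    bad = table.loc[(table["probability"] < 0) | (table["probability"] > 1)]
    if not bad.empty:
        raise ValueError(f"probabilities outside [0, 1]: {bad.to_dict('records')}")
    if table.duplicated(["patient_id", "source"]).any():
        raise ValueError("duplicate (patient, source) rows")
    return table


def assemble_features(
    table: pd.DataFrame, pattern: StackingPattern, labels_by_pid: dict[str, int] | None = None
) -> tuple[np.ndarray, np.ndarray | None, list[str]]:
    """Pivot the prediction table into one feature row per patient.

    Column order follows ``pattern.sources`` exactly. Returns
    (features, labels or None, patient ids in row order).
    """
    pids = sorted(table["patient_id"].unique())
    if not pids:
        return np.empty((0, pattern.n_features)), (np.empty(0, dtype=int) if labels_by_pid is not None else None), []
    wide = table.pivot(index="patient_id", columns="source", values="probability")
    for src in pattern.sources:
        if src not in wide.columns:
            raise ValueError(f"prediction table has no source {src!r}")
        missing = wide.index[wide[src].isna()]
        if len(missing):
            raise ValueError(f"missing {src} probability for patient(s) {list(missing)}")
    x = wide.loc[pids, list(pattern.sources)].to_numpy(dtype=float)
    y = None
    if labels_by_pid is not None:
        y = np.array([labels_by_pid[p] for p in pids], dtype=int)
    return x, y, pids


def _make_learner(spec: StackerSpec, params: dict):
    if spec.learner == "RF":
        return RandomForestClassifier(random_state=spec.seed, **params)
    return GradientBoostingClassifier(random_state=spec.seed, **params)


@dataclass
class FittedStacker:
    learner: str
    pattern: StackingPattern
    estimator: object
    chosen_params: dict
    dev_f1: float
    seed: int

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(features)[:, 1]


def fit_stacker(
    features: np.ndarray,
    labels: np.ndarray,
    spec: StackerSpec,
    dev_features: np.ndarray,
    dev_labels: np.ndarray,
    pattern: StackingPattern | None = None,
) -> FittedStacker:
    """Grid search maximizing dev F1, then refit the winner on (features, labels)."""
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("stacking training labels contain a single class")
    pattern = pattern or StackingPattern("custom", tuple(f"f{i}" for i in range(features.shape[1])))
    best_f1, best_params = -1.0, None
    for params in spec.grid:
        est = _make_learner(spec, params)
        est.fit(features, labels)
        probs = est.predict_proba(dev_features)[:, 1]
        f1 = binary_metrics(probs, dev_labels, spec.threshold)["f1"]
        if f1 > best_f1:  # strict: ties keep the earlier grid entry
            best_f1, best_params = f1, params
    est = _make_learner(spec, best_params)
    est.fit(features, labels)
    return FittedStacker(
        learner=spec.learner,
        pattern=pattern,
        estimator=est,
        chosen_params=dict(best_params),
        dev_f1=float(best_f1),
        seed=spec.seed,
    )


def stacker_importances(fitted: FittedStacker) -> dict[str, float]:
    """Normalized per-source importance (impurity decrease / total gain)."""
    est = fitted.estimator
    if not hasattr(est, "feature_importances_"):
        raise ValueError("meta-learner is not fitted")
    imp = np.asarray(est.feature_importances_, dtype=float)
    if imp.size != fitted.pattern.n_features:
        raise ValueError(
            f"estimator saw {imp.size} features but pattern {fitted.pattern.name} has {fitted.pattern.n_features}"
        )
    total = imp.sum()
    if total <= 0:  # degenerate fit: no split used any feature
        imp = np.full_like(imp, 1.0 / imp.size)
    else:
        imp = imp / total
    return dict(zip(fitted.pattern.sources, imp.tolist()))
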