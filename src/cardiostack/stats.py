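"""Evaluation statistics: ROC/AUC, bootstrap metric resampling, ANOVA +
Tukey-Kramer model comparison, and top-3 model selection.

AUC is computed with the rank formula and is exactly the probability that a
random positive outscores a random negative, counting ties as one half.
Bootstrap resampling is un-stratified at the record level; resamples that
lose one of the classes are redrawn. ANOVA / Tukey-Kramer are run across the
per-model bootstrap AUC vectors — a fidelity choice, not an independent-
sample design (the resamples of one model are dependent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata

__all__ = [
    "BootstrapReport",
    "ComparisonResult",
    "roc_auc",
    "binary_metrics",
    "bootstrap_metrics",
    "compare_models",
    "select_models",
]

METRIC_NAMES = ("auc", "f1", "sensitivity", "specificity")


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError(f"labels must be binary 0/1, got values {uniq}")
    if uniq.size < 2:
        raise ValueError("both classes must be present")
    return labels.astype(int)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals ``P(score+ > score-) + 0.5 * P(score+ == score-)`` over all
    positive-negative pairs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)  # average ranks handle ties as half-wins
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def binary_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """F1, sensitivity and specificity at a probability threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return {"f1": f1, "sensitivity": sens, "specificity": spec}


@dataclass
class BootstrapReport:
    """Per-model mean +/- SD of AUC/F1/sensitivity/specificity over B resamples."""

    model: str
    n_resamples: int
    seed: int
    means: dict[str, float]
    sds: dict[str, float]
    auc_samples: np.ndarray = field(repr=False)
    f1_samples: np.ndarray = field(repr=False)

    def row(self) -> dict[str, float | str | int]:
        out: dict[str, float | str | int] = {"model": self.model, "B": self.n_resamples}
        for m in METRIC_NAMES:
            out[m] = self.means[m]
            out[f"{m}_sd"] = self.sds[m]
        return out


def bootstrap_metrics(
    scores,
    labels,
    B: int = 2000,
    seed: int = 0,
    threshold: float = 0.5,
    model: str = "model",
) -> BootstrapReport:
    """Resample records with replacement B times and report metric mean +/- SD.

    Degenerate resamples (a single class) are redrawn so every resample
    supports an AUC.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    n = labels.size
    rng = np.random.default_rng(seed)
    samples = {m: np.empty(B) for m in METRIC_NAMES}
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            ls = labels[idx]
            if ls.min() != ls.max():
                break
        ss = scores[idx]
        samples["auc"][b] = roc_auc(ss, ls)
        thr = binary_metrics(ss, ls, threshold)
        for m in ("f1", "sensitivity", "specificity"):
            samples[m][b] = thr[m]
    means = {m: float(samples[m].mean()) for m in METRIC_NAMES}
    # ddof=0: SD over the realized resamples, 0 by definition at B=1
    sds = {m: float(samples[m].std(ddof=0)) for m in METRIC_NAMES}
    return BootstrapReport(
        model=model,
        n_resamples=B,
        seed=seed,
        means=means,
        sds=sds,
        auc_samples=samples["auc"],
        f1_samples=samples["f1"],
    )


@dataclass
class ComparisonResult:
    """ANOVA + all-pairs Tukey-Kramer conclusions over bootstrapped AUC."""

    models: list[str]
    anova_statistic: float
    anova_pvalue: float
    pairwise_pvalues: np.ndarray  # symmetric (k, k)
    significant_pairs: list[tuple[str, str]]  # at alpha
    alpha: float
    ranking: list[str]  # by mean AUC desc, ties by mean F1
    top3: list[str]

    def to_dict(self) -> dict:
        return {
            "models": self.models,
            "anova_statistic": self.anova_statistic,
            "anova_pvalue": self.anova_pvalue,
            "pairwise_pvalues": self.pairwise_pvalues.tolist(),
            "significant_pairs": [list(p) for p in self.significant_pairs],
            "alpha": self.alpha,
            "ranking": self.ranking,
            "top3": self.top3,
        }


def compare_models(reports: list[BootstrapReport], alpha: float = 0.05) -> ComparisonResult:
    """One-way ANOVA plus Tukey-Kramer HSD across per-model bootstrap AUCs."""
    if len(reports) < 2:
        raise ValueError("need at least two models to compare")
    B = reports[0].n_resamples
    if any(r.n_resamples != B for r in reports):
        raise ValueError("all reports must use the same number of resamples")
    vecs = [r.auc_samples for r in reports]
    names = [r.model for r in reports]
    if all(np.allclose(v, vecs[0]) for v in vecs[1:]):
        # identical AUC vectors: zero between- and within-group variance makes
        # the F statistic 0/0; declare no differences directly
        k = len(vecs)
        stat, p = 0.0, 1.0
        pvals = np.ones((k, k))
        np.fill_diagonal(pvals, 0.0)
        sig: list[tuple[str, str]] = []
    else:
        stat, p = sps.f_oneway(*vecs)
        hsd = sps.tukey_hsd(*vecs)
        pvals = np.asarray(hsd.pvalue)
        sig = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if pvals[i, j] < alpha
        ]
    order = sorted(
        range(len(reports)),
        key=lambda i: (-reports[i].means["auc"], -reports[i].means["f1"], i),
    )
    ranking = [names[i] for i in order]
    return ComparisonResult(
        models=names,
        anova_statistic=float(stat),
        anova_pvalue=float(p),
        pairwise_pvalues=pvals,
        significant_pairs=sig,
        alpha=alpha,
        ranking=ranking,
        top3=ranking[:3],
    )


def select_models(
    test_auc: dict[tuple[str, int], float],
    methods: list[str],
    folds: list[int],
    test_f1: dict[tuple[str, int], float] | None = None,
    k: int = 3,
) -> list[dict]:
    """Keep each method's best fold by test AUC, rank survivors, return top k.

    ``test_auc`` maps (method, fold) -> AUC over the shared test set. Ties in
    AUC break by test F1 when given, then by method order in ``methods``.
    """
    missing = [(m, f) for m in methods for f in folds if (m, f) not in test_auc]
    if missing:
        raise ValueError(f"missing evaluation cells: {missing}")
    survivors = []
    for mi, m in enumerate(methods):
        best_fold = max(folds, key=lambda f: (test_auc[(m, f)], -f))
        entry = {
            "method": m,
            "fold": best_fold,
            "test_auc": test_auc[(m, best_fold)],
            "_order": mi,
        }
        if test_f1 is not None:
            entry["test_f1"] = test_f1[(m, best_fold)]
        survivors.append(entry)
    survivors.sort(
        key=lambda e: (-e["test_auc"], -e.get("test_f1", 0.0), e["_order"])
    )
    for e in survivors:
        del e["_order"]
    return survivors[:k]
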