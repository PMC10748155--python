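"""Modal contribution analysis: refit a selected stacking model under R
fluctuating seeds (default 50) and aggregate normalized per-source
importances into mean +/- SD.

Only the meta-learner is refit across seeds; the single-modal CNN features
are held fixed. Repetition seeds are the consecutive integers
``base_seed .. base_seed + R - 1`` for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cardiostack.stacking import (
    FittedStacker,
    StackerSpec,
    StackingPattern,
    fit_stacker,
    stacker_importances,
)

__all__ = ["ContributionReport", "contribution_analysis"]


@dataclass
class ContributionReport:
    model: str
    fold: int
    n_repetitions: int
    base_seed: int
    sources: tuple[str, ...]
    mean: dict[str, float]
    sd: dict[str, float]
    per_repetition: pd.DataFrame = field(repr=False)

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "model": self.model,
                "fold": self.fold,
                "source": s,
                "mean": self.mean[s],
                "sd": self.sd[s],
                "R": self.n_repetitions,
            }
            for s in self.sources
        ]
        return pd.DataFrame(rows)

    def summed(self, prefix: str) -> float:
        """Total mean importance over sources whose name starts with prefix."""
        return sum(v for s, v in self.mean.items() if s.startswith(prefix))


def contribution_analysis(
    features: np.ndarray,
    labels: np.ndarray,
    dev_features: np.ndarray,
    dev_labels: np.ndarray,
    pattern: StackingPattern,
    learner: str = "RF",
    R: int = 50,
    base_seed: int = 0,
    fold: int = -1,
    model_name: str = "",
    grid: list[dict] | None = None,
) -> ContributionReport:
    """Refit the stacker R times with seeds base_seed..base_seed+R-1 and
    report per-source importance mean +/- SD (per-repetition importances each
    sum to 1)."""
    if R < 1:
        raise ValueError("R must be >= 1")
    rows = []
    for r in range(R):
        spec = StackerSpec(learner=learner, seed=base_seed + r, grid=[dict(g) for g in grid] if grid else [])
        fitted: FittedStacker = fit_stacker(features, labels, spec, dev_features, dev_labels, pattern)
        imp = stacker_importances(fitted)
        rows.append({"repetition": r, "seed": base_seed + r, **imp})
    per_rep = pd.DataFrame(rows)
    mean = {s: float(per_rep[s].mean()) for s in pattern.sources}
    sd = {s: float(per_rep[s].std(ddof=0)) for s in pattern.sources}
    return ContributionReport(
        model=model_name or f"{learner}({pattern.name})",
        fold=fold,
        n_repetitions=R,
        base_seed=base_seed,
        sources=pattern.sources,
        mean=mean,
        sd=sd,
        per_repetition=per_rep,
    )
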