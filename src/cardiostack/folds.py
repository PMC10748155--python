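"""Modified stratified 4-fold cross-validation structure.

One test set is shared by all folds; the remaining patients are partitioned
into four disjoint development blocks. Fold k trains on the three dev blocks
it does not validate on, so the four train/dev groupings never share dev
patients ("without overlap" read as applying to the dev blocks).
Stratification is joint over the (AS, MR, LVD) grade triple, with sparse
strata pooled by their severe flags so every stratum can be split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cardiostack.synthetic import DISEASES, CohortManifest

__all__ = ["N_FOLDS", "FoldAssignment", "make_folds"]

N_FOLDS = 4


@dataclass
class FoldAssignment:
    test_ids: list[str]
    dev_ids: dict[int, list[str]]  # fold -> dev block
    seed: int

    @property
    def n_folds(self) -> int:
        return N_FOLDS

    def train_ids(self, fold: int) -> list[str]:
        return [p for f, blk in self.dev_ids.items() if f != fold for p in blk]

    def apply(self, manifest: CohortManifest) -> CohortManifest:
        """Write split/fold columns back into the manifest table."""
        t = manifest.table
        t["split"] = ""
        t["fold"] = -1
        t.loc[t["patient_id"].isin(self.test_ids), "split"] = "test"
        for fold, ids in self.dev_ids.items():
            sel = t["patient_id"].isin(ids)
            t.loc[sel, "split"] = "dev"
            t.loc[sel, "fold"] = fold
        return manifest

    def frame(self) -> pd.DataFrame:
        rows = [{"patient_id": p, "split": "test", "fold": -1} for p in self.test_ids]
        for fold, ids in self.dev_ids.items():
            rows += [{"patient_id": p, "split": "dev", "fold": fold} for p in ids]
        return pd.DataFrame(rows)


def make_folds(
    manifest: CohortManifest,
    test_fraction: float = 0.2,
    seed: int = 0,
    min_stratum: int = 2,
) -> FoldAssignment:
    """Deterministic joint-stratified assignment of test and 4 dev blocks.

    Within each stratum, a shuffled ``test_fraction`` share goes to the
    shared test set and the rest is dealt round-robin into the four dev
    blocks. Strata smaller than ``min_stratum`` are pooled by their
    (severe-AS, severe-MR, severe-LVD) flag triple so rare grade
    combinations still split proportionally.
    """
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    t = manifest.table
    keys = t[[f"{d}_grade" for d in DISEASES]].agg("|".join, axis=1)
    counts = keys.value_counts()
    # pool sparse strata by severity flags only
    pooled = {}
    for key in counts.index:
        if counts[key] >= min_stratum:
            pooled[key] = key
        else:
            flags = "|".join("S" if g == "severe" else "-" for g in key.split("|"))
            pooled[key] = f"pooled:{flags}"
    strata = keys.map(pooled)

    rng = np.random.default_rng(seed)
    test_ids: list[str] = []
    dev_ids: dict[int, list[str]] = {f: [] for f in range(N_FOLDS)}
    next_fold = 0
    for stratum in sorted(strata.unique()):
        pids = sorted(t.loc[strata == stratum, "patient_id"])
        rng.shuffle(pids)
        n_test = int(round(test_fraction * len(pids)))
        if len(pids) - n_test < 0:
            n_test = len(pids)
        test_ids += pids[:n_test]
        for pid in pids[n_test:]:
            dev_ids[next_fold].append(pid)
            next_fold = (next_fold + 1) % N_FOLDS
    empty = [f for f, ids in dev_ids.items() if not ids]
    if empty:
        raise ValueError(
            f"cohort of {len(t)} patients too small to fill dev blocks {empty}"
        )
    assignment = FoldAssignment(test_ids=sorted(test_ids), dev_ids={f: sorted(i) for f, i in dev_ids.items()}, seed=seed)
    assignment.apply(manifest)
    return assignment
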