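"""Dataset assembly, the training loop, and record-level inference.

One binary model is trained per (disease, source) where source is one of
three auscultation sites or three ECG page views. Training applies the
severity-dependent oversampling plus SpecAugment/mixup (heart sound only);
evaluation uses the deterministic base segmentation (grade-"none" count) for
heart sounds and the single unshifted crop for ECG views, and aggregates
segment probabilities to one record probability by the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from cardiostack.cnn.model import Cnn, CnnConfig
from cardiostack.ecg import EcgCropParams, crop_view, resize_view, shift_augment
from cardiostack.pcg import PcgPreprocParams, log_mel, mixup, segment_record, spec_augment, LogMelSegment
from cardiostack.synthetic import CohortManifest, EcgScan, PcgRecord

__all__ = [
    "PCG_SOURCES",
    "ECG_SOURCES",
    "ALL_SOURCES",
    "TrainResult",
    "build_pcg_dataset",
    "build_ecg_dataset",
    "train_classifier",
    "train_single_modal",
    "predict_record",
]

PCG_SOURCES = ("PCG-2RSB", "PCG-ERB", "PCG-APX")
ECG_SOURCES = ("ECG-all12", "ECG-limb", "ECG-precordial")
ALL_SOURCES = PCG_SOURCES + ECG_SOURCES

_SOURCE_SITE = {"PCG-2RSB": "2RSB", "PCG-ERB": "ERB", "PCG-APX": "APX"}
_SOURCE_VIEW = {"ECG-all12": "all12", "ECG-limb": "limb", "ECG-precordial": "precordial"}


def build_pcg_dataset(
    manifest: CohortManifest,
    ids: list[str],
    site: str,
    disease: str,
    params: PcgPreprocParams,
    train: bool,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Log-Mel segments for the given patients at one auscultation site.

    Training applies the per-grade oversampling count; evaluation always cuts
    the base (grade-"none") number of segments.
    """
    xs, ys, groups = [], [], []
    for pid in ids:
        paths = manifest.paths_for(pid)
        rec = PcgRecord.read_wav(paths[site], site=site, patient_id=pid)
        grade = manifest.label_of(pid, disease).grade
        label = int(grade == "severe")
        eff_grade = grade if train else "none"
        for w_i, window in enumerate(segment_record(rec, params, eff_grade)):
            seg = log_mel(window, params, sample_rate=rec.sample_rate, source=(pid, site, float(w_i)), label=label)
            xs.append(seg.values.astype(np.float32))
            ys.append(label)
            groups.append(pid)
    return np.stack(xs), np.asarray(ys), groups


def build_ecg_dataset(
    manifest: CohortManifest,
    ids: list[str],
    view: str,
    disease: str,
    params: EcgCropParams,
    train: bool,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Cropped/resized page views; shift augmentation only on the training path.

    Pixel intensities are inverted to trace-bright ([0, 1]) before the CNN.
    """
    xs, ys, groups = [], [], []
    for pid in ids:
        paths = manifest.paths_for(pid)
        scan = EcgScan.read_png(paths["ecg"], patient_id=pid)
        grade = manifest.label_of(pid, disease).grade
        label = int(grade == "severe")
        if train:
            images = shift_augment(scan, params, grade)
        else:
            images = [resize_view(crop_view(scan, params), params)]
        for img in images:
            xs.append(((255.0 - img) / 255.0).astype(np.float32))
            ys.append(label)
            groups.append(pid)
    return np.stack(xs), np.asarray(ys), groups


def predict_record(model: Cnn, segments: np.ndarray, aggregate: str = "mean") -> float:
    """Record-level anomaly probability over its evaluation-time segments."""
    if len(segments) == 0:
        raise ValueError("record has no segments")
    probs = model.predict_proba(np.asarray(segments))
    return float(probs.max() if aggregate == "max" else probs.mean())


def _record_probs(model: Cnn, x: np.ndarray, groups: list[str]) -> dict[str, float]:
    probs = model.predict_proba(x)
    by_pid: dict[str, list[float]] = {}
    for p, pid in zip(probs, groups):
        by_pid.setdefault(pid, []).append(float(p))
    return {pid: float(np.mean(v)) for pid, v in by_pid.items()}


def _dev_auc(model: Cnn, x: np.ndarray, groups: list[str], labels_by_pid: dict[str, int]) -> float:
    from cardiostack.stats import roc_auc

    rec = _record_probs(model, x, groups)
    pids = sorted(rec)
    ys = np.array([labels_by_pid[p] for p in pids])
    if ys.min() == ys.max():
        return float("nan")
    return roc_auc(np.array([rec[p] for p in pids]), ys)


@dataclass
class TrainResult:
    model: Cnn
    history: list[dict] = field(default_factory=list)
    dev_auc: float = float("nan")
    source: str = ""
    disease: str = ""
    fold: int = -1

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)


def train_classifier(
    x_train: np.ndarray,
    y_train: np.ndarray,
    config: CnnConfig,
    dev: tuple[np.ndarray, list[str], dict[str, int]] | None = None,
    augment: str = "none",
) -> TrainResult:
    """Train the CNN with cross-entropy (soft labels supported via mixup).

    ``augment='pcg'`` enables SpecAugment + mixup on each training batch.
    Checkpoint selection: best record-level dev AUC across epochs.
    """
    if y_train.min() == y_train.max():
        raise ValueError("training split must contain both classes")
    model = Cnn(config)
    opt = model.make_optimizer()
    rng = np.random.default_rng([config.seed, 12345])
    n = len(x_train)
    best_auc, best_state = -np.inf, None
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb = x_train[idx]
            yb = np.eye(2, dtype=np.float32)[y_train[idx]]
            if augment == "pcg":
                masked = np.empty_like(xb)
                for j in range(len(xb)):
                    seg = LogMelSegment(values=xb[j], source=("", "", 0.0), label=int(y_train[idx][j]))
                    masked[j] = spec_augment(
                        seg,
                        freq_mask_width=min(config.freq_mask_width, xb.shape[2]),
                        time_mask_width=min(config.time_mask_width, xb.shape[1]),
                        n_masks=config.spec_augment_masks,
                        rng=rng,
                    ).values
                lam = float(rng.beta(config.mixup_alpha, config.mixup_alpha))
                perm = rng.permutation(len(masked))
                xb = lam * masked + (1.0 - lam) * masked[perm]
                yb = lam * yb + (1.0 - lam) * yb[perm]
            losses.append(model.train_step(xb, yb, opt))
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if dev is not None:
            auc = _dev_auc(model, *dev)
            row["dev_auc"] = auc
            if np.isfinite(auc) and auc > best_auc:
                best_auc, best_state = auc, model.state()
        history.append(row)
    if best_state is not None:
        model.load_state(best_state)
    return TrainResult(model=model, history=history, dev_auc=float(best_auc) if np.isfinite(best_auc) else float("nan"))


def split_ids(manifest: CohortManifest, fold: int) -> tuple[list[str], list[str], list[str]]:
    """(train, dev, test) patient ids for one fold of the shared-test design."""
    t = manifest.table
    test = list(t.loc[t["split"] == "test", "patient_id"])
    dev = list(t.loc[(t["split"] == "dev") & (t["fold"] == fold), "patient_id"])
    train = list(t.loc[(t["split"] == "dev") & (t["fold"] != fold), "patient_id"])
    if not dev or not train:
        raise ValueError(f"fold {fold} has no train/dev assignment; run make_folds first")
    return train, dev, test


def train_single_modal(
    manifest: CohortManifest,
    disease: str,
    source: str,
    fold: int,
    config: CnnConfig,
    pcg_params: PcgPreprocParams | None = None,
    ecg_params: EcgCropParams | None = None,
) -> TrainResult:
    """Train one (disease, source) model on a fold's train split, monitoring
    the dev split with augmentations off."""
    if source not in ALL_SOURCES:
        raise ValueError(f"unknown source {source!r}; expected one of {ALL_SOURCES}")
    train_ids, dev_ids, _ = split_ids(manifest, fold)
    labels_by_pid = {
        pid: int(manifest.label_of(pid, disease).binary_target) for pid in train_ids + dev_ids
    }
    if source in PCG_SOURCES:
        from cardiostack.pcg import DEFAULT_SEGMENT_COUNTS

        params = pcg_params or PcgPreprocParams(segment_counts=dict(DEFAULT_SEGMENT_COUNTS[disease]))
        site = _SOURCE_SITE[source]
        xt, yt, _ = build_pcg_dataset(manifest, train_ids, site, disease, params, train=True)
        xd, _, gd = build_pcg_dataset(manifest, dev_ids, site, disease, params, train=False)
        augment = "pcg"
    else:
        view = _SOURCE_VIEW[source]
        params = ecg_params or EcgCropParams.for_view(view, disease)
        xt, yt, _ = build_ecg_dataset(manifest, train_ids, view, disease, params, train=True)
        xd, _, gd = build_ecg_dataset(manifest, dev_ids, view, disease, params, train=False)
        augment = "none"
    result = train_classifier(xt, yt, config, dev=(xd, gd, labels_by_pid), augment=augment)
    result.source, result.disease, result.fold = source, disease, fold
    return result
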