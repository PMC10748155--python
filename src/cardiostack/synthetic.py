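"""Disease-conditioned synthetic cohort generator.

Produces per-patient records shaped like the clinical acquisition protocol:
three 15-s, 4000-Hz heart-sound WAVs (sites 2RSB / Erb / apex), one rendered
grayscale scan of a printed 12-lead ECG page (3187 x 1840 px by default),
and ordinal severity grades for aortic stenosis (AS), mitral regurgitation
(MR) and left-ventricular dysfunction (LVD).

Signal model
------------
Heart sounds are periodic S1/S2 Gaussian-windowed tone bursts plus broadband
noise. Severe AS adds a mid-systolic band-limited noise burst loudest at
2RSB; severe MR adds a holosystolic burst loudest at the apex; severe LVD
attenuates S1. ECG pages render sum-of-Gaussians PQRST traces, limb leads in
the upper half and precordial leads in the lower half; severe AS raises
precordial R amplitude, severe MR perturbs rhythm regularity and P waves,
severe LVD widens QRS and lowers R amplitude. All disease terms scale with
``effect_size`` and vanish exactly at ``effect_size == 0``. Every output is
a pure function of (arguments, seed). Generators emit ground-truth metadata
(systolic windows, QRS template width) so property tests need no detector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.io import wavfile
from scipy.signal import butter, lfilter

__all__ = [
    "DISEASES",
    "GRADES",
    "SITES",
    "SeverityLabel",
    "PcgRecord",
    "EcgScan",
    "CohortManifest",
    "generate_pcg",
    "generate_ecg_scan",
    "generate_cohort",
    "DEFAULT_PREVALENCES",
]

DISEASES = ("AS", "MR", "LVD")
GRADES = ("none", "mild", "moderate", "severe")
SITES = ("2RSB", "ERB", "APX")

PCG_SAMPLE_RATE = 4000
PCG_DURATION_S = 15.0
PAGE_WIDTH = 3187
PAGE_HEIGHT = 1840

# Default grade prevalences. AS and MR follow the published cohort's grade
# counts (785/68/66/132 and 469/385/130/67 of 1051); LVD grade counts are
# not published, so a plausible distribution with ~7% severe is used.
DEFAULT_PREVALENCES: dict[str, tuple[float, ...]] = {
    "AS": (785 / 1051, 68 / 1051, 66 / 1051, 132 / 1051),
    "MR": (469 / 1051, 385 / 1051, 130 / 1051, 67 / 1051),
    "LVD": (0.78, 0.09, 0.06, 0.07),
}

# Relative murmur loudness per auscultation site.
_AS_SITE_GAIN = {"2RSB": 1.0, "ERB": 0.55, "APX": 0.25}
_MR_SITE_GAIN = {"2RSB": 0.25, "ERB": 0.55, "APX": 1.0}

# rng stream tags keep base anatomy, noise and disease terms independent so
# zeroing a disease term cannot perturb anything else
_TAG_RHYTHM, _TAG_NOISE, _TAG_DISEASE, _TAG_ECG, _TAG_LABELS = 101, 102, 103, 201, 301


@dataclass(frozen=True)
class SeverityLabel:
    """Ordinal grade for one disease; ``severe`` is the positive class."""

    disease: str
    grade: str

    def __post_init__(self) -> None:
        if self.disease not in DISEASES:
            raise ValueError(f"unknown disease {self.disease!r}; expected one of {DISEASES}")
        if self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r}; expected one of {GRADES}")

    @property
    def binary_target(self) -> bool:
        return self.grade == "severe"


@dataclass
class PcgRecord:
    """One heart-sound recording at a single auscultation site."""

    samples: np.ndarray
    sample_rate: int
    site: str
    patient_id: str
    metadata: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def write_wav(self, path: str | Path) -> None:
        """16-bit PCM mono WAV at the record's sampling rate."""
        pcm = np.clip(np.round(self.samples * 8000.0), -32768, 32767).astype(np.int16)
        wavfile.write(str(path), self.sample_rate, pcm)

    @classmethod
    def read_wav(cls, path: str | Path, site: str = "", patient_id: str = "") -> "PcgRecord":
        rate, pcm = wavfile.read(str(path))
        return cls(samples=pcm.astype(float) / 8000.0, sample_rate=int(rate), site=site, patient_id=patient_id)


@dataclass
class EcgScan:
    """One scanned 12-lead ECG page; dark trace on a white background."""

    pixels: np.ndarray  # uint8, shape (height, width)
    patient_id: str
    metadata: dict = field(default_factory=dict)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    def write_png(self, path: str | Path) -> None:
        Image.fromarray(self.pixels, mode="L").save(str(path))

    @classmethod
    def read_png(cls, path: str | Path, patient_id: str = "") -> "EcgScan":
        return cls(pixels=np.asarray(Image.open(str(path)).convert("L")), patient_id=patient_id)


def _validate_grades(disease_grades: dict[str, str]) -> dict[str, str]:
    grades = {d: "none" for d in DISEASES}
    for d, g in disease_grades.items():
        if d not in DISEASES:
            raise ValueError(f"unknown disease {d!r}; expected one of {DISEASES}")
        if g not in GRADES:
            raise ValueError(f"unknown grade {g!r}; expected one of {GRADES}")
        grades[d] = g
    return grades


def _add_tone_burst(x: np.ndarray, fs: int, center: float, freq: float, sigma: float, amp: float) -> None:
    """Add a Gaussian-windowed sinusoid in place, evaluated on a +/-5-sigma slice."""
    i0 = max(0, int((center - 5 * sigma) * fs))
    i1 = min(x.size, int((center + 5 * sigma) * fs) + 1)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / fs
    env = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    x[i0:i1] += amp * env * np.sin(2 * np.pi * freq * (t - center))


def _add_gauss_env(env: np.ndarray, fs: int, center: float, sigma: float) -> None:
    i0 = max(0, int((center - 5 * sigma) * fs))
    i1 = min(env.size, int((center + 5 * sigma) * fs) + 1)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / fs
    env[i0:i1] += np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _add_plateau_env(env: np.ndarray, fs: int, lo: float, hi: float, edge: float = 0.004) -> None:
    from scipy.special import expit

    i0 = max(0, int((lo - 8 * edge) * fs))
    i1 = min(env.size, int((hi + 8 * edge) * fs) + 1)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / fs
    env[i0:i1] += expit((t - lo) / edge) * expit(-(t - hi) / edge)


def _band_noise(rng: np.random.Generator, n: int, fs: int, lo: float, hi: float) -> np.ndarray:
    white = rng.standard_normal(n)
    b, a = butter(4, [lo / (fs / 2), hi / (fs / 2)], btype="band")
    return lfilter(b, a, white)


def generate_pcg(
    disease_grades: dict[str, str],
    site: str,
    seed: int,
    effect_size: float = 1.0,
    duration: float = PCG_DURATION_S,
    sample_rate: int = PCG_SAMPLE_RATE,
    patient_id: str = "",
) -> PcgRecord:
    """Synthesize one heart-sound recording.

    The cardiac rhythm stream depends only on ``seed`` so all three sites of
    a patient share one rhythm; noise and disease streams additionally hash
    the site so they stay independent of each other.
    """
    if site not in SITES:
        raise ValueError(f"unknown site {site!r}; expected one of {SITES}")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    grades = _validate_grades(disease_grades)
    site_idx = SITES.index(site)

    n = round(sample_rate * duration)

    rhythm = np.random.default_rng([_TAG_RHYTHM, seed])
    hr = rhythm.uniform(60.0, 100.0)
    period = 60.0 / hr
    f_s1 = rhythm.uniform(60.0, 110.0)
    f_s2 = rhythm.uniform(90.0, 150.0)
    onsets = np.arange(0.1, duration - 0.45 * period, period)

    s1_amp = 1.0
    if grades["LVD"] == "severe" and effect_size > 0:
        s1_amp = float(np.exp(-0.6 * effect_size))

    noise_rng = np.random.default_rng([_TAG_NOISE, seed, site_idx])
    x = 0.02 * noise_rng.standard_normal(n)

    systolic_windows = []
    for onset in onsets:
        s2_center = onset + 0.35 * period
        _add_tone_burst(x, sample_rate, onset, f_s1, 0.018, s1_amp)
        _add_tone_burst(x, sample_rate, s2_center, f_s2, 0.014, 0.8)
        systolic_windows.append((onset + 0.05 * period, onset + 0.30 * period))

    if grades["AS"] == "severe" and effect_size > 0:
        rng = np.random.default_rng([_TAG_DISEASE, seed, site_idx, 0])
        noise = _band_noise(rng, n, sample_rate, 150.0, 600.0)
        env = np.zeros(n)
        for onset in onsets:  # crescendo-decrescendo, peaking mid-systole
            _add_gauss_env(env, sample_rate, onset + 0.175 * period, 0.055 * period)
        x += 0.9 * effect_size * _AS_SITE_GAIN[site] * env * noise

    if grades["MR"] == "severe" and effect_size > 0:
        rng = np.random.default_rng([_TAG_DISEASE, seed, site_idx, 1])
        noise = _band_noise(rng, n, sample_rate, 100.0, 400.0)
        env = np.zeros(n)
        for onset in onsets:  # flat holosystolic plateau
            _add_plateau_env(env, sample_rate, onset + 0.02 * period, onset + 0.33 * period)
        x += 0.7 * effect_size * _MR_SITE_GAIN[site] * env * noise

    return PcgRecord(
        samples=x,
        sample_rate=sample_rate,
        site=site,
        patient_id=patient_id,
        metadata={
            "heart_rate_bpm": float(hr),
            "systolic_windows": [(float(a), float(b)) for a, b in systolic_windows],
            "s1_amplitude": float(s1_amp),
        },
    )


# 12-lead layout: two rows of three cells per page half
_LIMB_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF")
_PRECORDIAL_LEADS = ("V1", "V2", "V3", "V4", "V5", "V6")
_LIMB_GAIN = (0.6, 1.0, 0.7, 0.45, 0.4, 0.8)
_PRECORDIAL_GAIN = (0.5, 0.7, 0.9, 1.1, 1.0, 0.8)


def _pqrst(t: np.ndarray, beat_times: np.ndarray, gain: float, r_amp: float,
           qrs_sigma: float, p_amp: float, p_sigma: float) -> np.ndarray:
    """Sum-of-Gaussians PQRST template evaluated at times ``t``."""
    waves = (
        (p_amp, p_sigma, -0.16),
        (-0.12, 0.010, -0.028),
        (r_amp, qrs_sigma, 0.0),
        (-0.25, 0.010, 0.030),
        (0.30, 0.050, 0.30),
    )
    y = np.zeros_like(t)
    for bt in beat_times:
        for amp, sigma, off in waves:
            y += amp * np.exp(-0.5 * ((t - bt - off) / sigma) ** 2)
    return gain * y


def generate_ecg_scan(
    disease_grades: dict[str, str],
    seed: int,
    effect_size: float = 1.0,
    width: int = PAGE_WIDTH,
    height: int = PAGE_HEIGHT,
    patient_id: str = "",
) -> EcgScan:
    """Render one synthetic scanned 12-lead ECG page.

    Limb leads occupy the upper half (two rows of three), precordial leads
    the lower half. Rendering is pure integer pixel filling — no
    anti-aliasing — so pages are bit-deterministic per seed.
    """
    if width <= 0 or height <= 0:
        raise ValueError("page size must be positive")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    grades = _validate_grades(disease_grades)

    rng = np.random.default_rng([_TAG_ECG, seed])
    hr = rng.uniform(60.0, 100.0)
    period = 60.0 / hr
    seconds_per_cell = 3.0
    n_beats = int(seconds_per_cell / period) + 3

    qrs_sigma = 0.012
    r_scale = 1.0
    p_amp, p_sigma = 0.15, 0.025
    precordial_r_boost = 1.0
    if grades["LVD"] == "severe" and effect_size > 0:
        qrs_sigma *= 1.0 + 0.8 * effect_size
        r_scale /= 1.0 + 0.5 * effect_size
    if grades["AS"] == "severe" and effect_size > 0:
        precordial_r_boost = 1.0 + 0.5 * effect_size

    # one shared rhythm; severe MR jitters RR intervals and flattens P waves
    rr = np.full(n_beats, period)
    if grades["MR"] == "severe" and effect_size > 0:
        mr_rng = np.random.default_rng([_TAG_ECG, seed, 7])
        rr = period * (1.0 + 0.18 * effect_size * mr_rng.standard_normal(n_beats))
        rr = np.clip(rr, 0.35, 1.8)
        p_amp *= float(np.exp(-1.5 * effect_size))
        p_sigma *= 1.0 + 0.6 * effect_size
    beat_times = 0.25 + np.concatenate(([0.0], np.cumsum(rr[:-1])))

    page = np.full((height, width), 255, dtype=np.uint8)
    grid_step = max(8, round(height / 46))
    page[::grid_step, :] = 225
    page[:, ::grid_step] = 225

    cell_w = width // 3
    cell_h = height // 4
    px_per_s = cell_w / seconds_per_cell
    t_cols = np.arange(cell_w) / px_per_s

    for li in range(12):
        half = 0 if li < 6 else 1  # 0 = limb (upper), 1 = precordial (lower)
        pos = li % 6
        row, col = half * 2 + pos // 3, pos % 3
        gain = _LIMB_GAIN[pos] if half == 0 else _PRECORDIAL_GAIN[pos]
        r_amp = r_scale * (precordial_r_boost if half == 1 else 1.0)
        y = _pqrst(t_cols + col * seconds_per_cell, beat_times, gain, r_amp,
                   qrs_sigma, p_amp, p_sigma)
        baseline = row * cell_h + int(0.62 * cell_h)
        amp_px = 0.30 * cell_h
        y_px = np.clip(baseline - np.round(y * amp_px).astype(int), row * cell_h, (row + 1) * cell_h - 1)
        x0 = col * cell_w
        for i in range(cell_w - 1):
            lo = min(y_px[i], y_px[i + 1])
            hi = max(y_px[i], y_px[i + 1])
            page[lo : hi + 2, x0 + i] = 20  # 2-px-thick dark trace

    return EcgScan(
        pixels=page,
        patient_id=patient_id,
        metadata={
            "heart_rate_bpm": float(hr),
            "qrs_sigma_s": float(qrs_sigma),
            "qrs_width_s": float(6 * qrs_sigma),
            "r_scale": float(r_scale),
            "precordial_r_boost": float(precordial_r_boost),
            "rr_intervals_s": [float(v) for v in rr],
            "p_amplitude": float(p_amp),
        },
    )


MANIFEST_COLUMNS = [
    "patient_id", "pcg_2RSB", "pcg_ERB", "pcg_APX", "ecg",
    "AS_grade", "MR_grade", "LVD_grade", "split", "fold",
]


@dataclass
class CohortManifest:
    """Per-patient file paths, grades and (optional) split/fold assignment."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.table["patient_id"])

    def grades(self, disease: str) -> pd.Series:
        if disease not in DISEASES:
            raise ValueError(f"unknown disease {disease!r}")
        return self.table[f"{disease}_grade"]

    def labels(self, disease: str) -> np.ndarray:
        """Binary severe/not-severe target vector for one disease."""
        return (self.grades(disease) == "severe").to_numpy().astype(int)

    def label_of(self, patient_id: str, disease: str) -> SeverityLabel:
        row = self.table.loc[self.table["patient_id"] == patient_id]
        if row.empty:
            raise KeyError(patient_id)
        return SeverityLabel(disease, row.iloc[0][f"{disease}_grade"])

    def paths_for(self, patient_id: str) -> dict[str, str]:
        row = self.table.loc[self.table["patient_id"] == patient_id]
        if row.empty:
            raise KeyError(patient_id)
        r = row.iloc[0]
        return {"2RSB": r["pcg_2RSB"], "ERB": r["pcg_ERB"], "APX": r["pcg_APX"], "ecg": r["ecg"]}

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(directory / "manifest.csv", index=False)
        with open(directory / "manifest_meta.json", "w") as fh:
            json.dump(self.metadata, fh, indent=1)

    @classmethod
    def load(cls, directory: str | Path) -> "CohortManifest":
        directory = Path(directory)
        table = pd.read_csv(directory / "manifest.csv", keep_default_na=False)
        table["fold"] = table["fold"].astype(int)
        meta_path = directory / "manifest_meta.json"
        metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(table=table, metadata=metadata)


def generate_cohort(
    n: int,
    out_dir: str | Path,
    prevalences: dict[str, tuple[float, ...]] | None = None,
    seed: int = 0,
    effect_size: float = 1.0,
    duration: float = PCG_DURATION_S,
    page_width: int = PAGE_WIDTH,
    page_height: int = PAGE_HEIGHT,
    pcg_effect_size: float | None = None,
    ecg_effect_size: float | None = None,
) -> CohortManifest:
    """Write an n-patient synthetic cohort and return its manifest.

    Grade draws for disease ``d`` (index i in AS/MR/LVD order) come from the
    stream ``default_rng([301, seed, i]).choice(4, size=n, p=prevalences[d])``
    — documented so tests can replay them independently. Patient signal seeds
    are ``seed * 1_000_003 + patient_index``.

    ``pcg_effect_size`` / ``ecg_effect_size`` override ``effect_size`` per
    modality, e.g. to plant disease signal in the heart sounds only.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pcg_eff = effect_size if pcg_effect_size is None else pcg_effect_size
    ecg_eff = effect_size if ecg_effect_size is None else ecg_effect_size
    if pcg_eff < 0 or ecg_eff < 0:
        raise ValueError("effect sizes must be >= 0")
    prev = dict(DEFAULT_PREVALENCES)
    if prevalences:
        prev.update(prevalences)
    for d in DISEASES:
        p = np.asarray(prev[d], dtype=float)
        if p.size != len(GRADES) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"invalid grade distribution for {d}: {prev[d]}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    grade_idx = {}
    for di, d in enumerate(DISEASES):
        rng = np.random.default_rng([_TAG_LABELS, seed, di])
        grade_idx[d] = rng.choice(len(GRADES), size=n, p=np.asarray(prev[d], dtype=float))

    rows = []
    meta: dict[str, dict] = {}
    for i in range(n):
        pid = f"P{i:04d}"
        pseed = seed * 1_000_003 + i
        grades = {d: GRADES[grade_idx[d][i]] for d in DISEASES}
        row = {"patient_id": pid, "split": "", "fold": -1}
        pmeta: dict = {"seed": pseed, "grades": grades}
        for site in SITES:
            rec = generate_pcg(grades, site, pseed, pcg_eff, duration=duration, patient_id=pid)
            path = out_dir / f"{pid}_{site}.wav"
            rec.write_wav(path)
            row[f"pcg_{site}"] = str(path)
            if site == SITES[0]:
                pmeta["heart_rate_bpm"] = rec.metadata["heart_rate_bpm"]
                pmeta["systolic_windows"] = rec.metadata["systolic_windows"]
        scan = generate_ecg_scan(grades, pseed, ecg_eff, width=page_width, height=page_height, patient_id=pid)
        path = out_dir / f"{pid}_ecg.png"
        scan.write_png(path)
        row["ecg"] = str(path)
        pmeta["qrs_width_s"] = scan.metadata["qrs_width_s"]
        for d in DISEASES:
            row[f"{d}_grade"] = grades[d]
        rows.append(row)
        meta[pid] = pmeta

    table = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest = CohortManifest(
        table=table,
        metadata={
            "seed": seed,
            "effect_size": effect_size,
            "pcg_effect_size": pcg_eff,
            "ecg_effect_size": ecg_eff,
            "n": n,
            "duration_s": duration,
            "page_width": page_width,
            "page_height": page_height,
            "patients": meta,
        },
    )
    manifest.save(out_dir)
    return manifest
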