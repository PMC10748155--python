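"""Declarative run configuration with two compute profiles.

``paper`` mirrors the published geometry (15-s 4000-Hz audio, 243 x 128
log-Mel grids, 3187 x 1840 pages, 512/256-px ECG views, full channel
profile). ``tiny`` keeps the identical pipeline but shrinks pages, view
sizes, spectrogram resolution, channel widths and oversampling factors so
the whole experiment graph runs on one CPU in minutes. The profile is
recorded in every output.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any

from cardiostack.cnn.model import DEFAULT_CHANNELS, TINY_CHANNELS, CnnConfig
from cardiostack.ecg import DEFAULT_SHIFT_COUNTS, EcgCropParams
from cardiostack.pcg import DEFAULT_SEGMENT_COUNTS, PcgPreprocParams
from cardiostack.synthetic import DISEASES, PAGE_HEIGHT, PAGE_WIDTH

__all__ = ["ExperimentConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    profile: str = "tiny"
    seed: int = 0
    diseases: tuple[str, ...] = DISEASES
    # generator
    n_patients: int = 60
    effect_size: float = 1.0
    duration_s: float = 15.0
    page_width: int = PAGE_WIDTH
    page_height: int = PAGE_HEIGHT
    # pcg front-end
    pcg_window_s: float = 4.0
    pcg_fft: int = 512
    pcg_hop: int = 64
    pcg_mels: int = 128
    segment_counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {d: dict(DEFAULT_SEGMENT_COUNTS[d]) for d in DISEASES}
    )
    # ecg front-end; None -> per-view defaults scaled to the page
    ecg_scale: float = 1.0
    shift_counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {d: dict(DEFAULT_SHIFT_COUNTS[d]) for d in DISEASES}
    )
    # cnn
    channels: tuple[int, ...] = DEFAULT_CHANNELS
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    mixup_alpha: float = 0.2
    freq_mask_width: int = 16
    time_mask_width: int = 24
    # evaluation / contribution
    test_fraction: float = 0.2
    bootstrap_B: int = 2000
    threshold: float = 0.5
    contribution_R: int = 50
    stacker_grid_rf: list[dict] | None = None
    stacker_grid_gbt: list[dict] | None = None

    def __post_init__(self) -> None:
        if self.profile not in ("paper", "tiny"):
            raise ConfigError(f"unknown profile {self.profile!r}")
        bad = [d for d in self.diseases if d not in DISEASES]
        if bad:
            raise ConfigError(f"unknown disease(s) {bad}")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if not (0 < self.test_fraction < 1):
            raise ConfigError("test_fraction must be in (0, 1)")
        if self.bootstrap_B < 1 or self.contribution_R < 1:
            raise ConfigError("bootstrap_B and contribution_R must be >= 1")

    # -- derived parameter bundles ------------------------------------------

    def pcg_params(self, disease: str) -> PcgPreprocParams:
        return PcgPreprocParams(
            window_length_s=self.pcg_window_s,
            fft_window=self.pcg_fft,
            hop=self.pcg_hop,
            n_mels=self.pcg_mels,
            segment_counts=dict(self.segment_counts[disease]),
        )

    def ecg_params(self, view: str, disease: str) -> EcgCropParams:
        """Crop geometry tied to the configured page: the 12-lead view is a
        full-height square, half views keep the published 960/1840 ratio, and
        offsets always fit the largest (x44) factor on the page width."""
        if view == "all12":
            side = self.page_height
            resize = max(2, round(512 * self.ecg_scale))
        else:
            side = round(self.page_height * 960 / 1840)
            resize = max(2, round(256 * self.ecg_scale))
        offset = max(1, (self.page_width - side) // 43)
        return EcgCropParams(
            view=view, crop_side=side, resize_to=resize, shift_offset=offset,
            shift_counts=dict(self.shift_counts[disease]),
        )

    def pcg_input_shape(self) -> tuple[int, int]:
        sr = 4000
        frames = 1 + (round(self.pcg_window_s * sr) - self.pcg_fft) // self.pcg_hop
        return (frames, self.pcg_mels)

    def ecg_input_shape(self, view: str) -> tuple[int, int]:
        side = self.ecg_params(view, "AS").resize_to
        return (side, side)

    def cnn_config(self, input_shape: tuple[int, int], seed: int) -> CnnConfig:
        return CnnConfig(
            input_shape=input_shape,
            channels=tuple(self.channels),
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=seed,
            mixup_alpha=self.mixup_alpha,
            freq_mask_width=self.freq_mask_width,
            time_mask_width=self.time_mask_width,
        )

    # -- profiles ------------------------------------------------------------

    @classmethod
    def paper(cls, **overrides: Any) -> "ExperimentConfig":
        return cls(profile="paper", **overrides)

    @classmethod
    def tiny(cls, **overrides: Any) -> "ExperimentConfig":
        """CPU-scale profile: same pipeline, reduced geometry and widths."""
        defaults: dict[str, Any] = dict(
            profile="tiny",
            page_width=720,
            page_height=416,
            pcg_window_s=2.0,
            pcg_fft=256,
            pcg_hop=128,
            pcg_mels=24,
            segment_counts={d: {"none": 2, "mild": 2, "moderate": 2, "severe": 6} for d in DISEASES},
            ecg_scale=64 / 512,  # view inputs become 64 px (all12) / 32 px (limb, precordial)
            shift_counts={d: {"none": 2, "mild": 2, "moderate": 2, "severe": 6} for d in DISEASES},
            channels=TINY_CHANNELS,
            epochs=8,
            learning_rate=3e-3,
            freq_mask_width=3,  # masks scaled to the 61 x 24 tiny grid
            time_mask_width=6,
            batch_size=16,
            bootstrap_B=200,
            contribution_R=10,
            stacker_grid_rf=[{"n_estimators": 50, "max_depth": 3}],
            stacker_grid_gbt=[{"n_estimators": 50, "max_depth": 2, "learning_rate": 0.1}],
        )
        defaults.update(overrides)
        return cls(**defaults)

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["diseases"] = list(self.diseases)
        d["channels"] = list(self.channels)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data)
        profile = data.pop("profile", "tiny")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("diseases", "channels"):
            if key in data:
                data[key] = tuple(data[key])
        if profile == "tiny":
            return cls.tiny(**data)
        return cls(profile=profile, **data)
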