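"""Configuration objects for every stage of the pipeline.

All configs are plain dataclasses that round-trip losslessly through
dictionaries (and hence YAML); ``ExperimentConfig.from_dict`` rejects
unknown keys so a typo in a config file fails loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields

from scipy.constants import c as SPEED_OF_LIGHT


def _validate_positive(obj, names):
    for name in names:
        if not getattr(obj, name) > 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be positive")


@dataclass
class RadarConfig:
    """FMCW waveform and array geometry.

    Defaults describe a 60 GHz sensor sweeping at 60.011 MHz/us, sampling
    108 complex IF points per chirp at 2 MS/s, firing 1500 chirps at 500 Hz
    (3 s per recording) into one TX and four RX channels.
    """

    start_frequency: float = 60e9          # Hz
    bandwidth: float = 3.96e9              # Hz (full ramp sweep)
    slope: float = 60.011e12               # Hz/s
    sample_rate: float = 2e6               # complex samples/s
    chirp_rep_frequency: float = 500.0     # Hz
    num_chirps: int = 1500
    num_tx: int = 1
    num_rx: int = 4
    num_adc_samples: int = 108

    def __post_init__(self):
        _validate_positive(self, [f.name for f in fields(self)])

    @property
    def wavelength(self) -> float:
        """Carrier wavelength [m]."""
        return SPEED_OF_LIGHT / self.start_frequency

    @property
    def range_bin_spacing(self) -> float:
        """Range per FFT bin [m], set by the ADC-limited swept bandwidth."""
        beat_resolution = self.sample_rate / self.num_adc_samples
        return SPEED_OF_LIGHT * beat_resolution / (2.0 * self.slope)

    @property
    def recording_duration(self) -> float:
        """Seconds covered by one cube."""
        return self.num_chirps / self.chirp_rep_frequency

    @property
    def max_unambiguous_range(self) -> float:
        """Largest range whose beat frequency stays below the sample rate [m]."""
        return SPEED_OF_LIGHT * self.sample_rate / (2.0 * self.slope)

    @property
    def max_unambiguous_speed(self) -> float:
        """|v| at the Doppler Nyquist edge [m/s]."""
        return self.wavelength * self.chirp_rep_frequency / 4.0

    def doppler_bin_spacing(self, doppler_window: int) -> float:
        """Doppler-frequency per bin [Hz] for a given slow-time window."""
        return self.chirp_rep_frequency / doppler_window

    def speed_bin_spacing(self, doppler_window: int) -> float:
        """Radial speed per Doppler bin [m/s]."""
        return self.wavelength * self.doppler_bin_spacing(doppler_window) / 2.0

    def range_to_bin(self, rng_m: float) -> float:
        """Fractional range-FFT bin for a target at ``rng_m`` meters."""
        return rng_m / self.range_bin_spacing

    def speed_to_doppler_offset(self, speed: float, doppler_window: int) -> float:
        """Fractional bin offset from the zero-velocity column (positive = away)."""
        doppler_hz = 2.0 * speed / self.wavelength
        return doppler_hz / self.doppler_bin_spacing(doppler_window)


@dataclass
class PipelineConfig:
    """Sliding-window range-Doppler preprocessing parameters."""

    doppler_window: int = 125      # chirps per Doppler FFT
    doppler_step: int = 40         # chirps between frame starts
    band_width: int = 48           # range bins kept around the primary bin
    log_offset: float = 1e-6       # additive floor inside the log
    window_fn: str | None = None   # None (rectangular) or "hann"

    def __post_init__(self):
        if self.doppler_window <= 0 or self.doppler_step < 1 or self.band_width <= 0:
            raise ValueError("window/step/band must be positive")
        if self.log_offset <= 0:
            raise ValueError("log_offset must be positive")
        if self.window_fn not in (None, "hann"):
            raise ValueError(f"unknown window_fn {self.window_fn!r}")


@dataclass
class DatasetSpec:
    """Synthetic-dataset composition.

    Defaults mirror the study conditions: 15 subjects, per subject 21 cough +
    82 non-cough recordings in the bed scene and 18 cough + 90 non-cough in
    the sitting scene (3165 recordings in total).
    """

    num_subjects: int = 15
    bed_cough: int = 21
    bed_noncough: int = 82
    sitting_cough: int = 18
    sitting_noncough: int = 90
    snr_db: float | None = 20.0
    master_seed: int = 0

    def __post_init__(self):
        counts = (self.num_subjects, self.bed_cough, self.bed_noncough,
                  self.sitting_cough, self.sitting_noncough)
        if any(v < 0 for v in counts):
            raise ValueError("counts must be non-negative")

    @property
    def per_subject_total(self) -> int:
        return (self.bed_cough + self.bed_noncough
                + self.sitting_cough + self.sitting_noncough)

    @property
    def total_records(self) -> int:
        return self.num_subjects * self.per_subject_total


@dataclass
class AugmentationConfig:
    """Sequence-consistent range translation + random erasing."""

    max_shift: int = 12
    p_translate: float = 0.5
    erase_area_range: tuple[float, float] = (0.05, 0.20)
    erase_aspect_range: tuple[float, float] = (0.3, 3.33)
    p_erase: float = 0.5

    def __post_init__(self):
        self.erase_area_range = tuple(self.erase_area_range)
        self.erase_aspect_range = tuple(self.erase_aspect_range)
        for p in (self.p_translate, self.p_erase):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.erase_area_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("erase_area_range must satisfy 0 < lo <= hi < 1")
        alo, ahi = self.erase_aspect_range
        if not (0.0 < alo <= ahi):
            raise ValueError("erase_aspect_range must be positive with lo <= hi")
        if self.max_shift < 0:
            raise ValueError("max_shift must be >= 0")


@dataclass
class ModelConfig:
    """Classifier architecture knobs."""

    feature_dim: int = 256
    num_heads: int = 4
    num_attention_layers: int = 2
    ffn_hidden_dim: int = 1024
    num_classes: int = 2
    spatial_backbone: str = "resnet34"   # "resnet34" or "resnet18"
    base_channels: int = 64              # stage-width scale of the trunk
    positional_encoding: str = "sinusoidal"  # "sinusoidal" or "none"
    variant: str = "full"                # "full", "resnet_only", "attention_only"

    def __post_init__(self):
        if self.feature_dim % self.num_heads:
            raise ValueError("feature_dim must be divisible by num_heads")
        if self.num_classes != 2:
            raise ValueError("binary cough/non-cough classifier: num_classes must be 2")
        if self.spatial_backbone not in ("resnet34", "resnet18"):
            raise ValueError(f"unknown backbone {self.spatial_backbone!r}")
        if self.positional_encoding not in ("sinusoidal", "none"):
            raise ValueError(f"unknown positional_encoding {self.positional_encoding!r}")
        if self.variant not in ("full", "resnet_only", "attention_only"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def backbone_depth(self) -> int:
        return 34 if self.spatial_backbone == "resnet34" else 18


@dataclass
class TrainConfig:
    """Adam training hyperparameters."""

    learning_rate: float = 1e-4
    weight_decay: float = 0.3
    batch_size: int = 32
    epochs: int = 15
    lr_schedule: str = "constant"   # "constant" or "warmup_cosine"
    max_grad_norm: float | None = None   # global-norm gradient clipping
    adam_betas: tuple[float, float] = (0.9, 0.999)
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate and batch_size must be positive")
        if self.epochs < 0 or self.weight_decay < 0:
            raise ValueError("epochs and weight_decay must be non-negative")
        if self.lr_schedule not in ("constant", "warmup_cosine"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")
        self.adam_betas = tuple(self.adam_betas)
        if not all(0.0 <= b < 1.0 for b in self.adam_betas):
            raise ValueError("adam_betas must lie in [0, 1)")


_BLOCKS = {
    "radar": RadarConfig,
    "pipeline": PipelineConfig,
    "dataset": DatasetSpec,
    "augment": AugmentationConfig,
    "model": ModelConfig,
    "train": TrainConfig,
}


@dataclass
class ExperimentConfig:
    """One experiment = one block of each stage config plus a master seed."""

    radar: RadarConfig = field(default_factory=RadarConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    dataset: DatasetSpec = field(default_factory=DatasetSpec)
    augment: AugmentationConfig = field(default_factory=AugmentationConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    master_seed: int = 0

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        return clean(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        if not isinstance(data, dict):
            raise TypeError("experiment config must be a mapping")
        unknown = set(data) - set(_BLOCKS) - {"master_seed"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, block_cls in _BLOCKS.items():
            if name in data:
                block = data[name]
                if not isinstance(block, dict):
                    raise TypeError(f"config block {name!r} must be a mapping")
                valid = {f.name for f in fields(block_cls)}
                bad = set(block) - valid
                if bad:
                    raise ValueError(f"unknown keys in {name!r}: {sorted(bad)}")
                kwargs[name] = block_cls(**block)
        return cls(master_seed=data.get("master_seed", 0), **kwargs)

    def config_hash(self) -> str:
        """Short stable digest of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_experiment_config(path) -> ExperimentConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ExperimentConfig.from_dict(data)


def save_experiment_config(cfg: ExperimentConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
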