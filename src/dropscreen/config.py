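"""Configuration objects shared across the pipeline.

All stage parameters live in small validated dataclasses that can be
round-tripped through a single YAML/JSON config file.  Defaults reproduce the
study conditions the package simulates: 80 µm droplets imaged at 1 µm/pixel
with three stains (effector lineage, target lineage, apoptosis reporter) next
to brightfield, Poisson co-encapsulation at a 1:2 effector:target ratio, and
an 8 h killing assay with a small serial-killer subpopulation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "BRIGHTFIELD",
    "EFFECTOR_STAIN",
    "TARGET_STAIN",
    "APOPTOSIS_STAIN",
    "DEFAULT_CHANNELS",
    "RenderConfig",
    "KillingModel",
    "TrainingConfig",
    "SortErrorModel",
    "ExperimentConfig",
    "load_config",
    "save_config",
    "config_hash",
]

BRIGHTFIELD = "brightfield"
EFFECTOR_STAIN = "effector_stain"
TARGET_STAIN = "target_stain"
APOPTOSIS_STAIN = "apoptosis_stain"
DEFAULT_CHANNELS = (BRIGHTFIELD, EFFECTOR_STAIN, TARGET_STAIN, APOPTOSIS_STAIN)

#: Artifact classes a droplet image can carry.  ``none`` means usable.
OUTLIER_CLASSES = ("none", "bubble", "edge_cutoff", "double_layer_blur")


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


def _level_map(value, channels, default_bf, default_fluo) -> dict:
    """Expand a scalar or partial mapping into a per-channel intensity map."""
    if value is None:
        value = {}
    if isinstance(value, (int, float)):
        return {ch: float(value) for ch in channels}
    out = {}
    for ch in channels:
        if ch in value:
            out[ch] = float(value[ch])
        else:
            out[ch] = float(default_bf if ch == BRIGHTFIELD else default_fluo)
    return out


@dataclass
class RenderConfig:
    """Geometry, optics and artifact parameters of the synthetic microscope.

    Intensities are raw camera counts on a ``bit_depth``-bit scale.  For
    fluorescence channels ``signal_level`` is the in-cell intensity; for
    brightfield it is the intensity of the dark droplet rim (the "signal"
    being rim contrast against the bright background).
    """

    pixel_size: float = 1.0  # µm per pixel
    field_size: tuple[int, int] = (960, 960)  # (H, W) pixels
    crop_size: int = 96  # pixels, per-droplet crop / tile
    droplet_diameter: float = 80.0  # µm
    cell_diameter_range: tuple[float, float] = (8.0, 14.0)  # µm
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    bit_depth: int = 16
    background_level: Mapping[str, float] | float | None = None
    signal_level: Mapping[str, float] | float | None = None
    noise_sd: float = 60.0  # counts
    blur_sigma: float = 1.0  # pixels
    cell_brightfield_contrast: float = 0.2  # fractional dimming of cells in BF
    max_overlap: float = 0.3  # max overlap depth as fraction of smaller radius
    outlier_rates: Mapping[str, float] = field(
        default_factory=lambda: {"bubble": 0.0, "edge_cutoff": 0.0, "double_layer_blur": 0.0}
    )
    seed: int = 0

    def __post_init__(self):
        self.background_level = _level_map(
            self.background_level, self.channel_names, default_bf=20000.0, default_fluo=400.0
        )
        self.signal_level = _level_map(
            self.signal_level, self.channel_names, default_bf=8000.0, default_fluo=4000.0
        )
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be positive")
        if self.droplet_diameter <= 2.0 * self.cell_diameter_range[1]:
            raise ConfigError("droplet must be wider than two max-size cells")
        if not (0 < self.cell_diameter_range[0] <= self.cell_diameter_range[1]):
            raise ConfigError("cell_diameter_range must be an increasing positive pair")
        for ch in self.channel_names:
            gap = abs(self.signal_level[ch] - self.background_level[ch])
            if gap <= 5.0 * self.noise_sd:
                raise ConfigError(
                    f"channel {ch!r}: |signal-background| must exceed 5*noise_sd "
                    f"for thresholding to be well-posed"
                )
        rates = dict(self.outlier_rates)
        for k, v in rates.items():
            if k not in OUTLIER_CLASSES[1:]:
                raise ConfigError(f"unknown outlier class {k!r}")
            if not 0.0 <= v <= 1.0:
                raise ConfigError("outlier rates must lie in [0, 1]")
        if sum(rates.values()) > 1.0 + 1e-12:
            raise ConfigError("outlier rates must sum to at most 1")
        self.outlier_rates = rates

    # -- derived geometry ---------------------------------------------------
    @property
    def droplet_radius_px(self) -> float:
        return self.droplet_diameter / (2.0 * self.pixel_size)

    @property
    def max_intensity(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def fluorescence_channels(self) -> tuple[str, ...]:
        return tuple(ch for ch in self.channel_names if ch != BRIGHTFIELD)


@dataclass
class KillingModel:
    """Stochastic model of per-droplet NK-cell cytotoxicity.

    Effectors carry one of three phenotypes.  Killers eliminate available live
    targets with independent exponential waiting times at ``kill_rate`` until
    their capacity is exhausted or no live target remains; a dead effector
    kills no further.  All cells are additionally subject to baseline
    (spontaneous) exponential death.  Only the serial-killer fraction (0.09)
    is anchored to observed parent populations; the remaining defaults are
    chosen to emulate high target viability and mildly reduced effector
    viability late in an 8 h assay.
    """

    phenotype_fractions: tuple[float, float, float] = (0.65, 0.26, 0.09)
    kill_rate: float = 0.5  # h^-1 per pending kill
    serial_capacity: int = 3  # max kills of a serial killer
    baseline_target_death_rate: float = 0.003  # h^-1
    baseline_effector_death_rate: float = 0.01  # h^-1
    duration: float = 8.0  # h
    timestep: float = 1.0  # h

    #: canonical phenotype order matching ``phenotype_fractions``
    PHENOTYPES = ("non_killer", "single_killer", "serial_killer")

    def __post_init__(self):
        fr = tuple(float(f) for f in self.phenotype_fractions)
        if len(fr) != 3 or any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ConfigError("phenotype_fractions must be 3 non-negative numbers summing to 1")
        self.phenotype_fractions = fr
        for name in ("kill_rate", "baseline_target_death_rate", "baseline_effector_death_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.serial_capacity < 2:
            raise ConfigError("serial_capacity must be at least 2")
        if self.duration <= 0 or self.timestep <= 0:
            raise ConfigError("duration and timestep must be positive")

    def capacity(self, phenotype: str) -> int:
        return {"non_killer": 0, "single_killer": 1, "serial_killer": self.serial_capacity}[
            phenotype
        ]

    @property
    def time_grid(self):
        import numpy as np

        n = int(round(self.duration / self.timestep))
        return np.linspace(0.0, n * self.timestep, n + 1)


@dataclass
class TrainingConfig:
    """Hyper-parameters of the NumPy CNN classifiers."""

    crop_size: int = 96
    downsample: int = 2  # average-pool factor applied before the network
    c_max: int = 5  # top class means "c_max or more"
    epochs: int = 12
    batch_size: int = 64
    learning_rate: float = 2e-3
    augment_rotations: bool = True
    augment_flips: bool = True
    conv_channels: tuple[int, int, int] = (10, 20, 40)
    shared_trunk: bool = True  # four heads on one trunk; False = separate trunks
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.c_max < 4:
            raise ConfigError("c_max must be at least 4")
        if self.epochs < 1:
            raise ConfigError("epochs must be at least 1")
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise ConfigError("invalid optimiser settings")


@dataclass
class SortErrorModel:
    """Timing-error budget of the sorter, abstracted to per-droplet probabilities.

    ``misroute_probability`` models trigger/delay mis-synchronisation: with
    this probability a droplet is routed by the electrode pattern meant for
    the *previous* droplet in the stream (a one-period window shift), so
    wrongly collected droplets appear in proportion to the positive rate —
    about one misrouted droplet per hundred sorted at the default.
    ``frame_drop_probability`` models a droplet passing the detection ROI
    without being imaged (it is then routed to the negative channel by the
    default electrode state).
    """

    misroute_probability: float = 0.01
    frame_drop_probability: float = 0.005

    def __post_init__(self):
        for name in ("misroute_probability", "frame_drop_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")


@dataclass
class ExperimentConfig:
    """Top-level config tying the stages into one experiment."""

    n_droplets: int = 5000
    conc_effector: float = 3.0e6  # cells / mL
    conc_target: float = 6.0e6  # cells / mL
    sort_time: float = 6.0  # h, incubation before sorting
    calibration_droplets: int = 1500
    gate_margin: float = 6.0  # feature units added around calibration hulls
    render: RenderConfig = field(default_factory=RenderConfig)
    killing: KillingModel = field(default_factory=KillingModel)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    sort_errors: SortErrorModel = field(default_factory=SortErrorModel)

    def __post_init__(self):
        if self.n_droplets < 1:
            raise ConfigError("n_droplets must be at least 1")
        if self.conc_effector < 0 or self.conc_target < 0:
            raise ConfigError("concentrations must be non-negative")


_SECTIONS = {
    "render": RenderConfig,
    "killing": KillingModel,
    "training": TrainingConfig,
    "sort_errors": SortErrorModel,
}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an :class:`ExperimentConfig` from a YAML (or JSON) file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, val in raw.items():
        if key in _SECTIONS:
            section = dict(val or {})
            for tup_field in ("field_size", "cell_diameter_range", "channel_names",
                              "phenotype_fractions", "conv_channels"):
                if tup_field in section and isinstance(section[tup_field], list):
                    section[tup_field] = tuple(section[tup_field])
            kwargs[key] = _SECTIONS[key](**section)
        else:
            kwargs[key] = val
    return ExperimentConfig(**kwargs)


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=False))


def config_hash(cfg) -> str:
    """Stable short hash of a config dataclass, for run manifests."""
    payload = json.dumps(_to_plain(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
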