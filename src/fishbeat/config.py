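"""Pipeline configuration.

All tunable thresholds live here, grouped the way the stages consume them.
Values are dimensionless fractions unless a unit is given. A YAML file with
the same nesting (``hough: {radius_range: [...], ...}``) can be loaded with
:func:`load_config`; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class HoughConfig:
    #: (min, max) circle radius as a fraction of the short image side.
    radius_range: tuple[float, float] = (0.15, 0.45)
    #: every k-th non-empty frame votes in the circle detection.
    frame_stride: int = 5
    #: spacing of candidate radii in pixels.
    radius_step: int = 4
    #: integer downscale factor for the edge/Hough stage (1 = full size);
    #: detection at reduced resolution, coordinates mapped back.
    downscale: int = 2


@dataclass
class CropConfig:
    #: margin around the detected circle, as a fraction of its radius.
    margin_fraction: float = 0.10


@dataclass
class DiffConfig:
    #: rolling-difference window in frames (>= 2).
    window: int = 2
    #: Gaussian blur sigma in pixels applied before differencing.
    blur_sigma: float = 2.0


@dataclass
class MaskConfig:
    #: connected components smaller than this many pixels are dropped.
    min_object_px: int = 50
    #: radius in pixels of the disc structuring element for opening.
    opening_radius: int = 2


@dataclass
class FtConfig:
    #: acceptable dominant-frequency band in Hz (heart rates 30-300 bpm).
    band_hz: tuple[float, float] = (0.5, 5.0)
    #: minimum peak-to-background SNR for a pixel to count as periodic.
    snr_min: float = 2.0
    #: optional SNR upper bound (None = open).
    snr_max: float | None = None


@dataclass
class KdeConfig:
    #: Gaussian kernel bandwidth in Hz; None = one frequency-bin width.
    bandwidth_hz: float | None = None
    #: number of evaluation grid points across the band.
    grid_points: int = 512
    #: weight each pixel's frequency vote by its peak amplitude.
    amplitude_weighted: bool = False


@dataclass
class PhaseConfig:
    max_clusters: int = 3
    #: phase clustering is attempted only with at least this many pixels.
    min_pixels: int = 100


@dataclass
class QcConfig:
    floor_bpm: float = 70.0
    #: tolerance on |hi/lo - 2| for the double-harmonic relation.
    ratio_tol: float = 0.15
    #: relative tolerance around the group reference bpm.
    group_tol: float = 0.20
    #: movement before this many seconds voids the measurement.
    min_stable_seconds: float = 5.0
    #: frame-to-frame shift above this fraction of crop width = movement.
    movement_px_fraction: float = 0.05


@dataclass
class PipelineConfig:
    """Every knob of the plate pipeline, with field-realistic defaults."""

    #: frames whose mean intensity (on [0, 1]) falls below this are "empty".
    empty_threshold: float = 0.01
    #: the well is invalidated when >= this fraction of frames is empty.
    max_empty_fraction: float = 0.05
    hough: HoughConfig = field(default_factory=HoughConfig)
    crop: CropConfig = field(default_factory=CropConfig)
    diff: DiffConfig = field(default_factory=DiffConfig)
    mask: MaskConfig = field(default_factory=MaskConfig)
    ft: FtConfig = field(default_factory=FtConfig)
    kde: KdeConfig = field(default_factory=KdeConfig)
    phase: PhaseConfig = field(default_factory=PhaseConfig)
    qc: QcConfig = field(default_factory=QcConfig)

    def __post_init__(self) -> None:
        lo, hi = self.ft.band_hz
        if not 0 < lo < hi:
            raise ValueError(f"invalid frequency band: {self.ft.band_hz}")
        if self.diff.window < 2:
            raise ValueError("diff.window must be >= 2")
        if not 0 < self.max_empty_fraction <= 1:
            raise ValueError("max_empty_fraction must be in (0, 1]")


def _update_dataclass(obj, data: dict, path: str = ""):
    fields = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in fields:
            raise KeyError(f"unknown config key: {path}{key}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _update_dataclass(current, value, path=f"{path}{key}.")
        elif isinstance(current, tuple) and isinstance(value, (list, tuple)):
            setattr(obj, key, tuple(value))
        else:
            setattr(obj, key, value)
    return obj


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from an optional YAML file + overrides.

    Overrides use the same nested-dict shape as the YAML and win over it.
    """
    cfg = PipelineConfig()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        _update_dataclass(cfg, data)
    if overrides:
        _update_dataclass(cfg, overrides)
    cfg.__post_init__()
    return cfg
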