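"""YAML-backed run configuration.

A flat key/value file controls the solver and imaging defaults, e.g.::

    max_degree: 24
    quadrature_order: 100
    constraint_tolerance: 1.0e-4
    sphere_tol: 0.01
    pin_threshold: 0.8
    neck_prominence: 0.15
    pixel_size: 0.2
    z_step: 1.0

Unknown keys raise immediately — silent typos in threshold names have
outsized effects on classification.  ``echo_settings`` renders the
effective configuration for run logs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .minimize import OptimizerSettings
from .quant import SegmentationConfig
from .synth import ImagingConfig

_OPTIMIZER_KEYS = {f.name for f in fields(OptimizerSettings)}
_IMAGING_KEYS = {f.name for f in fields(ImagingConfig)}
_SEGMENT_KEYS = {f.name for f in fields(SegmentationConfig)}
_CLASSIFIER_KEYS = {"sphere_tol", "pin_threshold", "neck_prominence", "fold_depth"}


@dataclass
class RunConfig:
    optimizer: OptimizerSettings = field(default_factory=OptimizerSettings)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    classifier: dict = field(default_factory=dict)


def load_config(path=None) -> RunConfig:
    """Build a RunConfig from a flat YAML file (defaults when path is None)."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping of key: value pairs")
    opt, img, seg, cls = {}, {}, {}, {}
    for key, value in data.items():
        if key in _OPTIMIZER_KEYS:
            opt[key] = value
        elif key in _IMAGING_KEYS:
            img[key] = value
        elif key in _SEGMENT_KEYS:
            seg[key] = value
        elif key in _CLASSIFIER_KEYS:
            cls[key] = value
        else:
            raise KeyError(f"unknown configuration key: {key!r}")
    if "frame_shape" in img:
        img["frame_shape"] = tuple(img["frame_shape"])
    return RunConfig(
        optimizer=OptimizerSettings(**opt),
        imaging=ImagingConfig(**img),
        segmentation=SegmentationConfig(**seg),
        classifier=cls,
    )


def echo_settings(config: RunConfig) -> str:
    """Human-readable dump of the effective settings (for run logs)."""
    parts = {
        "optimizer": asdict(config.optimizer),
        "imaging": asdict(config.imaging),
        "segmentation": asdict(config.segmentation),
        "classifier": config.classifier,
    }
    return yaml.safe_dump(parts, sort_keys=True)
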