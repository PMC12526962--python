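"""YAML-backed configuration for the model and training runs.

Config files mirror the dataclass tree::

    backbone: {depth: 101, cbam_enabled: true, reduction_r: 16, ...}
    neck:     {type: acfpn, out_channels: 256, cem: {dilations: [...]}}
    detector: {num_classes: 4, score_thresh: 0.5, ...}
    train:    {batch_size: 4, base_lr: 0.004, epochs: 70, input_size: 512}

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import pathlib

import yaml

from .backbone import BackboneConfig
from .detector import DetectorConfig, ModelConfig, TrainConfig
from .neck import CEMConfig, NeckConfig


def _build(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise KeyError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        if k == "cem" and isinstance(v, dict):
            v = _build(CEMConfig, v)
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


def model_config_from_dict(d: dict) -> ModelConfig:
    return ModelConfig(
        backbone=_build(BackboneConfig, d.get("backbone", {})),
        neck=_build(NeckConfig, d.get("neck", {})),
        detector=_build(DetectorConfig, d.get("detector", {})),
    )


def train_config_from_dict(d: dict) -> TrainConfig:
    return _build(TrainConfig, d)


def load_config(path: str | pathlib.Path) -> tuple[ModelConfig, TrainConfig]:
    data = yaml.safe_load(pathlib.Path(path).read_text()) or {}
    model = model_config_from_dict(
        {k: data[k] for k in ("backbone", "neck", "detector") if k in data})
    train = train_config_from_dict(data.get("train", {}))
    return model, train


def dump_config(model: ModelConfig, train: TrainConfig,
                path: str | pathlib.Path):
    payload = dataclasses.asdict(model)
    payload["train"] = dataclasses.asdict(train)

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    pathlib.Path(path).write_text(yaml.safe_dump(clean(payload),
                                                 sort_keys=True))


def micro_model_config(input_size: int = 256) -> ModelConfig:
    """A config-scaled model small enough for CPU training runs: reduced
    channel widths everywhere, full architecture otherwise."""
    return ModelConfig(
        backbone=BackboneConfig(depth=50, width_mult=0.125),
        neck=NeckConfig(out_channels=48, latent_channels=16,
                        cem=CEMConfig(dilations=(1, 2, 4))),
        detector=DetectorConfig(
            rpn_channels=48, head_dim=192, mask_channels=48,
            rpn_pre_nms_topk=400, rpn_post_nms_topk=100, roi_batch=32,
            roi_pos_frac=0.5, train_gt_jitter=8),
    )
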