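"""Quantification configuration: every numeric threshold in one place.

The ``reference`` preset freezes the published protocol values (blur sigma 1,
rolling radius 50, Yen dark + floors 15/20, >50% overlap, 1.1x background,
run > 3 um, comigration > 2 um, flux line 10 um / 30 s window, 20-px line
scans with 0.5-um bins, 0.5 x 1 um septal rectangle, 0.3 s frame interval).
Configs serialize losslessly to YAML with a frozen schema version.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from hyphaquant.errors import ConfigError
from hyphaquant.motility import TrackingParams
from hyphaquant.segcoloc import CooccurrenceRule, SegmentationParams

SCHEMA_VERSION = 1


@dataclass
class QuantConfig:
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    cooccurrence: CooccurrenceRule = field(default_factory=CooccurrenceRule)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    run_min_um: float = 3.0
    comig_min_um: float = 2.0
    flux_line_um: float = 10.0
    flux_window_s: float = 30.0
    linescan_width_px: int = 20
    linescan_bin_um: float = 0.5
    septal_rect_um: tuple = (0.5, 1.0)
    pixel_size_um: float = 0.11
    frame_interval_s: float = 0.3
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["septal_rect_um"] = list(self.septal_rect_um)
        return d

    def to_yaml(self, path=None):
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        version = d.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ConfigError(f"unsupported config schema version {version}")
        try:
            seg = SegmentationParams(**d.pop("segmentation", {}))
            rule = CooccurrenceRule(**d.pop("cooccurrence", {}))
            tp = TrackingParams(**d.pop("tracking", {}))
            cfg = cls(segmentation=seg, cooccurrence=rule, tracking=tp, **d)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        cfg.septal_rect_um = tuple(cfg.septal_rect_um)
        return cfg

    @classmethod
    def from_yaml(cls, path_or_text):
        text = path_or_text
        try:
            with open(path_or_text) as fh:
                text = fh.read()
        except (OSError, TypeError):
            pass
        return cls.from_dict(yaml.safe_load(text))


def reference_config(seed=0):
    """The frozen published-protocol preset."""
    return QuantConfig(seed=seed)


PRESETS = {"reference": reference_config}


def _flatten(d, prefix=""):
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out


def validate_config(config):
    """Check invariants and report every deviation from the reference preset.

    Returns ``{"errors": [...], "deviations": [...]}``; deviations are
    strings ``field: value (reference ref_value)``.  Invalid numeric values
    raise on dataclass construction, so errors here cover cross-field checks.
    """
    errors = []
    for name in ("run_min_um", "comig_min_um", "flux_line_um", "flux_window_s",
                 "linescan_bin_um", "pixel_size_um", "frame_interval_s"):
        if getattr(config, name) <= 0:
            errors.append(f"{name} must be positive")
    if config.linescan_width_px < 1:
        errors.append("linescan_width_px must be >= 1")
    if len(config.septal_rect_um) != 2 or any(v <= 0 for v in config.septal_rect_um):
        errors.append("septal_rect_um must be two positive extents")

    ref = _flatten(reference_config(seed=config.seed).to_dict())
    cur = _flatten(config.to_dict())
    deviations = [
        f"{key}: {cur[key]} (reference {ref[key]})"
        for key in sorted(ref)
        if key in cur and cur[key] != ref[key]
    ]
    return {"errors": errors, "deviations": deviations}
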