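"""YAML configuration for scenes, rigs, detector settings and colour ranges.

One plain-text file describes a whole measurement setup; every section is
optional and falls back to the documented defaults.  Schema::

    body:      {a, b, z_range: [z0, z1], checkerboard_interval}
    layout:    {horizontal_offsets: [..]|null, vertical_offsets: [..],
                first_row, base_col, marker_radius: null|metres}
    rig:       {shooting_distance, baseline, focal, width, height, verged}
    session:   {angles: [..]|null, noise_sigma, supersample, seed, body_part}
    detector:  {smooth_sigma, window_size, quality, min_distance,
                refine_window, refine_max_iter, refine_eps, mask_erosion}
    hsv:       {red_h1: [lo, hi], red_h2, red_s, red_v, cyan_h, ...}
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .corners import DetectorParams
from .markers import HSVRanges
from .scene import BodySegmentModel, MarkerLayout, TurntableRig, make_turntable_rig

__all__ = ["SessionConfig", "load_config", "save_config"]


@dataclass
class SessionConfig:
    """Everything needed to simulate and measure one session."""

    model: BodySegmentModel = field(default_factory=BodySegmentModel)
    layout: MarkerLayout = field(default_factory=MarkerLayout)
    rig_params: dict = field(default_factory=dict)
    angles: list | None = None
    noise_sigma: float = 0.0
    supersample: int = 3
    seed: int = 0
    body_part: str = "waist"
    detector: DetectorParams = field(default_factory=DetectorParams)
    hsv: HSVRanges = field(default_factory=HSVRanges)

    def make_rig(self) -> TurntableRig:
        return make_turntable_rig(**self.rig_params)


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def load_config(path) -> SessionConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    cfg = SessionConfig()
    if "body" in doc:
        cfg.model = BodySegmentModel(**_tuplify(doc["body"]))
    if "layout" in doc:
        cfg.layout = MarkerLayout(**_tuplify(doc["layout"]))
    cfg.rig_params = doc.get("rig", {})
    sess = doc.get("session", {})
    cfg.angles = sess.get("angles")
    cfg.noise_sigma = sess.get("noise_sigma", 0.0)
    cfg.supersample = sess.get("supersample", 3)
    cfg.seed = sess.get("seed", 0)
    cfg.body_part = sess.get("body_part", "waist")
    if "detector" in doc:
        cfg.detector = DetectorParams(**doc["detector"])
    if "hsv" in doc:
        cfg.hsv = HSVRanges(**_tuplify(doc["hsv"]))
    return cfg


def save_config(cfg: SessionConfig, path) -> None:
    doc = {
        "body": {
            "a": cfg.model.a,
            "b": cfg.model.b,
            "z_range": list(cfg.model.z_range),
            "checkerboard_interval": cfg.model.checkerboard_interval,
            "baseline_z": cfg.model.baseline_z,
        },
        "layout": {
            "horizontal_offsets": (
                list(cfg.layout.horizontal_offsets)
                if cfg.layout.horizontal_offsets is not None
                else None
            ),
            "vertical_offsets": list(cfg.layout.vertical_offsets),
            "first_row": cfg.layout.first_row,
            "base_col": cfg.layout.base_col,
            "marker_radius": cfg.layout.marker_radius,
        },
        "rig": cfg.rig_params,
        "session": {
            "angles": cfg.angles,
            "noise_sigma": cfg.noise_sigma,
            "supersample": cfg.supersample,
            "seed": cfg.seed,
            "body_part": cfg.body_part,
        },
        "detector": asdict(cfg.detector),
        "hsv": {k: list(v) for k, v in asdict(cfg.hsv).items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
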