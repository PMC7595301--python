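"""Shared YAML/JSON run configuration.

One file with per-command sections; command-line flags override file values.

Recognized keys (all optional, defaults in parentheses):

- ``geometry``: ``length_m`` (120), ``width_m`` (3), ``danger_zone_m`` (0.8),
  ``total_area_m2`` (length x width)
- ``f_hz`` (10)
- ``bin_edges_m`` ([0, 0.5, 1.0, 1.5, 2.0, 2.5]), ``physical_distance_m`` (1.5)
- ``classify``: ``lambda1``, ``lambda2``, ``alpha_s``,
  ``repeated_degree_threshold``, ``min_family_persistence_s``, ``d``
- ``window``: ``enabled``, ``occupancy_threshold``, ``quiet_duration_s``
- ``mc``: ``n``, ``n_realizations``, ``min_dist_m``, ``bin_width_m``, ``r_max_m``
- ``scenario``: any :class:`~proxigraph.synthetic_crowd.ScenarioConfig` field
  except ``geometry`` and ``f`` (taken from the top level)
"""

from __future__ import annotations

import json

import yaml

from .contact_classify import ClassificationParams
from .interaction_graph import DistanceBinning
from .synthetic_crowd import ScenarioConfig
from .trajectory_io import PlatformGeometry

__all__ = ["load_config", "geometry_from", "binning_from", "params_from", "scenario_from"]


def load_config(path: str | None) -> dict:
    if path is None:
        return {}
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    cfg = json.loads(text) if path.endswith(".json") else yaml.safe_load(text)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def geometry_from(cfg: dict) -> PlatformGeometry:
    return PlatformGeometry(**cfg.get("geometry", {}))


def binning_from(cfg: dict) -> DistanceBinning:
    kwargs = {}
    if "bin_edges_m" in cfg:
        kwargs["edges_m"] = tuple(cfg["bin_edges_m"])
    if "physical_distance_m" in cfg:
        kwargs["physical_distance_m"] = cfg["physical_distance_m"]
    return DistanceBinning(**kwargs)


def params_from(cfg: dict) -> ClassificationParams:
    section = dict(cfg.get("classify", {}))
    section.pop("d", None)
    return ClassificationParams(**section)


def scenario_from(cfg: dict, seed: int | None = None) -> ScenarioConfig:
    section = dict(cfg.get("scenario", {}))
    section.pop("geometry", None)
    section.pop("f", None)
    for key in ("family_sizes", "waiting_band_m", "train_times_s", "entry_points",
                "entry_window_s", "speed_range_mps"):
        if key in section and section[key] is not None:
            section[key] = tuple(tuple(v) if isinstance(v, (list, tuple)) else v for v in section[key]) \
                if key == "entry_points" else tuple(section[key])
    if seed is not None:
        section["seed"] = seed
    return ScenarioConfig(geometry=geometry_from(cfg), f=cfg.get("f_hz", 10.0), **section)
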