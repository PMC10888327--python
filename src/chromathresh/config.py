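"""YAML/JSON configuration loading.

A config file may carry any of these top-level blocks::

    display:                 # DisplayModel fields
      width_px: 2736
      height_px: 1824
      diagonal_in: 12.3
      gamma: 2.2
      peak_luminance: 120.0
    viewing_distance_cm: 50.0
    cohort:                  # list of group blocks
      - label: trichromat
        count: 65
        mean: [4.44, 5.38, 8.45]
        sd: [1.53, 1.46, 2.36]
        range: [[2.54, 10.63], [2.51, 9.40], [3.30, 13.04]]

Unspecified fields keep their defaults.
"""

from __future__ import annotations

import dataclasses

import yaml

from .colorimetry import DisplayModel
from .observer_sim import CohortSpec, DEFAULT_COHORT_SPEC, GroupSpec
from .stimulus import ViewingGeometry

__all__ = [
    "load_config",
    "display_from_dict",
    "geometry_from_config",
    "cohort_spec_from_config",
]


def load_config(path: str) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return data


def display_from_dict(block: dict | None) -> DisplayModel:
    block = dict(block or {})
    known = {f.name for f in dataclasses.fields(DisplayModel)}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown display keys: {sorted(unknown)}")
    for key in ("white_xy",):
        if key in block:
            block[key] = tuple(block[key])
    if "rgb_primaries_xy" in block:
        block["rgb_primaries_xy"] = tuple(tuple(p) for p in block["rgb_primaries_xy"])
    return DisplayModel(**block)


def geometry_from_config(config: dict | None) -> ViewingGeometry:
    config = config or {}
    return ViewingGeometry(
        viewing_distance_cm=float(config.get("viewing_distance_cm", 50.0)),
        display=display_from_dict(config.get("display")),
    )


def cohort_spec_from_config(config: dict | None) -> CohortSpec:
    config = config or {}
    if "cohort" not in config:
        return DEFAULT_COHORT_SPEC
    groups = []
    for block in config["cohort"]:
        groups.append(
            GroupSpec(
                label=str(block["label"]),
                count=int(block["count"]),
                mean=tuple(float(v) for v in block["mean"]),
                sd=tuple(float(v) for v in block["sd"]),
                range=tuple((float(lo), float(hi)) for lo, hi in block["range"]),
            )
        )
    return CohortSpec(groups=tuple(groups))
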