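"""Flat, namespaced run configuration.

All tunable parameters of the pipeline live in a single flat mapping with
``module.key`` names.  Unknown keys are rejected, and every CLI run writes
the fully resolved configuration next to its outputs so a run can be
reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

from .errors import ParameterError

#: Default values for every recognised configuration key.
DEFAULTS: dict[str, Any] = {
    # speckle denoising (median then Gaussian)
    "preprocess.median_window": 3,
    "preprocess.gaussian_sigma": 1.5,
    # layer detection and RPE spline fit
    "segmentation.ilm_threshold": 0.25,
    "segmentation.mask_offset_px": 25,
    "segmentation.n_per_ascan": 3,
    "segmentation.band_halfwidth": 15,
    "segmentation.gap_min": 20,
    "segmentation.intensity_floor_rel": 0.5,
    "segmentation.n_knots": 5,
    "segmentation.smooth_penalty": 1.0,
    "segmentation.order_single_segment": 3,
    "segmentation.order_multi_segment": 2,
    # edema quantification
    "quantify.threshold_px": 20,
    "quantify.margin_frac": 0.10,
    "quantify.threshold_sign": "below_reference",
}


def resolve_config(overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Merge ``overrides`` onto :data:`DEFAULTS`, rejecting unknown keys."""
    cfg = dict(DEFAULTS)
    if overrides:
        unknown = sorted(set(overrides) - set(DEFAULTS))
        if unknown:
            raise ParameterError(f"unknown configuration keys: {unknown}")
        cfg.update(overrides)
    return cfg


def load_config_file(path: str | Path) -> dict[str, Any]:
    """Read a TOML or JSON config file into a flat override mapping.

    TOML tables are flattened to ``table.key`` names so both
    ``quantify.threshold_px = 10`` and ``[quantify] threshold_px = 10``
    spellings work.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        import tomllib

        data = tomllib.loads(text)
    flat: dict[str, Any] = {}
    for key, value in data.items():
        if isinstance(value, dict):
            for sub, subval in value.items():
                flat[f"{key}.{sub}"] = subval
        else:
            flat[key] = value
    return flat


def config_digest(cfg: Mapping[str, Any]) -> str:
    """Short stable hash of a resolved configuration."""
    blob = json.dumps(dict(cfg), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_resolved_config(cfg: Mapping[str, Any], path: str | Path) -> None:
    from . import __version__

    payload = {"version": __version__, "config": dict(sorted(cfg.items()))}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
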