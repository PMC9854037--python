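"""Run configuration and manifest logging.

A YAML config selects the channel, history counts, seeds, scoring grids and
interpolation options; CLI flags override config values.  Every CLI run logs
the seed, a config hash and the package version to stderr and writes a
run-manifest JSON next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path

import yaml

from . import __version__

__all__ = ["DEFAULTS", "load_config", "config_hash", "write_manifest"]

DEFAULTS = {
    "channel": "1_2",
    "n_histories": 1_000_000,
    "seed": 1,
    "scoring_distance_cm": 100.0,
    "radii_cm": [0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0,
                 4.0, 5.0, 6.0, 7.0, 8.0, 10.0],
    "thetas_deg": [0, 5, 10, 15, 20, 25, 30, 40, 50, 60, 70, 80, 90,
                   100, 110, 120, 130, 140, 150, 155, 160, 165, 170, 175],
    "fit_range_cm": [0.25, 10.0],
}


def load_config(path=None, **overrides) -> dict:
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg.update(user)
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_manifest(out_dir, cfg: dict, command: str) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": cfg.get("seed"),
        "config_hash": config_hash(cfg),
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": cfg,
    }
    print(f"[brachydose {__version__}] {command} seed={cfg.get('seed')} "
          f"config={manifest['config_hash']}", file=sys.stderr)
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
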