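"""Delimited-text table I/O with metadata headers, and YAML run configs.

All pipeline artifacts are plain CSV with '#'-prefixed header lines
carrying run metadata (seed, config hash, stage), so outputs are
diff-able and self-describing.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .synthgen import APCTruth
from .tabulate import APCDesign, build_design


def config_hash(config: Mapping) -> str:
    """Short stable hash of a config mapping (order-insensitive)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, meta: Mapping | None = None) -> Path:
    """Write a CSV with '# key: value' metadata lines before the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        for k, v in (meta or {}).items():
            f.write(f"# {k}: {v}\n")
        df.to_csv(f, index=False)
    return path


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV written by :func:`write_table`; returns (table, metadata)."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as f:
        pos = f.tell()
        line = f.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            pos = f.tell()
            line = f.readline()
        f.seek(pos)
        df = pd.read_csv(f)
    return df, meta


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def design_from_config(cfg: Mapping) -> APCDesign:
    d = cfg["design"]
    return build_design(int(d["age_min"]), int(d["age_max"]),
                        int(d["period_min"]), int(d["period_max"]))


def truth_from_config(cfg: Mapping) -> APCTruth:
    """Truth curves given as year -> value maps under the 'truth' key."""
    t = cfg["truth"]
    def _curve(m):
        return {int(k): float(v) for k, v in m.items()}
    return APCTruth(
        age_curve=_curve(t["age_curve"]),
        period_curve=_curve(t["period_curve"]),
        cohort_curve=_curve(t["cohort_curve"]),
        residual_sd=float(t.get("residual_sd", 1.0)),
    )
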