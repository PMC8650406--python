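"""Output writers and run manifests.

Every table or trace written by the analysis drivers is accompanied by a
manifest (JSON) recording the package version, a hash of the full
parameter configuration, any seeds, and a timestamp — enough to
reproduce the file exactly.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .parameters import ParameterBundle, _to_dict

__all__ = [
    "config_hash",
    "run_manifest",
    "write_manifest",
    "write_results_json",
    "write_table_csv",
    "write_trace_csv",
]


def config_hash(bundle: ParameterBundle) -> str:
    canonical = yaml.safe_dump(_to_dict(bundle), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_manifest(
    command: str,
    bundle: ParameterBundle,
    seeds: dict[str, int] | None = None,
    overrides: dict[str, Any] | None = None,
) -> dict[str, Any]:
    return {
        "command": command,
        "package_version": __version__,
        "config_hash": config_hash(bundle),
        "seeds": seeds or {},
        "overrides": overrides or {},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }


def write_manifest(path: str | Path, manifest: dict[str, Any]) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")


def write_results_json(path: str | Path, results: dict[str, Any]) -> None:
    """Full-precision JSON serialisation of result quantities."""
    Path(path).write_text(json.dumps(results, indent=2, default=float) + "\n")


def _display_round(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if col.startswith(("cost", "delta_cost")) or col == "icer":
            out[col] = out[col].round(0)
        elif col.startswith(("qaly", "delta_qaly")):
            out[col] = out[col].round(2)
    return out


def write_table_csv(path: str | Path, table: pd.DataFrame, raw: bool = False) -> None:
    """Results table as CSV, rounded for display (whole GBP, 2 d.p.
    QALYs) unless ``raw``."""
    (table if raw else _display_round(table)).to_csv(path, index=False)


def write_trace_csv(path: str | Path, trace: pd.DataFrame) -> None:
    trace.to_csv(path, index=False)
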