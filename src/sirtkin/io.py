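"""File formats: rate tables, fit reports, and network configs.

Rate tables are plain CSV (UTF-8, '.' decimal, mandatory header) with
columns enzyme,nad_uM,nam_uM,isonam_uM,v_uM_per_min,replicate; a missing
isonam_uM column is read as zeros. Fit reports are JSON with an embedded
schema version. Reaction-network configs are flat key = value text
(rate-constant name -> value; units as in ReactionNetwork).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .fitting import RATE_COLUMNS, FitResult, KineticDataset
from .steady_state import ReactionNetwork

__all__ = [
    "read_rate_table",
    "write_rate_table",
    "write_fit_report",
    "read_fit_report",
    "read_network_config",
]


def read_rate_table(path: str | Path) -> KineticDataset:
    """Read a CSV rate table into a KineticDataset."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty rate table: {path}")
    df = pd.read_csv(path)
    if "isonam_uM" not in df.columns:
        df["isonam_uM"] = 0.0
    missing = [c for c in RATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    enzyme = str(df["enzyme"].iloc[0]) if len(df) else ""
    return KineticDataset(df[RATE_COLUMNS], enzyme=enzyme, provenance=str(path))


def write_rate_table(ds: KineticDataset, path: str | Path) -> None:
    """Write a KineticDataset as CSV (column order fixed, lossless)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ds.data[RATE_COLUMNS].to_csv(path, index=False)


def write_fit_report(result: FitResult, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(result.to_dict(), indent=2) + "\n")


def read_fit_report(path: str | Path) -> dict:
    d = json.loads(Path(path).read_text())
    if d.get("schema_version") != 1:
        raise ValueError(f"unsupported fit-report schema: {d.get('schema_version')}")
    return d


def read_network_config(path: str | Path) -> ReactionNetwork:
    """Parse a flat 'name = value' config into a ReactionNetwork."""
    entries: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'name = value', got {raw!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        entries[key] = float(val)
    return ReactionNetwork.from_dict(entries)
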