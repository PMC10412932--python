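"""File formats: the mouse-record CSV, parameter files, configs, manifests.

The canonical cohort table is a comma-separated UTF-8 CSV with a header row
and '.' decimals; times are days since the first tamoxifen injection.  All
fraction columns are proportions in [0, 1].
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "MOUSE_TABLE_COLUMNS",
    "read_mouse_table",
    "write_mouse_table",
    "write_params",
    "read_params",
    "load_config",
    "write_manifest",
]

MOUSE_TABLE_COLUMNS = [
    "mouse_id",
    "age_at_treatment_d",
    "time_d",
    "organ",
    "lineage",
    "population",
    "total_count",
    "frac_yfp",
    "frac_ki67_in_yfp",
    "frac_ki67_total",
]

_ORGANS = {"thymus", "spleen", "LN"}
_LINEAGES = {"CD4", "CD8"}
_POPULATIONS = {"DP", "mSP", "naive"}
_FRACTION_COLS = ["frac_yfp", "frac_ki67_in_yfp", "frac_ki67_total"]


class SchemaError(ValueError):
    """Raised when a mouse table does not match the canonical schema."""


def read_mouse_table(path) -> pd.DataFrame:
    """Read and validate a mouse-record CSV.

    Raises :class:`SchemaError` naming the offending column/row on a missing
    column, an out-of-range fraction, a negative or non-numeric count, or an
    unknown organ/lineage/population value.
    """
    df = pd.read_csv(path)
    missing = [c for c in MOUSE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"mouse table missing column(s): {', '.join(missing)}")
    df = df[MOUSE_TABLE_COLUMNS]
    for col, allowed in [
        ("organ", _ORGANS),
        ("lineage", _LINEAGES),
        ("population", _POPULATIONS),
    ]:
        bad = set(df[col].unique()) - allowed
        if bad:
            raise SchemaError(f"unknown {col} value(s): {sorted(bad)}")
    for col in ["time_d", "total_count", *_FRACTION_COLS]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            mid = df.loc[vals.isna(), "mouse_id"].iloc[0]
            raise SchemaError(f"non-numeric {col} (first offender: mouse {mid})")
        df[col] = vals
    if (df["total_count"] < 0).any():
        mid = df.loc[df["total_count"] < 0, "mouse_id"].iloc[0]
        raise SchemaError(f"negative total_count (mouse {mid})")
    if (df["time_d"] < 0).any():
        raise SchemaError("negative time_d")
    for col in _FRACTION_COLS:
        bad = (df[col] < 0) | (df[col] > 1)
        if bad.any():
            mid = df.loc[bad, "mouse_id"].iloc[0]
            raise SchemaError(f"{col} outside [0, 1] (mouse {mid})")
    return df


def write_mouse_table(df: pd.DataFrame, path) -> None:
    df[MOUSE_TABLE_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------


def write_params(entries, path) -> None:
    """Write fitted parameters as a plain-text TSV.

    ``entries`` is an iterable of dicts with keys name, value, and optional
    lineage, role, lo, hi.
    """
    cols = ["name", "value", "lineage", "role", "lo", "hi"]
    rows = [{c: e.get(c, "") for c in cols} for e in entries]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_params(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def write_manifest(path, *, seed, config=None, extra=None) -> None:
    """Record what produced an artifact: seed, config hash, settings."""
    payload = {
        "seed": int(seed),
        "config_sha256": (
            hashlib.sha256(
                json.dumps(config, sort_keys=True, default=str).encode()
            ).hexdigest()
            if config is not None
            else None
        ),
        "config": config,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
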