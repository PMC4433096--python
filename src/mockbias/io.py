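"""File formats: count tables, truth JSON, and the flat run configuration."""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, SchemaError


def write_counts(table: pd.DataFrame, path: str | Path) -> None:
    """Write a samples × taxa integer count table as TSV (index = sample_id)."""
    out = table.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path, sep="\t")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a TSV count table; validates nonnegative integer counts.

    A sample with all-zero counts passes reading but triggers a warning.
    Bit-exact round trip with :func:`write_counts` (column order preserved).
    """
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty count table") from exc
    if frame.shape[1] == 0:
        raise SchemaError(f"{path}: count table has no taxon columns")
    for col in frame.columns:
        vals = frame[col]
        if not np.issubdtype(vals.dtype, np.number):
            raise SchemaError(f"{path}: column {col!r} is not numeric")
        if np.any(vals < 0):
            raise SchemaError(f"{path}: column {col!r} contains negative counts")
        if np.any(vals != vals.astype(np.int64)):
            raise SchemaError(f"{path}: column {col!r} contains non-integer counts")
    frame = frame.astype(np.int64)
    zero = frame.index[frame.sum(axis=1) == 0]
    if len(zero):
        warnings.warn(f"{path}: samples with zero total counts: {list(zero[:5])}")
    return frame


def write_proportions(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path, sep="\t", float_format="%.12g")


#: configuration keys, their types and defaults (None = required/optional path)
CONFIG_SCHEMA: dict[str, tuple[type, object]] = {
    "taxa_path": (str, None),
    "design_path": (str, None),
    "exp1_path": (str, None),
    "exp2_path": (str, None),
    "exp3_path": (str, None),
    "out_dir": (str, "mockbias_out"),
    "n_taxa": (int, 7),
    "n_support": (int, 0),  # 0 -> special_cubic_size(p)
    "n_lack_of_fit": (int, 2),
    "n_replicates": (int, 15),
    "scenario": (str, "default"),
    "depth": (int, 16_000),
    "noise_cv": (float, 0.03),
    "alpha": (float, 0.05),
    "n_boot": (int, 10_000),
    "boot_level": (float, 0.95),
    "n_trees": (int, 500),
    "max_features": (int, 2),
    "cv_folds": (int, 5),
    "factor_orientation": (str, "obs_over_actual"),
    "design_seed": (int, 1),
    "truth_seed": (int, 2),
    "boot_seed": (int, 3),
    "forest_seed": (int, 4),
}


class RunConfig(dict):
    """Validated flat configuration for the end-to-end pipeline."""

    def __init__(self, **kwargs):
        unknown = set(kwargs) - set(CONFIG_SCHEMA)
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        merged = {k: default for k, (_, default) in CONFIG_SCHEMA.items()}
        for key, value in kwargs.items():
            typ, _ = CONFIG_SCHEMA[key]
            if value is not None:
                try:
                    value = typ(value)
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"configuration key {key!r}: {exc}") from exc
            merged[key] = value
        super().__init__(merged)

    def __getattr__(self, key):
        try:
            return self[key]
        except KeyError as exc:  # pragma: no cover
            raise AttributeError(key) from exc

    def hash(self) -> str:
        payload = json.dumps(self, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_config(path: str | Path) -> RunConfig:
    """Load a flat YAML key-value configuration; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a flat mapping")
    return RunConfig(**raw)
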