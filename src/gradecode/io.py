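"""Readers and writers for the tab-delimited interchange formats.

All tables are plain TSV with required headers; readers validate the header
and hand back pandas DataFrames (or the package's domain objects for traces
and configs).
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decode import ARRAY_COLUMNS, validate_feature_table
from .gradient import A260Trace
from .psilac import PEPTIDE_COLUMNS
from .simulate import SimConfig

__all__ = ["read_trace", "write_trace", "read_feature_table", "write_feature_table",
           "read_qpcr_table", "read_peptide_table", "load_config", "save_config"]

QPCR_COLUMNS = ["gene", "condition", "fraction", "mean", "se",
                "control_mean", "control_se"]


def read_trace(path) -> A260Trace:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["time_s", "absorbance_au"]:
        raise ValueError("trace file must have header 'time_s\\tabsorbance_au'")
    return A260Trace(times=df["time_s"].to_numpy(float),
                     absorbance=df["absorbance_au"].to_numpy(float))


def write_trace(trace: A260Trace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "absorbance_au": trace.absorbance}) \
        .to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_feature_table(df[ARRAY_COLUMNS].copy()
                                  if set(ARRAY_COLUMNS) <= set(df.columns) else df)


def write_feature_table(table: pd.DataFrame, path) -> None:
    validate_feature_table(table)
    table.to_csv(path, sep="\t", index=False)


def read_qpcr_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"qPCR table missing columns: {missing}")
    return df


def read_peptide_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PEPTIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peptide table missing columns: {missing}")
    return df


def load_config(path) -> SimConfig:
    """Load a SimConfig from a YAML mapping of field names to values."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in fields(SimConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("dispersion_pos", "load_bounds", "translation_effect",
                "abundance_effect", "protein_coupling"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return SimConfig(**data)


def save_config(config: SimConfig, path) -> None:
    data = {}
    for f in fields(SimConfig):
        v = getattr(config, f.name)
        if isinstance(v, tuple):
            v = list(v)
        elif isinstance(v, np.integer):
            v = int(v)
        data[f.name] = v
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
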