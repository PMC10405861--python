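"""On-disk formats and run configuration.

Tables are CSV (comma, UTF-8, header row) with fixed, validated schemas;
results and configuration are JSON/YAML.  Angles are stored in degrees
everywhere on disk.  Schema validation fails loudly, naming the offending
columns.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .design import TRIAL_COLUMNS
from .preprocess import ERROR_COLUMNS

SCHEMA_VERSION = "1"

__all__ = [
    "RunConfig",
    "read_trial_table",
    "write_trial_table",
    "read_error_table",
    "write_error_table",
    "write_json",
    "read_json",
]


def _validate(df: pd.DataFrame, columns: list[str], kind: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(
            f"{kind} is malformed: missing columns {missing}; "
            f"found {list(df.columns)}"
        )
    return df


def write_trial_table(table: pd.DataFrame, path) -> None:
    cols = TRIAL_COLUMNS + (["response_deg"] if "response_deg" in table.columns else [])
    _validate(table, TRIAL_COLUMNS, "trial table")[cols].to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    return _validate(pd.read_csv(path), TRIAL_COLUMNS, f"trial table {path}")


def write_error_table(table: pd.DataFrame, path) -> None:
    _validate(table, ERROR_COLUMNS, "error table")[ERROR_COLUMNS].to_csv(
        path, index=False
    )


def read_error_table(path) -> pd.DataFrame:
    return _validate(pd.read_csv(path), ERROR_COLUMNS, f"error table {path}")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, allow_nan=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; round-trips losslessly via YAML."""

    study: int = 1
    n_subjects: int = 4
    seed: int = 0
    # phenotype distribution of the simulated cohort
    amp_range: tuple[float, float] = (-3.0, 9.0)
    fwhm_range: tuple[float, float] = (12.0, 71.0)
    fwhm_mean: float = 37.6
    fwhm_sd: float = 14.7
    noise_sd: float = 11.0
    global_bias_sd: float = 1.0
    lapse_rate: float = 0.01
    session_jitter_sd: float = 1.0
    # analysis knobs
    n_perm: int = 1000
    n_boot: int = 0
    model_free_range: float = 54.0
    window_deg: float = 20.0
    alpha: float = 0.05
    # I/O
    out_dir: str = "serialdep_run"
    input_csvs: list[str] = field(default_factory=list)  # skip simulation if set
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self):
        if self.study not in (1, 2):
            raise ValueError("study must be 1 or 2")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        self.amp_range = tuple(self.amp_range)
        self.fwhm_range = tuple(self.fwhm_range)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["amp_range"] = list(self.amp_range)
        data["fwhm_range"] = list(self.fwhm_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
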