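"""Delimited-text schemas, run configuration and report serialisation.

All tables are comma-separated UTF-8 with a header row and "." decimals.
Schema validation reports the offending column by name.  `RunConfig`
round-trips through YAML and rejects unknown keys so that a typo in a
config file fails loudly instead of silently running defaults.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .cohort import MSI_N_ITEMS

__all__ = [
    "SchemaError",
    "RunConfig",
    "RESPONSES_COLUMNS",
    "PRECISION_COLUMNS",
    "participants_columns",
    "read_responses",
    "write_responses",
    "read_participants",
    "write_participants",
    "read_precision",
    "write_precision",
    "write_report",
    "read_table_with_mapping",
]

RESPONSES_COLUMNS = (
    "participant_id",
    "trial_index",
    "domain",
    "condition",
    "target_param",
    "matched_param",
)

PRECISION_COLUMNS = (
    "participant_id",
    "domain",
    "condition",
    "n_trials",
    "sd_error",
    "precision",
    "z_precision",
)


def participants_columns() -> tuple[str, ...]:
    return (
        "participant_id",
        "age",
        "matrix_score",
        *(f"msi_item_{k + 1}" for k in range(MSI_N_ITEMS)),
        "msi_total",
        "msi_training_total",
    )


class SchemaError(ValueError):
    """A table does not match its expected column schema."""


def _check_columns(frame: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def _read(path, required, what) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _check_columns(frame, required, what)
    return frame


def read_responses(path) -> pd.DataFrame:
    return _read(path, RESPONSES_COLUMNS, "responses")


def write_responses(frame: pd.DataFrame, path) -> None:
    _check_columns(frame, RESPONSES_COLUMNS, "responses")
    frame.to_csv(path, index=False)


def read_participants(path) -> pd.DataFrame:
    return _read(path, participants_columns(), "participants")


def write_participants(frame: pd.DataFrame, path) -> None:
    _check_columns(frame, participants_columns(), "participants")
    frame.to_csv(path, index=False)


def read_precision(path) -> pd.DataFrame:
    return _read(path, PRECISION_COLUMNS, "precision")


def write_precision(frame: pd.DataFrame, path) -> None:
    _check_columns(frame, PRECISION_COLUMNS, "precision")
    frame.to_csv(path, index=False)


def read_table_with_mapping(path, column_mapping: Mapping[str, str]) -> pd.DataFrame:
    """Load an external export, renaming its columns onto the internal schema.

    ``column_mapping`` maps external -> internal column names, so real data
    exports with arbitrary headers can be adapted without editing them.
    """
    frame = pd.read_csv(path)
    missing = [c for c in column_mapping if c not in frame.columns]
    if missing:
        raise SchemaError(f"mapped table is missing column(s): {', '.join(missing)}")
    return frame.rename(columns=dict(column_mapping))


def write_report(report: Mapping, path) -> None:
    """Deterministic JSON: sorted keys, fixed indentation, trailing newline."""
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")


@dataclass
class RunConfig:
    """Configuration of a full simulate -> score -> analyze run."""

    experiment: str = "exp1"
    n_participants: int = 50
    trials_per_condition: int = 14
    seed: int = 0
    alpha: float = 0.05
    n_resamples: int = 5000
    adjustment_mode: str = "residualize_x_only"
    min_trials: int = 2
    output_dir: str = "."
    generative: dict = field(default_factory=dict)  # GenerativeConfig overrides

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, Mapping):
            raise SchemaError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
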