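"""CSV/JSON interchange for the pipeline's tables and fit results."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .errors import InvalidParameterError
from .models import (
    EVENT_COLUMNS,
    FIBRIL_COLUMNS,
    TRAJECTORY_COLUMNS,
    FibrilField,
    GroundTruth,
)


def _check_columns(df: pd.DataFrame, expected: list[str], what: str) -> pd.DataFrame:
    missing = set(expected) - set(df.columns)
    if missing:
        raise InvalidParameterError(f"{what} CSV missing columns {sorted(missing)}")
    return df[expected]


def write_events(df: pd.DataFrame, path) -> None:
    _check_columns(df, EVENT_COLUMNS, "event").to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    return _check_columns(pd.read_csv(path), EVENT_COLUMNS, "event")


def write_trajectories(df: pd.DataFrame, path) -> None:
    _check_columns(df, TRAJECTORY_COLUMNS, "trajectory").to_csv(path, index=False)


def read_trajectories(path) -> pd.DataFrame:
    return _check_columns(pd.read_csv(path), TRAJECTORY_COLUMNS, "trajectory")


def write_fibril_field(field: FibrilField, path) -> None:
    field.to_frame().to_csv(path, index=False)


def read_fibril_field(path) -> FibrilField:
    df = _check_columns(pd.read_csv(path), FIBRIL_COLUMNS, "fibril")
    return FibrilField.from_frame(df)


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(truth), indent=2) + "\n")


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth(**json.loads(Path(path).read_text()))


def write_json(obj, path) -> None:
    """Write any fit result / report (dataclasses handled) as JSON."""

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if hasattr(o, "tolist"):
            return o.tolist()
        if hasattr(o, "item"):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
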