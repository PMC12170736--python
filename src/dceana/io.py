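"""Readers and writers for the package's CSV/JSON interchange formats.

Choice data travel as long-format CSV (respondent_id, task_id, option,
mo..ad, chosen); designs as task_id/option/level CSV; fits and efficiency
reports as JSON.  Unknown columns are preserved on round trip, and JSON is
written with sorted keys and no timestamps so re-running a configuration
reproduces outputs byte-for-byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import ATTRIBUTE_COLUMNS, Design
from .data import REQUIRED_COLUMNS, ChoiceDataError, ChoiceDataset

__all__ = [
    "read_choice_data",
    "write_choice_data",
    "read_design",
    "write_design",
    "write_json",
    "read_json",
]


def read_choice_data(path) -> ChoiceDataset:
    """Read and validate long-format choice data.

    Contract violations are reported with the offending row or task named.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ChoiceDataError(f"{path.name}: missing columns {sorted(missing)}")
    info = None
    info_path = path.with_name(path.stem + "_respondents.csv")
    if info_path.exists():
        info = pd.read_csv(info_path)
    return ChoiceDataset(df, info)


def write_choice_data(data: ChoiceDataset, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data.df.to_csv(path, index=False)
    if data.respondent_info is not None:
        data.respondent_info.to_csv(
            path.with_name(path.stem + "_respondents.csv"), index=False
        )


def read_design(path, method: str = "unspecified", overlap_target: int | None = None) -> Design:
    df = pd.read_csv(path)
    return Design.from_frame(df, method=method, overlap_target=overlap_target)


def write_design(design: Design, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    design.to_frame().to_csv(path, index=False)


def write_json(obj: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
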