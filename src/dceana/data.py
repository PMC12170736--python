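"""Long-format choice data container shared by the estimation modules."""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd

from .core import (
    ATTRIBUTE_COLUMNS,
    N_LEVELS,
    N_PARAMS,
    InvalidProfileError,
)

REQUIRED_COLUMNS = ("respondent_id", "task_id", "option", *ATTRIBUTE_COLUMNS, "chosen")


class ChoiceDataError(ValueError):
    """The long-format table violates the choice-data contract."""


@dataclass
class ChoiceDataset:
    """Observed or simulated choices, one row per (respondent, task, option).

    Invariants enforced at construction: every (respondent, task) has
    exactly the two options A and B, exactly one of which is chosen, and
    every attribute level lies in 1..5.  Extra columns are carried along
    untouched.  ``respondent_info`` optionally holds one row per respondent
    (completion times, feedback codes, full-attendance flags ...).
    """

    df: pd.DataFrame
    respondent_info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        df = self.df
        missing = set(REQUIRED_COLUMNS) - set(df.columns)
        if missing:
            raise ChoiceDataError(f"missing columns: {sorted(missing)}")
        levels = df[list(ATTRIBUTE_COLUMNS)].to_numpy()
        bad = np.flatnonzero((levels < 1).any(axis=1) | (levels > N_LEVELS).any(axis=1))
        if bad.size:
            raise InvalidProfileError(
                f"row {int(bad[0])}: attribute level outside 1..{N_LEVELS}"
            )
        if df.duplicated(["respondent_id", "task_id", "option"]).any():
            dup = df[df.duplicated(["respondent_id", "task_id", "option"])].iloc[0]
            raise ChoiceDataError(
                f"duplicate option {dup['option']!r} for respondent "
                f"{dup['respondent_id']!r}, task {dup['task_id']!r}"
            )
        grp = df.groupby(["respondent_id", "task_id"], sort=False)
        sizes = grp.size()
        if (sizes != 2).any():
            rid, tid = sizes.index[sizes != 2][0]
            raise ChoiceDataError(
                f"respondent {rid!r}, task {tid!r}: needs exactly 2 options"
            )
        chosen = grp["chosen"].sum()
        if (chosen != 1).any():
            rid, tid = chosen.index[chosen != 1][0]
            raise ChoiceDataError(
                f"respondent {rid!r}, task {tid!r}: exactly one option must be chosen"
            )

    @cached_property
    def _arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
        """Per-task arrays: respondent codes, difference matrix Z = x_A - x_B,
        indicator y of choosing A, and the respondent id list."""
        df = self.df.sort_values(
            ["respondent_id", "task_id", "option"], kind="stable"
        )
        a = df[df["option"] == "A"]
        b = df[df["option"] == "B"]
        XA = _encode_rows(a)
        XB = _encode_rows(b)
        Z = XA - XB
        y = a["chosen"].to_numpy().astype(float)
        resp = a["respondent_id"].to_numpy()
        ids, codes = np.unique(resp, return_inverse=True)
        return codes, Z, y, list(ids)

    @property
    def respondents(self) -> list:
        return self._arrays[3]

    @property
    def n_respondents(self) -> int:
        return len(self._arrays[3])

    @property
    def n_tasks(self) -> int:
        """Total number of choice tasks (respondent-task pairs)."""
        return self._arrays[1].shape[0]

    def design_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(respondent codes, Z, y) with Z the paired-difference coding and
        y = 1 when option A was chosen."""
        codes, Z, y, _ = self._arrays
        return codes, Z, y

    def subset(self, respondent_ids) -> "ChoiceDataset":
        keep = self.df["respondent_id"].isin(set(respondent_ids))
        info = None
        if self.respondent_info is not None:
            info = self.respondent_info[
                self.respondent_info["respondent_id"].isin(set(respondent_ids))
            ].reset_index(drop=True)
        return ChoiceDataset(self.df[keep].reset_index(drop=True), info)


def _encode_rows(df: pd.DataFrame) -> np.ndarray:
    levels = df[list(ATTRIBUTE_COLUMNS)].to_numpy(dtype=int)
    n = levels.shape[0]
    X = np.zeros((n, N_PARAMS))
    for k in range(levels.shape[1]):
        mask = levels[:, k] >= 2
        X[np.arange(n)[mask], 4 * k + levels[mask, k] - 2] = 1.0
    return X
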