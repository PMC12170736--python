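"""Relative attribute importance and respondent-engagement diagnostics.

Relative attribute importance (RAI) is a dimension's share of the summed
level coefficients: ``RAI_k = beta_k / (beta_MO + ... + beta_AD)`` with
``beta_k`` the sum of the four level coefficients of dimension ``k``.  The
ratio of same-signed sums is positive and invariant to positive rescaling,
so anchored and raw coefficients give identical shares.

Straightlining is the strict "same option position in every task"
behaviour; the engagement cross-tab compares straightlining, completion
times, and feedback agreement across the full / partial / non attendance
classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ATTRIBUTES, N_ATTRIBUTES, N_PARAMS
from .data import ChoiceDataset

__all__ = [
    "RAIResult",
    "EngagementTable",
    "rai",
    "straightline_detect",
    "engagement_crosstab",
    "UndefinedRAIError",
]

from dataclasses import dataclass


class UndefinedRAIError(ValueError):
    """The total coefficient sum is zero, so shares are undefined."""


@dataclass
class RAIResult:
    """Per-dimension importance shares with the sums retained for audit."""

    shares: np.ndarray  # (5,) in ATTRIBUTES order
    dimension_sums: np.ndarray
    total: float

    def to_series(self) -> pd.Series:
        return pd.Series(self.shares, index=list(ATTRIBUTES), name="rai")


def rai(beta: np.ndarray) -> RAIResult:
    """Importance shares from a 20-vector of level coefficients."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (N_PARAMS,):
        raise ValueError(f"expected a {N_PARAMS}-vector")
    sums = beta.reshape(N_ATTRIBUTES, 4).sum(axis=1)
    total = float(sums.sum())
    if abs(total) < 1e-12:
        raise UndefinedRAIError("total coefficient sum is zero")
    return RAIResult(shares=sums / total, dimension_sums=sums, total=total)


def straightline_detect(data: ChoiceDataset) -> pd.Series:
    """Per-respondent flag: 'left' if option A was chosen in every task,
    'right' if option B, 'none' otherwise (strict definition; one deviation
    clears the flag).  Invariant to task order."""
    chosen = data.df[data.df["chosen"] == 1]
    out = {}
    for rid, grp in chosen.groupby("respondent_id", sort=False):
        opts = set(grp["option"])
        if opts == {"A"}:
            out[rid] = "left"
        elif opts == {"B"}:
            out[rid] = "right"
        else:
            out[rid] = "none"
    return pd.Series(out, name="straightline").reindex(data.respondents)


@dataclass
class EngagementTable:
    """Straightlining, completion time, and feedback agreement by class."""

    table: pd.DataFrame  # metrics x classes
    counts: pd.DataFrame  # raw counts backing the percentages

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string()


_CLASSES = ("full", "partial", "non")


def engagement_crosstab(
    labels: pd.Series | dict,
    data: ChoiceDataset,
    respondent_info: pd.DataFrame | None = None,
) -> EngagementTable:
    """Cross-tabulate engagement indicators by attendance class.

    ``labels`` maps every respondent to 'full' / 'partial' / 'non'.
    Completion times (median minutes) and feedback agreement are taken from
    ``respondent_info`` (defaulting to the dataset's own) when the columns
    exist; feedback percentages are computed only among respondents who
    answered.  Classes with zero respondents get zero counts and NaN
    medians.
    """
    labels = pd.Series(labels)
    missing = [r for r in data.respondents if r not in labels.index]
    if missing:
        raise ValueError(f"labels missing respondents: {missing[:5]}")
    if respondent_info is None:
        respondent_info = data.respondent_info
    straight = straightline_detect(data)

    rows: dict[str, dict[str, float]] = {}
    counts: dict[str, dict[str, float]] = {}
    for cls in _CLASSES:
        ids = [r for r in data.respondents if labels[r] == cls]
        n = len(ids)
        s = straight.reindex(ids)
        left = int((s == "left").sum())
        right = int((s == "right").sum())
        total = left + right
        col = {
            "n": n,
            "straightline_left": left,
            "straightline_right": right,
            "straightline_total": total,
            "straightline_pct": 100.0 * total / n if n else np.nan,
        }
        cnt = dict(col)
        if respondent_info is not None:
            info = respondent_info.set_index("respondent_id").reindex(ids)
            for c in ("task_time_min", "survey_time_min"):
                if c in info:
                    col[f"median_{c}"] = float(info[c].median()) if n else np.nan
            for c in info.columns:
                if c.startswith("feedback_"):
                    answered = info[c].notna().sum()
                    agreed = float(info[c].sum()) if answered else np.nan
                    col[f"{c}_pct"] = (
                        100.0 * agreed / answered if answered else np.nan
                    )
                    cnt[f"{c}_agreed"] = agreed
                    cnt[f"{c}_answered"] = int(answered)
        rows[cls] = col
        counts[cls] = cnt
    return EngagementTable(
        table=pd.DataFrame(rows), counts=pd.DataFrame(counts)
    )
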