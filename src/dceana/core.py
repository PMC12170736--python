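"""Core combinatorial objects for paired choice experiments on the EQ-5D-5L.

The descriptive system has five attributes -- mobility (MO), self-care (SC),
usual activities (UA), pain/discomfort (PD), anxiety/depression (AD) -- each
at five severity levels, 1 (no problems) to 5 (extreme problems).  A health
state is a 5-vector of levels, written as a 5-digit label: ``11111`` is full
health, ``55555`` the worst state.  A choice set pairs two distinct states.

Dummy coding uses level 1 of each attribute as the reference, giving 20 free
parameters.  Parameter indexing is attribute-major, level-minor and frozen:
position ``4*k + (l - 2)`` holds attribute ``k`` (MO, SC, UA, PD, AD order),
level ``l`` in 2..5.  Coefficient files written by this package rely on that
ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ATTRIBUTES: tuple[str, ...] = ("MO", "SC", "UA", "PD", "AD")
ATTRIBUTE_COLUMNS: tuple[str, ...] = ("mo", "sc", "ua", "pd", "ad")
N_ATTRIBUTES = 5
N_LEVELS = 5
N_PARAMS = N_ATTRIBUTES * (N_LEVELS - 1)

#: Frozen parameter names, attribute-major / level-minor: MO2..MO5, SC2..SC5, ...
PARAM_NAMES: tuple[str, ...] = tuple(
    f"{a}{l}" for a in ATTRIBUTES for l in range(2, N_LEVELS + 1)
)

#: Positions of the five level-5 coefficients (used for anchoring to 55555).
LEVEL5_INDICES: tuple[int, ...] = tuple(
    4 * k + (N_LEVELS - 2) for k in range(N_ATTRIBUTES)
)


class InvalidProfileError(ValueError):
    """A health-state profile violates the 5-attribute / level 1..5 contract."""


class InvalidChoiceSetError(ValueError):
    """A choice set's two options are identical (or otherwise malformed)."""


class DuplicateChoiceSetError(ValueError):
    """A design contains the same unordered pair twice."""


def param_index(attribute: int, level: int) -> int:
    """Position of the dummy coefficient for ``attribute`` (0-based) at ``level``."""
    if not (0 <= attribute < N_ATTRIBUTES):
        raise IndexError(f"attribute index {attribute} out of range")
    if not (2 <= level <= N_LEVELS):
        raise IndexError(f"level {level} has no dummy coefficient")
    return 4 * attribute + (level - 2)


@dataclass(frozen=True)
class Profile:
    """One health state: a level in 1..5 for each of the five attributes."""

    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        levels = tuple(int(v) for v in self.levels)
        if len(levels) != N_ATTRIBUTES:
            raise InvalidProfileError(
                f"profile needs {N_ATTRIBUTES} levels, got {len(levels)}"
            )
        for v in levels:
            if not (1 <= v <= N_LEVELS):
                raise InvalidProfileError(f"level {v} outside 1..{N_LEVELS}")
        object.__setattr__(self, "levels", levels)

    @classmethod
    def from_label(cls, label: str) -> "Profile":
        """Build a profile from its 5-digit state label, e.g. ``"21345"``."""
        if len(label) != N_ATTRIBUTES or not label.isdigit():
            raise InvalidProfileError(f"bad state label {label!r}")
        return cls(tuple(int(c) for c in label))

    @property
    def label(self) -> str:
        return "".join(str(v) for v in self.levels)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def encode_profile(p: Profile | Sequence[int]) -> np.ndarray:
    """Dummy-code a profile into the frozen 20-vector.

    Element ``param_index(k, l)`` is 1 iff attribute ``k`` is at level
    ``l >= 2``; a level-1 attribute contributes an all-zero block, so the
    reference state 11111 maps to the zero vector.
    """
    if not isinstance(p, Profile):
        p = Profile(tuple(p))
    x = np.zeros(N_PARAMS)
    for k, level in enumerate(p.levels):
        if level >= 2:
            x[param_index(k, level)] = 1.0
    return x


def decode_profile(x: np.ndarray) -> Profile:
    """Invert :func:`encode_profile` (exact on valid codings)."""
    x = np.asarray(x)
    if x.shape != (N_PARAMS,):
        raise InvalidProfileError(f"coding vector must have length {N_PARAMS}")
    levels = []
    for k in range(N_ATTRIBUTES):
        block = x[4 * k : 4 * k + 4]
        hot = np.flatnonzero(block == 1.0)
        if block.sum() == 0:
            levels.append(1)
        elif len(hot) == 1 and block.sum() == 1.0:
            levels.append(int(hot[0]) + 2)
        else:
            raise InvalidProfileError(f"attribute block {k} is not a valid coding")
    return Profile(tuple(levels))


def dominates(a: Profile, b: Profile) -> bool:
    """True iff ``a`` is at least as good on every attribute and strictly
    better on at least one (lower level = better health)."""
    better_or_equal = all(x <= y for x, y in zip(a.levels, b.levels))
    strictly = any(x < y for x, y in zip(a.levels, b.levels))
    return better_or_equal and strictly


@dataclass(frozen=True)
class ChoiceSet:
    """An unordered pair of distinct health states shown in one task."""

    option_a: Profile
    option_b: Profile

    def __post_init__(self) -> None:
        if self.option_a.levels == self.option_b.levels:
            raise InvalidChoiceSetError(
                f"options are identical ({self.option_a.label})"
            )

    @property
    def key(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        """Unordered-pair identity: (A,B) and (B,A) share a key."""
        return tuple(sorted((self.option_a.levels, self.option_b.levels)))  # type: ignore[return-value]

    def difference_vector(self) -> np.ndarray:
        """encode(A) - encode(B); the row this pair contributes to the
        paired-logit design matrix."""
        return encode_profile(self.option_a) - encode_profile(self.option_b)

    def has_dominated_option(self) -> bool:
        return dominates(self.option_a, self.option_b) or dominates(
            self.option_b, self.option_a
        )


def overlap_count(cs: ChoiceSet) -> int:
    """Number of attributes presented at the same level in both options.

    Equals 5 minus the Hamming distance between the level vectors; always in
    0..4 because identical pairs are rejected at construction.
    """
    return sum(
        1 for x, y in zip(cs.option_a.levels, cs.option_b.levels) if x == y
    )


@dataclass
class Design:
    """An ordered list of choice sets plus construction metadata.

    ``overlap_target`` of 0 or 2 asserts that every set has exactly that many
    overlapping attributes (None disables the check, e.g. for random
    benchmark designs).  Duplicate unordered pairs are rejected.
    """

    choice_sets: list[ChoiceSet]
    method: str = "unspecified"
    overlap_target: int | None = None
    prior: np.ndarray = field(default_factory=lambda: np.zeros(N_PARAMS))
    seed: int | None = None
    #: benchmark/audit escape hatch; real designs never repeat a pair
    allow_duplicates: bool = False

    def __post_init__(self) -> None:
        self.prior = np.asarray(self.prior, dtype=float)
        seen: set = set()
        for i, cs in enumerate(self.choice_sets):
            if not self.allow_duplicates and cs.key in seen:
                raise DuplicateChoiceSetError(
                    f"choice set {i} ({cs.option_a.label}, {cs.option_b.label}) "
                    "duplicates an earlier pair"
                )
            seen.add(cs.key)
            if self.overlap_target is not None and overlap_count(cs) != self.overlap_target:
                raise InvalidChoiceSetError(
                    f"choice set {i} has overlap {overlap_count(cs)}, "
                    f"design requires {self.overlap_target}"
                )

    def __len__(self) -> int:
        return len(self.choice_sets)

    def difference_matrix(self) -> np.ndarray:
        """(n_sets, 20) matrix of paired difference vectors."""
        if not self.choice_sets:
            return np.zeros((0, N_PARAMS))
        return np.vstack([cs.difference_vector() for cs in self.choice_sets])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per option, columns task_id, option, mo..ad."""
        rows = []
        for t, cs in enumerate(self.choice_sets, start=1):
            for opt, prof in (("A", cs.option_a), ("B", cs.option_b)):
                rows.append((t, opt, *prof.levels))
        return pd.DataFrame(
            rows, columns=["task_id", "option", *ATTRIBUTE_COLUMNS]
        )

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        method: str = "unspecified",
        overlap_target: int | None = None,
        seed: int | None = None,
    ) -> "Design":
        required = {"task_id", "option", *ATTRIBUTE_COLUMNS}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        sets = []
        for task_id, grp in df.groupby("task_id", sort=True):
            grp = grp.sort_values("option")
            if list(grp["option"]) != ["A", "B"]:
                raise InvalidChoiceSetError(
                    f"task {task_id} must have exactly options A and B"
                )
            profs = [
                Profile(tuple(int(v) for v in row))
                for row in grp[list(ATTRIBUTE_COLUMNS)].to_numpy()
            ]
            sets.append(ChoiceSet(profs[0], profs[1]))
        return cls(sets, method=method, overlap_target=overlap_target, seed=seed)


def all_profiles() -> list[Profile]:
    """All 5^5 = 3125 health states in lexicographic label order."""
    grids = np.meshgrid(*[np.arange(1, N_LEVELS + 1)] * N_ATTRIBUTES, indexing="ij")
    levels = np.stack([g.ravel() for g in grids], axis=1)
    return [Profile(tuple(int(v) for v in row)) for row in levels]
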