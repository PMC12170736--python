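"""Synthetic choice data with the generative structure the analysis assumes.

Each simulated respondent draws a latent attendance class, then answers
every task with the paired-logit probability implied by the shared
preference vector masked by that class -- the all-ignored class therefore
chooses uniformly at random.  An optional contamination step overwrites a
fraction of respondents with straightlined answers (always the left or
always the right option), independently of the class draw, so response
quality diagnostics can be exercised.

All randomness flows from the scenario seed through a fixed
``SeedSequence`` split: child 0 selects the task subset, child 1 draws
classes, child 2 draws choices, child 3 picks straightliners, child 4
draws engagement covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import ATTRIBUTE_COLUMNS, N_PARAMS, Design
from .data import ChoiceDataset
from .eclc import AttendancePattern, ECLCSpec, mask_beta

__all__ = [
    "SimulationScenario",
    "default_scenario",
    "default_true_beta",
    "simulate",
    "inject_straightliners",
]


@dataclass
class SimulationScenario:
    """Everything needed to generate one synthetic cohort."""

    design: Design
    true_beta: np.ndarray
    spec: ECLCSpec
    class_probs: np.ndarray
    n_respondents: int = 500
    n_tasks: int = 21
    straightliner_fraction: float = 0.0
    seed: int = 0
    engagement: bool = False

    def __post_init__(self) -> None:
        self.true_beta = np.asarray(self.true_beta, dtype=float)
        self.class_probs = np.asarray(self.class_probs, dtype=float)
        if self.true_beta.shape != (N_PARAMS,):
            raise ValueError(f"true_beta must have length {N_PARAMS}")
        if np.any(self.true_beta > 1e-12):
            raise ValueError("level coefficients must be non-positive")
        for k in range(5):
            block = self.true_beta[4 * k : 4 * k + 4]
            if np.any(np.diff(block) > 1e-12):
                raise ValueError(
                    "within-attribute coefficients must be monotone "
                    "(worse level, larger decrement)"
                )
        if self.class_probs.shape != (self.spec.n_classes,):
            raise ValueError("class_probs length must match the spec")
        if np.any(self.class_probs < 0) or abs(self.class_probs.sum() - 1) > 1e-8:
            raise ValueError("class_probs must lie on the simplex")
        if not (0.0 <= self.straightliner_fraction <= 1.0):
            raise ValueError("straightliner_fraction must be in [0, 1]")


def default_true_beta() -> np.ndarray:
    """Plausible monotone decrements: level 2 near -0.2 up to level 5 near
    -1, with mild attribute-to-attribute variation so no two dimensions are
    exactly exchangeable.  Configuration, not ground truth."""
    base = np.array([-0.2, -0.45, -0.7, -1.0])
    scale = np.array([1.1, 0.9, 1.0, 1.2, 0.8])
    return np.concatenate([base * s for s in scale])


def default_scenario(overlap: int, seed: int) -> SimulationScenario:
    """The study-shaped default: the matching generator design, three
    attendance classes {full 0.5, PD+AD ignored 0.3, all ignored 0.2},
    500 respondents, 21 tasks each."""
    from .construct import Generator, generator_design, orthogonal_array_25

    if overlap == 0:
        gens = [Generator((1, 1, 1, 2, 2)), Generator((2, 2, 2, 4, 4))]
    elif overlap == 2:
        gens = [Generator((1, 1, 1, 0, 0)), Generator((0, 0, 2, 1, 1))]
    else:
        raise ValueError("overlap must be 0 or 2")
    design = generator_design(orthogonal_array_25(), gens, seed=seed)
    spec = ECLCSpec(
        (
            AttendancePattern.full(),
            AttendancePattern.ignoring("PD", "AD"),
            AttendancePattern.all_ignored(),
        )
    )
    return SimulationScenario(
        design=design,
        true_beta=default_true_beta(),
        spec=spec,
        class_probs=np.array([0.5, 0.3, 0.2]),
        n_respondents=500,
        n_tasks=21,
        straightliner_fraction=0.0,
        seed=seed,
    )


def _identified_task_subset(
    design: Design, n_tasks: int, rng: np.random.Generator, max_tries: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded subset of presented tasks that keeps all 20 parameters
    identified.

    A careless subset of an overlap design can leave some attribute level
    never varying between options, making its coefficient inestimable; a
    survey instrument would not be fielded like that.  Subsets are redrawn
    (deterministically, from the same stream) until the dummy-coded
    difference matrix has full column rank; if no full-rank subset is found
    the last draw is returned with a warning.
    """
    Z_full = design.difference_matrix()
    if n_tasks == len(design):
        return np.arange(len(design)), Z_full
    if n_tasks < N_PARAMS:
        # full rank is unattainable; take the first draw
        idx = np.sort(rng.choice(len(design), size=n_tasks, replace=False))
        return idx, Z_full[idx]
    for _ in range(max_tries):
        idx = np.sort(rng.choice(len(design), size=n_tasks, replace=False))
        Z = Z_full[idx]
        if np.linalg.matrix_rank(Z) == N_PARAMS:
            return idx, Z
    warnings.warn(
        f"no full-rank subset of {n_tasks} tasks found in {max_tries} draws; "
        "some coefficients will be unidentified",
        stacklevel=3,
    )
    return idx, Z


def simulate(scenario: SimulationScenario) -> tuple[ChoiceDataset, pd.DataFrame]:
    """Generate a cohort and the true labels needed for recovery testing.

    Returns ``(data, labels)`` where ``labels`` has one row per respondent:
    the true class index/label, the implied full/partial/non attendance
    group, and the straightliner flag.
    """
    sc = scenario
    ss = np.random.SeedSequence(sc.seed)
    rng_tasks, rng_class, rng_choice, rng_straight, rng_engage = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    n_design = len(sc.design)
    if sc.n_tasks > n_design:
        raise ValueError(
            f"n_tasks {sc.n_tasks} exceeds the design's {n_design} sets"
        )
    task_idx, Z = _identified_task_subset(sc.design, sc.n_tasks, rng_tasks)
    sets = [sc.design.choice_sets[i] for i in task_idx]

    classes = rng_class.choice(
        sc.spec.n_classes, size=sc.n_respondents, p=sc.class_probs
    )
    # per-class P(choose A) for each task
    p_a_by_class = np.vstack(
        [expit(Z @ mask_beta(sc.true_beta, pat)) for pat in sc.spec.patterns]
    )
    u = rng_choice.random((sc.n_respondents, sc.n_tasks))
    chose_a = u < p_a_by_class[classes]

    rows = []
    for i in range(sc.n_respondents):
        for t, cs in enumerate(sets):
            a_chosen = int(chose_a[i, t])
            rows.append((i, t + 1, "A", *cs.option_a.levels, a_chosen))
            rows.append((i, t + 1, "B", *cs.option_b.levels, 1 - a_chosen))
    df = pd.DataFrame(
        rows,
        columns=["respondent_id", "task_id", "option", *ATTRIBUTE_COLUMNS, "chosen"],
    )

    group = []
    for c in classes:
        pat = sc.spec.patterns[c]
        group.append("full" if pat.is_full else "non" if pat.is_all_ignored else "partial")
    labels = pd.DataFrame(
        {
            "respondent_id": np.arange(sc.n_respondents),
            "true_class": classes,
            "true_class_label": [sc.spec.labels[c] for c in classes],
            "attendance_group": group,
            "straightliner": "none",
        }
    )

    info = None
    if sc.engagement:
        info = _engagement_covariates(labels, rng_engage)
    data = ChoiceDataset(df, info)

    if sc.straightliner_fraction > 0:
        data, flags = inject_straightliners(
            data, sc.straightliner_fraction, seed=rng_straight
        )
        labels["straightliner"] = labels["respondent_id"].map(flags).fillna("none")
    return data, labels


#: Class-conditional engagement profiles used when covariates are simulated:
#: median minutes on the tasks / survey and the probability of agreeing that
#: the whole description was considered.  Orderings (full > partial > non)
#: mirror what an attentive cohort should produce.
_ENGAGEMENT_PROFILES = {
    "full": {"task_time": 6.3, "survey_time": 10.2, "p_considered": 0.82},
    "partial": {"task_time": 5.0, "survey_time": 8.7, "p_considered": 0.71},
    "non": {"task_time": 3.2, "survey_time": 7.6, "p_considered": 0.56},
}


def _engagement_covariates(
    labels: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(labels)
    group = labels["attendance_group"].to_numpy()
    med_task = np.array([_ENGAGEMENT_PROFILES[g]["task_time"] for g in group])
    med_survey = np.array([_ENGAGEMENT_PROFILES[g]["survey_time"] for g in group])
    p_cons = np.array([_ENGAGEMENT_PROFILES[g]["p_considered"] for g in group])
    noise = rng.lognormal(0.0, 0.25, size=(2, n))
    answered = rng.random(n) < 0.9  # feedback questions are optional
    considered = np.where(
        answered, (rng.random(n) < p_cons).astype(float), np.nan
    )
    return pd.DataFrame(
        {
            "respondent_id": labels["respondent_id"],
            "task_time_min": med_task * noise[0],
            "survey_time_min": med_survey * noise[1],
            "feedback_considered_whole": considered,
        }
    )


def inject_straightliners(
    data: ChoiceDataset,
    fraction: float,
    seed: int | np.random.Generator | None = 0,
) -> tuple[ChoiceDataset, pd.Series]:
    """Overwrite a seeded random ``floor(fraction * n)`` subset of
    respondents with fixed-position answers (first half of the selection
    always chooses the left option, the rest the right).

    Returns the contaminated dataset and a per-respondent flag series
    ('left' / 'right') for the injected respondents.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ids = np.asarray(data.respondents)
    m = int(np.floor(fraction * len(ids)))
    if m == 0:
        return data, pd.Series(dtype=object)
    picked = np.sort(rng.choice(len(ids), size=m, replace=False))
    picked_ids = ids[picked]
    n_left = (m + 1) // 2
    side = {
        rid: ("left" if i < n_left else "right")
        for i, rid in enumerate(picked_ids)
    }
    df = data.df.copy()
    for rid, s in side.items():
        mask = df["respondent_id"] == rid
        df.loc[mask, "chosen"] = np.where(
            df.loc[mask, "option"] == ("A" if s == "left" else "B"), 1, 0
        )
    return ChoiceDataset(df, data.respondent_info), pd.Series(side)
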