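"""Construction and evaluation of paired-comparison designs.

Three design families are supported for the 5-attribute x 5-level system:

* **generator-developed** designs: start from an orthogonal array
  OA(25, 5^5, strength 2) and pair each run with its element-wise mod-5
  shift under one or more generator vectors.  With two generators that,
  per attribute, contribute one shift in {1, 4} and one in {2, 3}, the
  resulting 50 pairs are 100% D-efficient for main effects at zero priors.
  A generator with zeros leaves those attributes at identical levels in
  both options, which is how attribute-level overlap is built in.
* **modified Fedorov** designs: exchange search over an explicit candidate
  set of choice sets, minimising the D-error.
* **constrained Bayesian D-efficient** designs: exchange search minimising
  the D-error averaged over prior draws, subject to no duplicated pairs, no
  dominated options, and approximate level balance.

D-error here is ``det(M/n)^(-1/20)`` with ``M`` the multinomial-logit
information matrix of the paired design in dummy coding and ``n`` the number
of choice sets; D-efficiency against the theoretical optimum uses an
orthonormal contrast coding in which the optimal normalized information
matrix is ``I/8`` (main-effects bound for paired comparisons with 5-level
attributes).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import helmert

from .core import (
    ATTRIBUTES,
    N_ATTRIBUTES,
    N_LEVELS,
    N_PARAMS,
    ChoiceSet,
    Design,
    InvalidChoiceSetError,
    Profile,
)

__all__ = [
    "OrthogonalArray",
    "NO_OVERLAP_GENERATORS",
    "OVERLAP_GENERATORS",
    "Generator",
    "GeneratorValidation",
    "EfficiencyReport",
    "SearchFailureError",
    "InfeasibleDesignError",
    "orthogonal_array_25",
    "is_orthogonal_array",
    "generator_design",
    "validate_generators",
    "mnl_information_matrix",
    "d_error",
    "bayesian_d_error",
    "street_burgess_efficiency",
    "efficiency_report",
    "build_candidate_set",
    "enumerate_level_pairs",
    "count_candidate_pairs",
    "modified_fedorov",
    "constrained_bayesian_search",
]


#: The study's canonical generator pairs: per attribute, one shift in {1,4}
#: and one in {2,3} (100% efficient, no overlap); two zero entries per
#: generator (overlap on two attributes).
NO_OVERLAP_GENERATORS: tuple["Generator", ...]
OVERLAP_GENERATORS: tuple["Generator", ...]


class SearchFailureError(RuntimeError):
    """The exchange search could not produce a nonsingular design."""


class InfeasibleDesignError(RuntimeError):
    """The constraints (duplicates/dominance/level balance) cannot be met."""


class DegeneratePairError(ValueError):
    """An all-zero generator pairs every run with itself."""


@dataclass(frozen=True)
class OrthogonalArray:
    """A strength-2 orthogonal array: 25 runs over 5 five-level columns."""

    runs: tuple[Profile, ...]

    def __post_init__(self) -> None:
        if not is_orthogonal_array([p.levels for p in self.runs], strength=2):
            raise ValueError("runs do not form a strength-2 orthogonal array")

    def __len__(self) -> int:
        return len(self.runs)


def is_orthogonal_array(rows, strength: int = 2) -> bool:
    """Check the strength-2 property: every ordered level pair appears the
    same number of times in every pair of columns."""
    arr = np.asarray(rows, dtype=int)
    n, k = arr.shape
    if strength != 2:
        raise NotImplementedError("only strength 2 is checked")
    want = n / N_LEVELS**2
    if want != int(want):
        return False
    for i, j in itertools.combinations(range(k), 2):
        counts = np.zeros((N_LEVELS, N_LEVELS))
        np.add.at(counts, (arr[:, i] - 1, arr[:, j] - 1), 1)
        if not np.all(counts == want):
            return False
    return True


def orthogonal_array_25() -> OrthogonalArray:
    """The regular OA(25, 5^5, 2) over GF(5).

    Runs are indexed by (a, b) in {0..4}^2; the five columns are
    a, b, a+b, a+2b, a+3b (mod 5), shifted to levels 1..5.  Any two column
    coefficient vectors are linearly independent over GF(5), which gives
    strength 2.
    """
    runs = []
    for a in range(5):
        for b in range(5):
            cols = (a, b, (a + b) % 5, (a + 2 * b) % 5, (a + 3 * b) % 5)
            runs.append(Profile(tuple(c + 1 for c in cols)))
    return OrthogonalArray(tuple(runs))


@dataclass(frozen=True)
class Generator:
    """A level-shift vector applied mod 5 to every run of an orthogonal array."""

    shifts: tuple[int, ...]

    def __post_init__(self) -> None:
        shifts = tuple(int(s) for s in self.shifts)
        if len(shifts) != N_ATTRIBUTES:
            raise ValueError(f"generator needs {N_ATTRIBUTES} shifts")
        if any(not (0 <= s < N_LEVELS) for s in shifts):
            raise ValueError("generator shifts must be in 0..4")
        object.__setattr__(self, "shifts", shifts)

    @property
    def n_zero(self) -> int:
        return sum(1 for s in self.shifts if s == 0)

    def apply(self, p: Profile) -> Profile:
        """Element-wise mod-5 shift on levels mapped to {0..4} and back."""
        return Profile(
            tuple((l - 1 + s) % N_LEVELS + 1 for l, s in zip(p.levels, self.shifts))
        )


NO_OVERLAP_GENERATORS = (Generator((1, 1, 1, 2, 2)), Generator((2, 2, 2, 4, 4)))
OVERLAP_GENERATORS = (Generator((1, 1, 1, 0, 0)), Generator((0, 0, 2, 1, 1)))


def generator_design(
    oa: OrthogonalArray, generators: list[Generator], seed: int | None = None
) -> Design:
    """Pair every OA run with its shift under each generator.

    Produces ``len(oa) * len(generators)`` choice sets (runs-major order);
    each set's overlap equals the number of zero entries in its generator.
    """
    overlaps = {g.n_zero for g in generators}
    for g in generators:
        if g.n_zero == N_ATTRIBUTES:
            raise DegeneratePairError("all-zero generator pairs a run with itself")
    sets = [
        ChoiceSet(run, g.apply(run)) for run in oa.runs for g in generators
    ]
    target = overlaps.pop() if len(overlaps) == 1 else None
    return Design(
        sets,
        method="generator",
        overlap_target=target,
        seed=seed,
    )


@dataclass
class GeneratorValidation:
    """Per-attribute audit of the generator selection rules."""

    overlap_target: int
    per_attribute: dict[str, bool]
    per_generator: dict[int, bool]
    passed: bool
    messages: list[str] = field(default_factory=list)


def validate_generators(
    generators: list[Generator], overlap_target: int
) -> GeneratorValidation:
    """Audit generators against the selection rules for each overlap target.

    No overlap (target 0): across the generators, every attribute must see
    one shift in {1, 4} and one in {2, 3} (the condition for a 100%
    main-effects-efficient paired design at zero priors), and no shift may
    be zero.  Overlap on two attributes (target 2): every generator must
    have exactly two zero entries.
    """
    msgs: list[str] = []
    per_attr: dict[str, bool] = {}
    per_gen: dict[int, bool] = {}
    if overlap_target == 0:
        for gi, g in enumerate(generators):
            ok = all(s != 0 for s in g.shifts)
            per_gen[gi] = ok
            if not ok:
                msgs.append(f"generator {gi} has zero entries but target overlap is 0")
        for k, name in enumerate(ATTRIBUTES):
            shifts = {g.shifts[k] for g in generators}
            ok = bool(shifts & {1, 4}) and bool(shifts & {2, 3})
            per_attr[name] = ok
            if not ok:
                msgs.append(
                    f"attribute {name}: shifts {sorted(shifts)} lack a {{1,4}} "
                    "and a {2,3} entry"
                )
    elif overlap_target == 2:
        for gi, g in enumerate(generators):
            ok = g.n_zero == 2
            per_gen[gi] = ok
            if not ok:
                msgs.append(
                    f"generator {gi} has {g.n_zero} zero entries, need exactly 2"
                )
        for k, name in enumerate(ATTRIBUTES):
            per_attr[name] = True
    else:
        raise ValueError("overlap_target must be 0 or 2")
    passed = all(per_attr.values()) and all(per_gen.values())
    return GeneratorValidation(overlap_target, per_attr, per_gen, passed, msgs)


# ---------------------------------------------------------------------------
# Efficiency measures


def _choice_weights(Z: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """p(1-p) per choice set for the paired logit at ``beta``."""
    eta = Z @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    return p * (1.0 - p)


def mnl_information_matrix(d: Design, beta: np.ndarray | None = None) -> np.ndarray:
    """Unnormalized information matrix ``sum_s p_s(1-p_s) z_s z_s'``.

    ``z_s`` is the dummy-coded difference vector of choice set ``s`` and
    ``p_s`` the probability of option A at ``beta``.  At ``beta = 0`` every
    ``p_s`` is 1/2, so M reduces to ``0.25 * sum z z'``.
    """
    Z = d.difference_matrix()
    if beta is None:
        beta = np.zeros(N_PARAMS)
    beta = np.asarray(beta, dtype=float)
    w = _choice_weights(Z, beta)
    return (Z * w[:, None]).T @ Z


def d_error(d: Design, beta: np.ndarray | None = None) -> float:
    """``det(M/n)^(-1/K)`` with K = 20; +inf when M is singular.

    Normalizing by the number of choice sets makes the value comparable
    across designs of different sizes (duplicating every set leaves it
    unchanged).
    """
    n = len(d)
    if n == 0:
        return math.inf
    M = mnl_information_matrix(d, beta) / n
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0 or not np.isfinite(logdet):
        return math.inf
    return float(np.exp(-logdet / N_PARAMS))


def bayesian_d_error(d: Design, prior_draws) -> float:
    """Mean D-error over prior draws; with the single zero draw this equals
    the zero-prior D-error."""
    draws = [np.asarray(b, dtype=float) for b in prior_draws]
    if not draws:
        raise ValueError("prior_draws must be nonempty")
    errs = [d_error(d, b) for b in draws]
    if all(math.isinf(e) for e in errs):
        return math.inf
    return float(np.mean(errs))


#: Orthonormal contrast coding of a 5-level attribute: columns are the
#: (l-1)-dim codes of levels 1..5; rows orthonormal and orthogonal to ones.
_CONTRAST = helmert(N_LEVELS)

#: Optimal normalized per-attribute information block value for paired
#: comparisons (main effects, zero priors): 1 / (2 (l - 1)).
_OPT_BLOCK = 1.0 / (2.0 * (N_LEVELS - 1))


def _orthonormal_difference_matrix(d: Design) -> np.ndarray:
    """(n, 20) difference matrix under the orthonormal contrast coding."""
    rows = []
    for cs in d.choice_sets:
        parts = [
            _CONTRAST[:, a - 1] - _CONTRAST[:, b - 1]
            for a, b in zip(cs.option_a.levels, cs.option_b.levels)
        ]
        rows.append(np.concatenate(parts))
    return np.asarray(rows)


def street_burgess_efficiency(d: Design) -> float:
    """D-efficiency at zero priors against the main-effects optimal bound.

    The normalized information matrix is computed in the orthonormal
    contrast coding, where the optimal determinant for paired comparisons
    on five 5-level attributes is ``(1/8)^20``.  Returns
    ``(det C / det C_opt)^(1/20)``: 1.0 means 100% efficient; singular
    designs score 0.
    """
    n = len(d)
    if n == 0:
        return 0.0
    Z = _orthonormal_difference_matrix(d)
    C = 0.25 * (Z.T @ Z) / n
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0 or not np.isfinite(logdet):
        return 0.0
    log_eff = logdet / N_PARAMS - math.log(_OPT_BLOCK)
    return float(np.exp(log_eff))


@dataclass
class EfficiencyReport:
    """Summary of a design's statistical quality at a given prior."""

    n_choice_sets: int
    d_error: float
    d_efficiency_vs_bound: float
    information_matrix: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n_choice_sets": self.n_choice_sets,
            "d_error": self.d_error,
            "d_efficiency_vs_bound": self.d_efficiency_vs_bound,
        }


def efficiency_report(d: Design, beta: np.ndarray | None = None) -> EfficiencyReport:
    return EfficiencyReport(
        n_choice_sets=len(d),
        d_error=d_error(d, beta),
        d_efficiency_vs_bound=street_burgess_efficiency(d),
        information_matrix=mnl_information_matrix(d, beta),
    )


# ---------------------------------------------------------------------------
# Candidate enumeration


def _cartesian(arrays: list[np.ndarray]) -> np.ndarray:
    """Lexicographic cartesian product, first array slowest-varying."""
    grids = np.meshgrid(*arrays, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def count_candidate_pairs(
    overlap_target: int, n_attributes: int = N_ATTRIBUTES, n_levels: int = N_LEVELS
) -> int:
    """Closed-form count of unordered profile pairs with exactly
    ``overlap_target`` overlapping attributes:
    C(K, o) * L^o * (L(L-1))^(K-o) / 2."""
    K, L, o = n_attributes, n_levels, overlap_target
    if not (0 <= o < K):
        raise ValueError("overlap_target must be in 0..K-1")
    return math.comb(K, o) * L**o * (L * (L - 1)) ** (K - o) // 2


def enumerate_level_pairs(
    overlap_target: int,
    n_attributes: int = N_ATTRIBUTES,
    n_levels: int = N_LEVELS,
) -> tuple[np.ndarray, np.ndarray]:
    """All unordered level-vector pairs with exactly ``overlap_target``
    equal positions, as two (m, K) arrays in a fixed lexicographic order.

    Generic in the attribute system; unordered identity is enforced by
    requiring the A side to carry the lower level at the first differing
    position.
    """
    K, L, o = n_attributes, n_levels, overlap_target
    if not (0 <= o < K):
        raise ValueError("overlap_target must be in 0..K-1")
    eq_levels = np.arange(1, L + 1)
    # ordered level pairs (a, b), a != b, lexicographic
    ordered = np.array([(a, b) for a in range(1, L + 1) for b in range(1, L + 1) if a != b])
    # first differing attribute: a < b only (unordered identity)
    first = np.array([(a, b) for a in range(1, L + 1) for b in range(a + 1, L + 1)])

    blocks_a, blocks_b = [], []
    for mask in itertools.combinations(range(K), o):
        diff_pos = [k for k in range(K) if k not in mask]
        comps: list[np.ndarray] = []
        for k in mask:
            comps.append(np.arange(len(eq_levels)))
        comps_first = np.arange(len(first))
        comps_rest = [np.arange(len(ordered)) for _ in diff_pos[1:]]
        # component order: equal positions (by attribute index), then the
        # differing positions in attribute order
        idx = _cartesian(comps + [comps_first] + comps_rest)
        m = idx.shape[0]
        A = np.empty((m, K), dtype=np.int8)
        B = np.empty((m, K), dtype=np.int8)
        for j, k in enumerate(mask):
            A[:, k] = eq_levels[idx[:, j]]
            B[:, k] = A[:, k]
        A[:, diff_pos[0]] = first[idx[:, o], 0]
        B[:, diff_pos[0]] = first[idx[:, o], 1]
        for j, k in enumerate(diff_pos[1:]):
            A[:, k] = ordered[idx[:, o + 1 + j], 0]
            B[:, k] = ordered[idx[:, o + 1 + j], 1]
        blocks_a.append(A)
        blocks_b.append(B)
    return np.concatenate(blocks_a), np.concatenate(blocks_b)


def build_candidate_set(
    overlap_target: int,
    limit: int | None = None,
    seed: int | None = None,
    exclude_dominated: bool = False,
) -> list[ChoiceSet]:
    """Enumerate all unordered 5x5-system pairs with exactly
    ``overlap_target`` overlapping attributes, in a fixed lexicographic
    order (see :func:`enumerate_level_pairs`).

    ``exclude_dominated`` drops pairs where one option weakly improves on
    the other everywhere.  With ``limit`` a seeded uniform subsample (kept
    in enumeration order) is returned.
    """
    A, B = enumerate_level_pairs(overlap_target)

    if exclude_dominated:
        a_dom = np.all(A <= B, axis=1)  # first diff has A < B, so <= => dominates
        b_dom = np.all(B <= A, axis=1)
        keep = ~(a_dom | b_dom)
        A, B = A[keep], B[keep]

    total = A.shape[0]
    if limit is not None:
        if limit > total:
            raise ValueError(f"limit {limit} exceeds population {total}")
        rng = np.random.default_rng(seed)
        pick = np.sort(rng.choice(total, size=limit, replace=False))
        A, B = A[pick], B[pick]

    return [
        ChoiceSet(Profile(tuple(int(v) for v in a)), Profile(tuple(int(v) for v in b)))
        for a, b in zip(A, B)
    ]


# ---------------------------------------------------------------------------
# Exchange searches


def _log_det_objective(Z: np.ndarray, w: np.ndarray, idx: np.ndarray) -> float:
    """log det of the (unnormalized) information matrix of the selected sets."""
    Zs = Z[idx]
    M = (Zs * w[idx, None]).T @ Zs
    sign, logdet = np.linalg.slogdet(M)
    return logdet if sign > 0 else -math.inf


def modified_fedorov(
    candidates: list[ChoiceSet],
    n_sets: int,
    beta: np.ndarray | None = None,
    seed: int | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
    n_restarts: int = 1,
) -> Design:
    """Exchange search minimising the D-error over subsets of ``candidates``.

    Starts from a seeded random duplicate-free subset of size ``n_sets`` and
    sweeps design positions; at each position every candidate is tried and
    the exchange with the largest D-error reduction is accepted (ties go to
    the lowest candidate index).  Terminates when a full sweep improves the
    D-error by less than ``tol`` (relative) or after ``max_iter`` sweeps.
    The result is never worse than the starting design.  ``n_restarts``
    repeats the search from distinct seeded starting subsets and keeps the
    lowest D-error (exchange searches are local; restarts are the usual
    guard against local optima).

    The per-exchange determinant update uses the rank-2 matrix determinant
    lemma when the current information matrix is invertible, falling back to
    direct ``slogdet`` while it is singular.
    """
    if n_restarts > 1:
        child_seeds = np.random.SeedSequence(seed).generate_state(n_restarts)
        results = []
        for cseed in child_seeds:
            try:
                results.append(
                    modified_fedorov(
                        candidates, n_sets, beta, int(cseed) % 2**31, max_iter, tol
                    )
                )
            except SearchFailureError:
                continue
        if not results:
            raise SearchFailureError(
                "every restart produced a singular information matrix"
            )
        best = min(results, key=lambda des: d_error(des, beta))
        best.seed = seed
        return best
    if beta is None:
        beta = np.zeros(N_PARAMS)
    beta = np.asarray(beta, dtype=float)
    n_cand = len(candidates)
    if n_cand == 0:
        raise ValueError("candidate pool is empty")
    if n_sets > n_cand:
        raise ValueError("n_sets exceeds candidate pool size")
    keys = [cs.key for cs in candidates]
    if len(set(keys)) != n_cand:
        raise ValueError("candidate pool contains duplicate pairs")
    if n_sets == n_cand:
        return Design(list(candidates), method="fedorov", seed=seed)

    Z = np.vstack([cs.difference_vector() for cs in candidates])
    w = _choice_weights(Z, beta)
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_cand, size=n_sets, replace=False)
    in_design = np.zeros(n_cand, dtype=bool)
    in_design[idx] = True

    logdet = _log_det_objective(Z, w, idx)
    trace = [logdet]
    for _ in range(max_iter):
        improved_this_sweep = 0.0
        sweep_start = logdet
        for pos in range(n_sets):
            i = idx[pos]
            if math.isfinite(logdet):
                Zs = Z[idx]
                M = (Zs * w[idx, None]).T @ Zs
                Minv = np.linalg.inv(M)
                zi = Z[i]
                ZMZ = Z @ (Minv @ zi)  # t_j = z_j' Minv z_i
                s = np.einsum("ij,ij->i", Z @ Minv, Z)  # z_j' Minv z_j
                u = float(zi @ Minv @ zi)
                ratio = (1.0 + w * s) * (1.0 - w[i] * u) + w * w[i] * ZMZ**2
                ratio[in_design] = -math.inf
                ratio[i] = 1.0  # keeping the current set is neutral
                j = int(np.argmax(ratio))
                if ratio[j] > 1.0 and j != i:
                    gain = math.log(ratio[j])
                    idx[pos] = j
                    in_design[i] = False
                    in_design[j] = True
                    logdet += gain
                else:
                    continue
            else:
                # singular information: score candidates by direct slogdet
                best_j, best_val = i, logdet
                for j in range(n_cand):
                    if in_design[j] and j != i:
                        continue
                    trial = idx.copy()
                    trial[pos] = j
                    val = _log_det_objective(Z, w, trial)
                    if val > best_val + 1e-12:
                        best_j, best_val = j, val
                if best_j != i:
                    idx[pos] = best_j
                    in_design[i] = False
                    in_design[best_j] = True
                    logdet = best_val
        # exact recompute to kill drift from incremental updates
        logdet = _log_det_objective(Z, w, idx)
        trace.append(logdet)
        improved_this_sweep = logdet - sweep_start
        if math.isfinite(logdet) and improved_this_sweep < tol * N_PARAMS:
            break
    if not math.isfinite(logdet):
        raise SearchFailureError(
            "every explored design has a singular information matrix"
        )
    design = Design(
        [candidates[i] for i in idx], method="fedorov", seed=seed
    )
    design.search_trace = trace  # type: ignore[attr-defined]
    return design


def _level_balance_violation(
    counts: np.ndarray, n_sets: int, tol: float
) -> float:
    """Total excess of per-attribute level counts beyond ±tol of 2n/5."""
    target = 2.0 * n_sets / N_LEVELS
    return float(np.maximum(0.0, np.abs(counts - target) - tol).sum())


def _level_counts(A: np.ndarray, B: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """(5 attributes x 5 levels) level counts over both options of the
    selected sets."""
    counts = np.zeros((N_ATTRIBUTES, N_LEVELS))
    for arr in (A[idx], B[idx]):
        for k in range(N_ATTRIBUTES):
            np.add.at(counts[k], arr[:, k] - 1, 1)
    return counts


def constrained_bayesian_search(
    n_sets: int,
    prior_draws,
    level_balance_tol: float = 1.0,
    seed: int | None = None,
    max_iter: int = 20,
    overlap_target: int | None = None,
    candidate_pool: list[ChoiceSet] | None = None,
    candidate_limit: int = 2000,
) -> Design:
    """Constrained exchange search minimising the Bayesian D-error.

    Constraints: no duplicated unordered pair, no dominated option in any
    pair, and level balance -- every level of every attribute appears across
    the ``2 * n_sets`` options within ``level_balance_tol`` of the uniform
    count ``2 n / 5``.  Acceptance is lexicographic (balance violation
    first, then Bayesian D-error), so a feasible design is reached before
    efficiency is polished.  Raises :class:`InfeasibleDesignError` when no
    explored design satisfies the balance constraint.

    The candidate pool defaults to a seeded subsample of the exhaustive
    non-dominated enumeration at ``overlap_target`` (or of random distinct
    pairs when no overlap target is set).
    """
    draws = [np.asarray(b, dtype=float) for b in prior_draws]
    if not draws:
        raise ValueError("prior_draws must be nonempty")
    rng = np.random.default_rng(seed)
    if candidate_pool is None:
        if overlap_target is not None:
            pool_total = count_candidate_pairs(overlap_target)
            limit = candidate_limit if candidate_limit < pool_total else None
            candidate_pool = build_candidate_set(
                overlap_target,
                limit=limit,
                seed=int(rng.integers(2**31)),
                exclude_dominated=True,
            )
        else:
            candidate_pool = _random_pairs(candidate_limit, rng)
    candidates = [cs for cs in candidate_pool if not cs.has_dominated_option()]
    n_cand = len(candidates)
    if n_sets > n_cand:
        raise InfeasibleDesignError("candidate pool smaller than n_sets")

    Z = np.vstack([cs.difference_vector() for cs in candidates])
    A = np.array([cs.option_a.levels for cs in candidates], dtype=np.int16)
    B = np.array([cs.option_b.levels for cs in candidates], dtype=np.int16)
    W = np.stack([_choice_weights(Z, b) for b in draws])  # (draws, n_cand)

    def objective(idx: np.ndarray) -> tuple[float, float]:
        counts = _level_counts(A, B, idx)
        viol = _level_balance_violation(counts, n_sets, level_balance_tol)
        errs = []
        Zs = Z[idx]
        for dr in range(len(draws)):
            M = (Zs * W[dr, idx, None]).T @ Zs / n_sets
            sign, logdet = np.linalg.slogdet(M)
            errs.append(
                math.inf if sign <= 0 else float(np.exp(-logdet / N_PARAMS))
            )
        derr = math.inf if all(math.isinf(e) for e in errs) else float(np.mean(errs))
        return viol, derr

    idx = rng.choice(n_cand, size=n_sets, replace=False)
    in_design = np.zeros(n_cand, dtype=bool)
    in_design[idx] = True
    cur = objective(idx)
    for _ in range(max_iter):
        accepted = False
        for pos in range(n_sets):
            i = idx[pos]
            best_j, best = i, cur
            for j in range(n_cand):
                if in_design[j] and j != i:
                    continue
                if j == i:
                    continue
                idx[pos] = j
                val = objective(idx)
                if val < best:
                    best_j, best = j, val
            idx[pos] = best_j
            if best_j != i:
                in_design[i] = False
                in_design[best_j] = True
                cur = best
                accepted = True
        if not accepted:
            break
    if cur[0] > 0:
        raise InfeasibleDesignError(
            f"level balance violation {cur[0]:.1f} remains after search "
            f"(tol {level_balance_tol})"
        )
    design = Design(
        [candidates[i] for i in idx],
        method="bayesian",
        overlap_target=overlap_target,
        seed=seed,
    )
    design.bayesian_d_error_ = cur[1]  # type: ignore[attr-defined]
    return design


def _random_pairs(limit: int, rng: np.random.Generator) -> list[ChoiceSet]:
    """Seeded distinct non-dominated random pairs over the full 5^5 space."""
    seen: set = set()
    out: list[ChoiceSet] = []
    while len(out) < limit:
        a, b = rng.integers(1, N_LEVELS + 1, size=(2, N_ATTRIBUTES))
        if np.all(a == b):
            continue
        cs = ChoiceSet(Profile(tuple(int(v) for v in a)), Profile(tuple(int(v) for v in b)))
        if cs.key in seen or cs.has_dominated_option():
            continue
        seen.add(cs.key)
        out.append(cs)
    return out
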