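"""Equality-constrained latent class (ECLC) model of attribute non-attendance.

Respondents fall into latent classes defined not by different preferences
but by which attributes they attend to: all classes share one 20-dim
preference vector ``beta``, and a class that ignores an attribute has that
attribute's four level coefficients constrained to zero.  With five
attributes there are 2^5 = 32 possible attendance patterns; the class that
ignores everything implies a choice probability of exactly 1/2 for every
pair (random choice).

Estimation is by EM.  The E-step computes each respondent's posterior class
probabilities from the current ``(beta, pi)``; the M-step sets ``pi`` to the
mean posteriors and maximises the expected complete-data log-likelihood over
``beta`` -- a posterior-weighted paired logit over class-masked design
matrices -- by Newton steps with step-halving, which keeps the EM trace
monotone.  Class labels are structural (tied to attendance patterns), so
there is no label-switching ambiguity.

Model selection follows a five-step sequential procedure: start with full
attendance plus the five single-ignored patterns, then in turn offer the
two-, three-, and (four-ignored + all-ignored) patterns, dropping after
each fit every class whose membership probability falls below a threshold
(default 5%); dropped classes never re-enter.  The final model keeps only
the surviving classes.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from .core import ATTRIBUTES, N_ATTRIBUTES, N_PARAMS, PARAM_NAMES
from .data import ChoiceDataset
from .mnl import fit_mnl

logger = logging.getLogger(__name__)

__all__ = [
    "AttendancePattern",
    "ECLCSpec",
    "ECLCFit",
    "StepRecord",
    "StepwiseError",
    "all_patterns",
    "patterns_ignoring",
    "mask_beta",
    "eclc_loglik",
    "fit_eclc",
    "stepwise_selection",
    "classify_respondents",
    "class_prob_cis",
]


@dataclass(frozen=True)
class AttendancePattern:
    """A 5-bit attendance mask; True = the attribute is considered.

    Labelled by the attributes *not* attended, e.g. ``"None"`` for full
    attendance, ``"PD+AD"``, ``"MO+SC+UA+PD+AD"`` for ignoring everything.
    """

    attended: tuple[bool, ...]

    def __post_init__(self) -> None:
        att = tuple(bool(v) for v in self.attended)
        if len(att) != N_ATTRIBUTES:
            raise ValueError(f"pattern needs {N_ATTRIBUTES} flags")
        object.__setattr__(self, "attended", att)

    @classmethod
    def full(cls) -> "AttendancePattern":
        return cls((True,) * N_ATTRIBUTES)

    @classmethod
    def all_ignored(cls) -> "AttendancePattern":
        return cls((False,) * N_ATTRIBUTES)

    @classmethod
    def ignoring(cls, *names: str) -> "AttendancePattern":
        """Pattern that ignores the named attributes, e.g. ``ignoring("PD", "AD")``."""
        bad = [n for n in names if n.upper() not in ATTRIBUTES]
        if bad:
            raise ValueError(f"unknown attributes: {bad}")
        ignored = {n.upper() for n in names}
        return cls(tuple(a not in ignored for a in ATTRIBUTES))

    @classmethod
    def from_label(cls, label: str) -> "AttendancePattern":
        if label == "None":
            return cls.full()
        return cls.ignoring(*label.split("+"))

    @property
    def label(self) -> str:
        ignored = [a for a, att in zip(ATTRIBUTES, self.attended) if not att]
        return "+".join(ignored) if ignored else "None"

    @property
    def n_ignored(self) -> int:
        return sum(1 for a in self.attended if not a)

    @property
    def is_full(self) -> bool:
        return all(self.attended)

    @property
    def is_all_ignored(self) -> bool:
        return not any(self.attended)

    def coefficient_mask(self) -> np.ndarray:
        """20-vector of 0/1: 1 where the coefficient is free in this class."""
        m = np.zeros(N_PARAMS)
        for k, att in enumerate(self.attended):
            if att:
                m[4 * k : 4 * k + 4] = 1.0
        return m


def all_patterns() -> list[AttendancePattern]:
    """All 32 attendance patterns, full attendance first, then by number of
    ignored attributes (combination order within each count)."""
    out = [AttendancePattern.full()]
    for k in range(1, N_ATTRIBUTES + 1):
        out.extend(patterns_ignoring(k))
    return out


def patterns_ignoring(k: int) -> list[AttendancePattern]:
    """The C(5, k) patterns that ignore exactly ``k`` attributes."""
    out = []
    for combo in itertools.combinations(ATTRIBUTES, k):
        out.append(AttendancePattern.ignoring(*combo))
    return out


@dataclass(frozen=True)
class ECLCSpec:
    """The ordered set of attendance patterns included as classes."""

    patterns: tuple[AttendancePattern, ...]

    def __post_init__(self) -> None:
        pats = tuple(self.patterns)
        if not pats:
            raise ValueError("spec needs at least one class")
        if len({p.attended for p in pats}) != len(pats):
            raise ValueError("duplicate attendance patterns in spec")
        object.__setattr__(self, "patterns", pats)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.patterns]

    @property
    def n_classes(self) -> int:
        return len(self.patterns)

    def mask_matrix(self) -> np.ndarray:
        """(n_classes, 20) stack of coefficient masks."""
        return np.vstack([p.coefficient_mask() for p in self.patterns])


def mask_beta(beta: np.ndarray, pattern: AttendancePattern) -> np.ndarray:
    """Class-specific coefficients: shared ``beta`` with ignored attributes'
    level dummies zeroed."""
    beta = np.asarray(beta, dtype=float)
    return beta * pattern.coefficient_mask()


@dataclass
class ECLCFit:
    """Fitted ECLC model."""

    beta: np.ndarray
    class_probs: np.ndarray
    spec: ECLCSpec
    posteriors: pd.DataFrame  # respondents x class labels
    loglik: float
    aic: float
    bic: float
    em_trace: list[float]
    n_params: int
    converged: bool
    collapsed: list[str] = field(default_factory=list)
    class_prob_ci: pd.DataFrame | None = None

    def class_table(self) -> pd.DataFrame:
        tab = pd.DataFrame(
            {
                "attributes_non_attended": self.spec.labels,
                "prob": self.class_probs,
            }
        )
        if self.class_prob_ci is not None:
            tab = tab.join(self.class_prob_ci.reset_index(drop=True))
        return tab

    def to_dict(self) -> dict:
        out = {
            "classes": self.spec.labels,
            "class_probs": [float(p) for p in self.class_probs],
            "beta": dict(zip(PARAM_NAMES, map(float, self.beta))),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "n_params": int(self.n_params),
            "converged": bool(self.converged),
            "collapsed": self.collapsed,
        }
        if self.class_prob_ci is not None:
            out["class_prob_ci"] = {
                lab: [float(lo), float(hi)]
                for lab, lo, hi in zip(
                    self.spec.labels,
                    self.class_prob_ci["ci_lo"],
                    self.class_prob_ci["ci_hi"],
                )
            }
        return out


def _class_task_loglik(
    beta: np.ndarray, Z: np.ndarray, y: np.ndarray, masks: np.ndarray
) -> np.ndarray:
    """(n_tasks, n_classes) log-probability of the observed choice per class."""
    s = (2.0 * y - 1.0)[:, None]
    eta = Z @ (masks * beta).T  # (tasks, classes)
    return -np.logaddexp(0.0, -s * eta)


def _respondent_loglik(
    task_ll: np.ndarray, codes: np.ndarray, n_resp: int
) -> np.ndarray:
    acc = np.zeros((n_resp, task_ll.shape[1]))
    np.add.at(acc, codes, task_ll)
    return acc


def eclc_loglik(
    beta: np.ndarray,
    class_probs: np.ndarray,
    data: ChoiceDataset,
    spec: ECLCSpec,
) -> float:
    """Mixture log-likelihood: sum_i log sum_c pi_c prod_t P(choice | beta_c)."""
    beta = np.asarray(beta, dtype=float)
    pi = np.asarray(class_probs, dtype=float)
    if pi.shape != (spec.n_classes,):
        raise ValueError("class_probs length must match the spec")
    if np.any(pi < -1e-12) or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("class_probs must lie on the simplex")
    codes, Z, y = data.design_arrays()
    masks = spec.mask_matrix()
    L = _respondent_loglik(_class_task_loglik(beta, Z, y, masks), codes, data.n_respondents)
    with np.errstate(divide="ignore"):
        lp = np.log(pi)[None, :] + L
    return float(logsumexp(lp, axis=1).sum())


def _m_step_beta(
    beta: np.ndarray,
    W: np.ndarray,  # (n_resp, n_classes) posterior weights
    Z: np.ndarray,
    y: np.ndarray,
    codes: np.ndarray,
    masks: np.ndarray,
    free: np.ndarray,
    max_newton: int = 5,
    gtol: float = 1e-8,
) -> np.ndarray:
    """Increase the expected complete-data loglik over the shared beta.

    A few Newton steps with step-halving (generalized EM): any Q increase
    keeps the outer EM trace monotone, and full maximisation per iteration
    is unnecessary.  Coefficients attended in no class stay fixed (their
    gradient is identically zero).  Gradient and Hessian are accumulated
    over classes in one einsum each; the all-ignored class's masked design
    rows are all zero, so it drops out automatically.
    """
    Wt = W[codes]  # (tasks, classes)

    def q_value(b: np.ndarray) -> float:
        ll = _class_task_loglik(b, Z, y, masks)
        return float((Wt * ll).sum())

    beta = beta.copy()
    q = q_value(beta)
    for _ in range(max_newton):
        eta = Z @ (masks * beta).T  # (tasks, classes)
        P = expit(eta)
        R = Wt * (y[:, None] - P)  # residual weights per class
        S = Wt * P * (1.0 - P)
        # grad = sum_c m_c * (Z' r_c);  hess = sum_c (m_c m_c') * (Z' diag(s_c) Z)
        G = Z.T @ R  # (params, classes)
        grad = (G * masks.T).sum(axis=1) * free
        if np.linalg.norm(grad) < gtol:
            break
        hess = np.zeros((N_PARAMS, N_PARAMS))
        for c in range(masks.shape[0]):
            if not masks[c].any():
                continue
            A = Z.T @ (Z * S[:, c : c + 1])
            hess += np.outer(masks[c], masks[c]) * A
        hess = hess * np.outer(free, free)
        hess[np.diag_indices_from(hess)] += (1.0 - free) + 1e-10
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(hess) @ grad
        # step-halving: guarantee Q does not decrease
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            qc = q_value(cand)
            if qc >= q - 1e-12:
                beta, q = cand, qc
                break
            t *= 0.5
        else:
            break
    return beta


def fit_eclc(
    data: ChoiceDataset,
    spec: ECLCSpec,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 3,
    init_beta: np.ndarray | None = None,
) -> ECLCFit:
    """EM estimation of the ECLC model.

    Initialisation: uniform class probabilities and the plain MNL ``beta``
    (restarts jitter it with seeded noise); the restart with the best final
    log-likelihood is kept.  Convergence when the log-likelihood gain drops
    below ``tol``.  A class whose probability collapses towards zero is
    reported in ``collapsed``, not raised.
    """
    codes, Z, y = data.design_arrays()
    if init_beta is None:
        base = fit_mnl(data)
        init_beta = (
            np.asarray(base.beta, float)
            if np.all(np.isfinite(base.beta))
            else np.zeros(N_PARAMS)
        )
    best = None
    seeds = np.random.SeedSequence(seed).generate_state(max(1, n_restarts))
    for r, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        beta0 = init_beta + (rng.normal(0, 0.1 * r, N_PARAMS) if r else 0.0)
        fit = _em(data, spec, beta0, codes, Z, y, tol, max_iter)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best  # type: ignore[return-value]


def _em(
    data: ChoiceDataset,
    spec: ECLCSpec,
    beta0: np.ndarray,
    codes: np.ndarray,
    Z: np.ndarray,
    y: np.ndarray,
    tol: float,
    max_iter: int,
) -> ECLCFit:
    n_resp = data.n_respondents
    masks = spec.mask_matrix()
    free = (masks.sum(axis=0) > 0).astype(float)
    beta = np.asarray(beta0, dtype=float) * free
    pi = np.full(spec.n_classes, 1.0 / spec.n_classes)
    trace: list[float] = []
    converged = False
    ll_old = -np.inf
    for _ in range(max_iter):
        L = _respondent_loglik(_class_task_loglik(beta, Z, y, masks), codes, n_resp)
        with np.errstate(divide="ignore"):
            lp = np.log(np.maximum(pi, 1e-300))[None, :] + L
        lse = logsumexp(lp, axis=1)
        ll = float(lse.sum())
        trace.append(ll)
        if ll - ll_old < tol:
            converged = ll - ll_old > -1e-8
            break
        ll_old = ll
        W = np.exp(lp - lse[:, None])
        pi = W.mean(axis=0)
        beta = _m_step_beta(beta, W, Z, y, codes, masks, free)
    # final posteriors at the converged parameters
    L = _respondent_loglik(_class_task_loglik(beta, Z, y, masks), codes, n_resp)
    with np.errstate(divide="ignore"):
        lp = np.log(np.maximum(pi, 1e-300))[None, :] + L
    lse = logsumexp(lp, axis=1)
    W = np.exp(lp - lse[:, None])
    loglik = float(lse.sum())
    n_params = int(free.sum()) + spec.n_classes - 1
    aic = -2 * loglik + 2 * n_params
    bic = -2 * loglik + n_params * np.log(data.n_tasks)
    collapsed = [
        lab for lab, p in zip(spec.labels, pi) if p < 1e-12
    ]
    posteriors = pd.DataFrame(W, index=data.respondents, columns=spec.labels)
    return ECLCFit(
        beta=beta,
        class_probs=pi,
        spec=spec,
        posteriors=posteriors,
        loglik=loglik,
        aic=aic,
        bic=bic,
        em_trace=trace,
        n_params=n_params,
        converged=converged,
        collapsed=collapsed,
    )


@dataclass
class StepRecord:
    """One step of the sequential class-selection procedure."""

    step: int
    labels: list[str]
    class_probs: np.ndarray
    loglik: float
    dropped: list[str]


class StepwiseError(RuntimeError):
    """Every class fell below the membership threshold at some step."""

    def __init__(self, message: str, trace: list[StepRecord]):
        super().__init__(message)
        self.trace = trace


def stepwise_selection(
    data: ChoiceDataset,
    threshold: float = 0.05,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 1,
    screen_tol: float = 1e-4,
    screen_max_iter: int = 200,
) -> tuple[ECLCFit, list[StepRecord]]:
    """Five-step sequential inclusion/exclusion of attendance patterns.

    Step 1 fits full attendance plus the five one-ignored patterns (six
    classes); steps 2 and 3 drop classes with membership probability below
    ``threshold`` and offer the ten two-ignored, then ten three-ignored
    patterns; step 4 offers the five single-attended patterns and the
    all-ignored class; step 5 re-fits keeping only the surviving classes.
    Dropped classes are never re-added.  Returns the final fit plus the
    per-step trace.

    The screening fits (steps 1-4) only need class probabilities accurate
    enough for the threshold decision, so they use the looser
    ``screen_tol`` / ``screen_max_iter``; the final model is re-fit at the
    full ``tol``.
    """
    additions = [
        [AttendancePattern.full()] + patterns_ignoring(1),
        patterns_ignoring(2),
        patterns_ignoring(3),
        patterns_ignoring(4) + [AttendancePattern.all_ignored()],
        [],
    ]
    init_beta = None
    current: list[AttendancePattern] = []
    trace: list[StepRecord] = []
    fit: ECLCFit | None = None
    for step, adds in enumerate(additions, start=1):
        current = current + adds
        spec = ECLCSpec(tuple(current))
        final = step == len(additions)
        fit = fit_eclc(
            data,
            spec,
            seed=seed + step,
            tol=tol if final else max(tol, screen_tol),
            max_iter=max_iter if final else screen_max_iter,
            n_restarts=n_restarts,
            init_beta=init_beta,
        )
        init_beta = fit.beta
        keep = fit.class_probs >= threshold
        dropped = [lab for lab, k in zip(spec.labels, keep) if not k]
        trace.append(
            StepRecord(step, spec.labels, fit.class_probs.copy(), fit.loglik, dropped)
        )
        if not keep.any():
            raise StepwiseError(
                f"all classes fell below the {threshold:.0%} membership "
                f"threshold at step {step}",
                trace,
            )
        current = [p for p, k in zip(spec.patterns, keep) if k]
    if threshold <= 0 and fit is not None and fit.spec.n_classes >= 32:
        logger.warning(
            "threshold 0 retains all 32 attendance patterns; "
            "over-identification is likely"
        )
    assert fit is not None
    return fit, trace


def classify_respondents(fit: ECLCFit) -> pd.Series:
    """Map each respondent to full / partial / non attendance by modal
    posterior class (ties broken toward the class with larger overall
    probability)."""
    has_full = any(p.is_full for p in fit.spec.patterns)
    if not has_full:
        warnings.warn(
            "fitted spec lacks a full-attendance class; "
            "classification limited to partial/non",
            stacklevel=2,
        )
    W = fit.posteriors.to_numpy()
    pi = fit.class_probs
    # modal class; among posteriors tied within 1e-12, prefer larger pi
    order_score = W + 1e-12 * (pi / max(pi.max(), 1e-300))[None, :]
    modal = np.argmax(order_score, axis=1)
    labels = []
    for c in modal:
        pat = fit.spec.patterns[c]
        if pat.is_full:
            labels.append("full")
        elif pat.is_all_ignored:
            labels.append("non")
        else:
            labels.append("partial")
    return pd.Series(labels, index=fit.posteriors.index, name="attendance_class")


def class_prob_cis(
    fit: ECLCFit,
    data: ChoiceDataset,
    n_boot: int = 200,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> pd.DataFrame:
    """Percentile 95% CIs for the class probabilities by nonparametric
    bootstrap over respondents (fixed spec, warm-started re-fits)."""
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    ids = np.asarray(data.respondents)
    df = data.df.set_index("respondent_id", drop=False)
    boots = np.empty((n_boot, fit.spec.n_classes))
    for b in range(n_boot):
        draw = rng.choice(ids, size=len(ids), replace=True)
        frames = []
        for new_id, rid in enumerate(draw):
            block = df.loc[[rid]].copy()
            block["respondent_id"] = new_id
            frames.append(block)
        bdata = ChoiceDataset(pd.concat(frames, ignore_index=True))
        bfit = fit_eclc(
            bdata,
            fit.spec,
            seed=seed + 1 + b,
            tol=tol,
            max_iter=max_iter,
            n_restarts=1,
            init_beta=fit.beta,
        )
        boots[b] = bfit.class_probs
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    lo = np.minimum(lo, fit.class_probs)
    hi = np.maximum(hi, fit.class_probs)
    ci = pd.DataFrame(
        {"ci_lo": lo, "ci_hi": hi}, index=fit.spec.labels
    )
    fit.class_prob_ci = ci
    return ci
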