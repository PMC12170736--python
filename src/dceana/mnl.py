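"""Multinomial logit estimation for paired choice tasks.

With two options per task and i.i.d. type-I extreme value errors, the MNL
choice probability depends only on the difference of the dummy-coded
attribute vectors, so estimation reduces to a binary logit without
intercept on ``z = x_A - x_B`` with outcome "chose A".  Estimation is
delegated to :mod:`statsmodels` (Newton MLE, observed-information
covariance, Wald inference); this module adds the paired-design plumbing,
rank and separation diagnostics, the full-attendance interaction model, and
anchoring of coefficients to the worst state 55555.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .core import LEVEL5_INDICES, N_PARAMS, PARAM_NAMES, ChoiceSet, encode_profile
from .data import ChoiceDataset

__all__ = [
    "MNLFit",
    "choice_probability",
    "fit_mnl",
    "fit_mnl_interactions",
    "full_attender_decrements",
    "anchor",
    "AnchoringError",
]


class AnchoringError(ValueError):
    """The 55555 decrement is zero, so the anchored scale is undefined."""


@dataclass
class MNLFit:
    """Maximum-likelihood fit of the paired-choice MNL."""

    beta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    loglik: float
    aic: float
    bic: float
    n_obs: int
    converged: bool
    param_names: tuple[str, ...] = PARAM_NAMES
    pvalues: np.ndarray | None = None
    message: str = ""
    rank_deficient: bool = False

    @property
    def n_params(self) -> int:
        return len(self.beta)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.beta, "se": self.se, "p": self.pvalues},
            index=list(self.param_names),
        )

    def to_dict(self) -> dict:
        return {
            "coefficients": dict(zip(self.param_names, map(float, self.beta))),
            "se": dict(zip(self.param_names, map(float, self.se))),
            "pvalues": (
                dict(zip(self.param_names, map(float, self.pvalues)))
                if self.pvalues is not None
                else None
            ),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "message": self.message,
        }


@dataclass
class InteractionFit(MNLFit):
    """40-parameter fit: main effects plus full-attendance interactions."""

    @property
    def beta_main(self) -> np.ndarray:
        return self.beta[:N_PARAMS]

    @property
    def beta_interaction(self) -> np.ndarray:
        return self.beta[N_PARAMS:]


def choice_probability(
    beta: np.ndarray, cs: ChoiceSet
) -> tuple[float, float]:
    """(P(A), P(B)) under the paired logit at ``beta``.

    Invariant to adding a constant to both utilities; computed through the
    difference utility so it is overflow-safe.
    """
    beta = np.asarray(beta, dtype=float)
    z = encode_profile(cs.option_a) - encode_profile(cs.option_b)
    p_a = float(expit(z @ beta))
    return p_a, 1.0 - p_a


def _loglik(beta: np.ndarray, Z: np.ndarray, y: np.ndarray) -> float:
    eta = Z @ beta
    # log sigma(s*eta) with s = +/-1, stable form
    s = 2.0 * y - 1.0
    return float(-np.logaddexp(0.0, -s * eta).sum())


def _fit_logit(Z: np.ndarray, y: np.ndarray, names) -> MNLFit:
    n_obs, k = Z.shape
    rank = np.linalg.matrix_rank(Z)
    rank_deficient = rank < k
    message = ""
    converged = True
    if rank_deficient:
        warnings.warn(
            f"difference design matrix has rank {rank} < {k}; "
            "SEs use the pseudo-inverse of the information matrix",
            stacklevel=3,
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, Z)
            res = model.fit(disp=0, method="newton", maxiter=200)
        beta = np.asarray(res.params, dtype=float)
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception as exc:  # PerfectSeparation, singular Hessian, ...
        message = f"estimation failed: {exc}"
        beta = np.full(k, np.nan)
        converged = False
    if converged and np.max(np.abs(beta)) > 50:
        converged = False
        message = "apparent separation: a coefficient diverged"
    if not converged and message == "":
        message = "Newton iterations did not converge"
    if np.all(np.isfinite(beta)):
        p = expit(Z @ beta)
        w = p * (1 - p)
        info = (Z * w[:, None]).T @ Z
        vcov = np.linalg.pinv(info)
        ll = _loglik(beta, Z, y)
    else:
        vcov = np.full((k, k), np.nan)
        ll = np.nan
    se = np.sqrt(np.clip(np.diag(vcov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = beta / se
    from scipy.stats import norm

    pvalues = 2 * norm.sf(np.abs(zstat))
    aic = -2 * ll + 2 * k
    bic = -2 * ll + k * np.log(n_obs)
    return MNLFit(
        beta=beta,
        se=se,
        vcov=vcov,
        loglik=ll,
        aic=aic,
        bic=bic,
        n_obs=n_obs,
        converged=converged,
        param_names=tuple(names),
        pvalues=pvalues,
        message=message,
        rank_deficient=rank_deficient,
    )


def fit_mnl(data: ChoiceDataset) -> MNLFit:
    """Main-effects MNL on the paired differences.

    ``n_obs`` (and the BIC sample size) is the number of choice tasks.
    Separation and rank deficiency are reported through ``converged`` /
    ``rank_deficient`` rather than raised.
    """
    _, Z, y = data.design_arrays()
    return _fit_logit(Z, y, PARAM_NAMES)


def fit_mnl_interactions(
    data: ChoiceDataset, full_flags: dict | pd.Series
) -> MNLFit:
    """MNL with full-attendance interactions.

    Utility is ``x beta_main + f_i (x beta_int)`` with ``f_i`` the 0/1
    full-attender flag, so a full attender's total decrement for a level is
    ``beta_main + beta_int``.  With a single flag group the interaction
    block is unidentified and the model reduces to :func:`fit_mnl` (with a
    warning).
    """
    codes, Z, y = data.design_arrays()
    flags = pd.Series(full_flags)
    f = flags.reindex(data.respondents)
    if f.isna().any():
        missing = [r for r, v in zip(data.respondents, f) if pd.isna(v)]
        raise ValueError(f"full_flags missing respondents: {missing[:5]}")
    f_task = f.to_numpy(dtype=float)[codes]
    if len(np.unique(f_task)) < 2:
        warnings.warn(
            "all respondents share one full-attendance flag; "
            "interactions are unidentified, fitting main effects only",
            stacklevel=2,
        )
        fit = _fit_logit(Z, y, PARAM_NAMES)
        return InteractionFit(**fit.__dict__)
    Z40 = np.hstack([Z, Z * f_task[:, None]])
    names = list(PARAM_NAMES) + [f"full:{p}" for p in PARAM_NAMES]
    fit = _fit_logit(Z40, y, names)
    return InteractionFit(**fit.__dict__)


def full_attender_decrements(fit: MNLFit) -> np.ndarray:
    """Total level decrements for full attenders: beta_main + beta_int."""
    if len(fit.beta) != 2 * N_PARAMS:
        raise ValueError("fit has no interaction block")
    return fit.beta[:N_PARAMS] + fit.beta[N_PARAMS:]


def anchor(fit_or_beta) -> np.ndarray:
    """Rescale coefficients by the total decrement of state 55555.

    Each coefficient is divided by the sum of the five level-5
    coefficients, so the anchored value of 55555 is 1 by construction and
    the scale is invariant to multiplying the coefficient vector by any
    positive constant.
    """
    beta = (
        np.asarray(fit_or_beta, dtype=float)
        if not isinstance(fit_or_beta, MNLFit)
        else np.asarray(fit_or_beta.beta[:N_PARAMS], dtype=float)
    )
    if beta.shape != (N_PARAMS,):
        raise ValueError(f"expected a {N_PARAMS}-vector of main effects")
    total = beta[list(LEVEL5_INDICES)].sum()
    if abs(total) < 1e-12:
        raise AnchoringError("55555 decrement is zero; anchoring undefined")
    return beta / total
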